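"""Two-sample MR causal-effect estimators.

The central object is :class:`MRModel`, constructed from a
:class:`~mrscreen.harmonize.HarmonizedDataset`; ``fit(method=...)`` returns
an :class:`MRResult` carrying the estimate, its standard error, a
normal-based 95% CI and p-value, and method-specific extras.  Module-level
functions (:func:`wald_ratio`, :func:`ivw`, :func:`egger`,
:func:`weighted_median`, :func:`mode_estimators`) are thin wrappers over
the model class.

Methods
-------
wald_ratio
    beta_out/beta_exp for a single variant; first-order delta SE
    se_out/|beta_exp|.
ivw
    Weighted least squares of outcome betas on exposure betas through the
    origin, weights 1/se_out^2.  The fixed-effect SE is sqrt(1/sum(w x^2));
    the random-effects variant inflates it multiplicatively by
    sqrt(max(1, Q/(nsnp-1))).
egger
    The same regression with a free intercept after orienting every record
    to beta_exp >= 0; the intercept (with SE and p) estimates average
    directional pleiotropy.
weighted_median
    Weighted median of per-variant Wald ratios; consistent when >= 50% of
    weight lies on valid instruments.  SE by seeded parametric bootstrap.
simple_mode / weighted_mode
    Kernel-density modes of the ratio distribution (normal kernel,
    bandwidth = bandwidth_factor * 1.4826 * MAD of the ratios), unweighted
    and inverse-variance weighted.  SE by seeded parametric bootstrap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .harmonize import HarmonizedDataset

Z_95 = float(stats.norm.ppf(0.975))

METHOD_LABELS = {
    "wald_ratio": "Wald ratio",
    "ivw_fixed": "IVW (fixed effects)",
    "ivw_random": "IVW (multiplicative random effects)",
    "egger": "MR-Egger",
    "weighted_median": "Weighted median",
    "simple_mode": "Simple mode",
    "weighted_mode": "Weighted mode",
}

MODE_GRID_POINTS = 512
DEFAULT_N_BOOT = 1000


@dataclass
class MRResult:
    """A single causal-effect estimate (log-OR scale for binary outcomes)."""

    method: str
    beta: float
    se: float
    pvalue: float
    nsnp: int
    exposure: str = ""
    outcome: str = ""
    status: str = "ok"                   # "ok" | "not_applicable"
    extra: dict = field(default_factory=dict)

    @property
    def ci_low(self) -> float:
        return self.beta - Z_95 * self.se

    @property
    def ci_high(self) -> float:
        return self.beta + Z_95 * self.se

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.beta)

    def to_row(self) -> dict:
        row = {
            "exposure": self.exposure, "outcome": self.outcome,
            "method": self.method, "nsnp": self.nsnp,
            "beta": self.beta, "se": self.se,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "odds_ratio": math.exp(self.beta),
            "or_ci_low": math.exp(self.ci_low), "or_ci_high": math.exp(self.ci_high),
            "pvalue": self.pvalue,
        }
        row.update(self.extra)
        return row

    def summary(self) -> str:
        lab = METHOD_LABELS.get(self.method, self.method)
        if self.status != "ok":
            return f"{lab}: not applicable (nsnp={self.nsnp})"
        lines = [
            f"{lab}  ({self.exposure or 'exposure'} -> {self.outcome or 'outcome'})",
            f"  nsnp = {self.nsnp}",
            f"  beta = {self.beta:.6g}  (se {self.se:.6g})",
            f"  95% CI = [{self.ci_low:.6g}, {self.ci_high:.6g}]",
            f"  OR = {self.odds_ratio:.6g}  [{math.exp(self.ci_low):.6g}, {math.exp(self.ci_high):.6g}]",
            f"  p = {self.pvalue:.6g}",
        ]
        for k, v in self.extra.items():
            lines.append(f"  {k} = {v:.6g}" if isinstance(v, float) else f"  {k} = {v}")
        return "\n".join(lines)


def _norm_p(beta: float, se: float) -> float:
    if se == 0:
        return 1.0 if beta == 0 else 0.0
    return float(2.0 * stats.norm.sf(abs(beta / se)))


def _na_result(method: str, nsnp: int, exposure: str, outcome: str, why: str) -> MRResult:
    return MRResult(method, float("nan"), float("nan"), float("nan"), nsnp,
                    exposure, outcome, status="not_applicable", extra={"reason": why})


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median with linear interpolation at cumulative weight 0.5."""
    order = np.argsort(ratios, kind="mergesort")
    b = ratios[order]
    w = weights[order] / weights.sum()
    cum = np.cumsum(w) - 0.5 * w
    if cum[0] >= 0.5:
        return float(b[0])
    if cum[-1] < 0.5:
        return float(b[-1])
    i = int(np.searchsorted(cum, 0.5, side="right")) - 1
    if cum[i] == 0.5:
        return float(b[i])
    return float(b[i] + (b[i + 1] - b[i]) * (0.5 - cum[i]) / (cum[i + 1] - cum[i]))


def _mode(ratios: np.ndarray, weights: np.ndarray, bandwidth_factor: float) -> float:
    """Argmax of a normal-kernel density of the ratios (first max wins,
    i.e. ties break toward the smaller ratio)."""
    med = np.median(ratios)
    mad = np.median(np.abs(ratios - med))
    h = bandwidth_factor * 1.4826 * mad
    if h <= 0:
        # degenerate spread: point masses — the mode is the heaviest ratio
        h = 1e-9 * (1.0 + abs(float(med)))
    lo, hi = ratios.min() - 3 * h, ratios.max() + 3 * h
    grid = np.linspace(lo, hi, MODE_GRID_POINTS)
    z = (grid[:, None] - ratios[None, :]) / h
    dens = np.exp(-0.5 * z * z) @ (weights / weights.sum())
    top = dens.max()
    # near-ties (within float round-off) break toward the smaller ratio
    return float(grid[np.flatnonzero(dens >= top * (1.0 - 1e-12))[0]])


class MRModel:
    """Two-sample MR model over a harmonized exposure/outcome dataset.

    Parameters
    ----------
    data : HarmonizedDataset
        Per-SNP exposure and outcome effects on a common allele coding.

    Examples
    --------
    >>> model = MRModel(harmonized)
    >>> res = model.fit(method="ivw", effects_model="auto")
    >>> print(res.summary())
    """

    def __init__(self, data: HarmonizedDataset):
        self.data = data
        self.bx, self.sx, self.by, self.sy = data.arrays()
        if np.any(self.sx <= 0) or np.any(self.sy <= 0):
            raise ValueError("standard errors must be positive")
        self.nsnp = len(self.bx)
        self.exposure = data.exposure_name
        self.outcome = data.outcome_name

    # ---------------------------------------------------------------- ratios
    def _ratios(self, bx=None, by=None) -> tuple[np.ndarray, np.ndarray]:
        """Per-SNP Wald ratios and their first-order SEs."""
        bx = self.bx if bx is None else bx
        by = self.by if by is None else by
        if np.any(bx == 0):
            raise ValueError("wald ratio undefined: beta_exp = 0 for some SNP")
        return by / bx, self.sy / np.abs(bx)

    # ------------------------------------------------------------------- fit
    def fit(self, method: str = "ivw", effects_model: str = "fixed",
            n_boot: int = DEFAULT_N_BOOT, seed: int | None = None,
            bandwidth_factor: float = 1.0) -> MRResult:
        """Fit one estimator and return its :class:`MRResult`.

        ``method`` is one of ``wald_ratio, ivw, egger, weighted_median,
        simple_mode, weighted_mode``; for ``ivw``, ``effects_model`` selects
        ``fixed``, ``random`` or ``auto`` (heterogeneity-driven switch).
        """
        if method == "wald_ratio":
            return self._fit_wald()
        if method == "ivw":
            return self._fit_ivw(effects_model)
        if method == "egger":
            return self._fit_egger()
        if method == "weighted_median":
            return self._fit_weighted_median(n_boot, seed)
        if method in ("simple_mode", "weighted_mode"):
            return self._fit_mode(method, bandwidth_factor, n_boot, seed)
        raise ValueError(f"unknown method {method!r}")

    def fit_all(self, n_boot: int = DEFAULT_N_BOOT, seed: int | None = None,
                bandwidth_factor: float = 1.0) -> list[MRResult]:
        """Every estimator the SNP count permits (the standard method panel)."""
        if self.nsnp == 1:
            return [self._fit_wald()]
        out = [self._fit_ivw("auto")]
        out.append(self._fit_egger())
        out.append(self._fit_weighted_median(n_boot, seed))
        s, w = self.mode_estimators(bandwidth_factor, n_boot, seed)
        out.extend([s, w])
        return out

    # -------------------------------------------------------------- methods
    def _fit_wald(self) -> MRResult:
        if self.nsnp != 1:
            raise ValueError(f"wald_ratio requires exactly 1 SNP, got {self.nsnp}")
        bx, by, sy = self.bx[0], self.by[0], self.sy[0]
        if bx == 0:
            raise ValueError("undefined ratio: beta_exp = 0")
        beta = by / bx
        se = sy / abs(bx)
        return MRResult("wald_ratio", float(beta), float(se), _norm_p(beta, se), 1,
                        self.exposure, self.outcome)

    def cochran_q(self) -> tuple[float, int, float, float]:
        """(Q, df, p, I^2) over per-SNP Wald ratios, IVW-weighted."""
        if self.nsnp < 2:
            raise ValueError("cochran_q requires >= 2 SNPs")
        ratios, se_r = self._ratios()
        w = 1.0 / se_r**2
        beta_ivw = float(np.sum(w * ratios) / np.sum(w))
        q = float(np.sum(w * (ratios - beta_ivw) ** 2))
        df = self.nsnp - 1
        p_q = float(stats.chi2.sf(q, df))
        i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
        return q, df, p_q, i2

    def _fit_ivw(self, effects_model: str = "fixed") -> MRResult:
        if self.nsnp < 1:
            raise ValueError("ivw requires >= 1 SNP")
        w = 1.0 / self.sy**2
        sxx = float(np.sum(w * self.bx**2))
        beta = float(np.sum(w * self.bx * self.by) / sxx)
        se_fixed = math.sqrt(1.0 / sxx)
        extra: dict = {}
        if self.nsnp >= 2:
            q, df, p_q, i2 = self.cochran_q()
            extra.update(q=q, q_df=df, q_pvalue=p_q, i2=i2)
        else:
            q, df, p_q, i2 = 0.0, 0, float("nan"), 0.0
        if effects_model == "auto":
            from .sensitivity import select_effects_model
            effects_model = "fixed" if self.nsnp < 2 else select_effects_model(p_q, i2)
        if effects_model == "fixed":
            se, method = se_fixed, "ivw_fixed"
        elif effects_model == "random":
            infl = math.sqrt(max(1.0, q / df)) if df >= 1 else 1.0
            se, method = se_fixed * infl, "ivw_random"
        else:
            raise ValueError(f"unknown effects_model {effects_model!r}")
        return MRResult(method, beta, se, _norm_p(beta, se), self.nsnp,
                        self.exposure, self.outcome, extra=extra)

    def _egger_design(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        # InSIDE orientation: re-sign each record so beta_exp >= 0
        sign = np.where(self.bx < 0, -1.0, 1.0)
        return sign * self.bx, sign * self.by, 1.0 / self.sy**2

    def _fit_egger(self) -> MRResult:
        if self.nsnp < 3:
            return _na_result("egger", self.nsnp, self.exposure, self.outcome,
                              "MR-Egger requires >= 3 SNPs")
        x, y, w = self._egger_design()
        sw = w.sum()
        xbar = np.sum(w * x) / sw
        ybar = np.sum(w * y) / sw
        sxx = np.sum(w * (x - xbar) ** 2)
        slope = float(np.sum(w * (x - xbar) * (y - ybar)) / sxx)
        intercept = float(ybar - slope * xbar)
        resid = y - intercept - slope * x
        # multiplicative over-dispersion, floored at 1 (no under-dispersion credit)
        disp = max(1.0, float(np.sum(w * resid**2) / (self.nsnp - 2)))
        se_slope = math.sqrt(disp / sxx)
        se_inter = math.sqrt(disp * (1.0 / sw + xbar**2 / sxx))
        return MRResult("egger", slope, se_slope, _norm_p(slope, se_slope), self.nsnp,
                        self.exposure, self.outcome,
                        extra={"egger_intercept": intercept,
                               "egger_intercept_se": se_inter,
                               "egger_intercept_pvalue": _norm_p(intercept, se_inter),
                               "dispersion": disp})

    def _boot_draws(self, n_boot: int, seed: int | None) -> tuple[np.ndarray, np.ndarray]:
        rng = np.random.default_rng(seed)
        bx = rng.normal(self.bx, self.sx, size=(n_boot, self.nsnp))
        by = rng.normal(self.by, self.sy, size=(n_boot, self.nsnp))
        return bx, by

    def _fit_weighted_median(self, n_boot: int = DEFAULT_N_BOOT,
                             seed: int | None = None) -> MRResult:
        if self.nsnp < 3:
            return _na_result("weighted_median", self.nsnp, self.exposure, self.outcome,
                              "weighted median requires >= 3 SNPs")
        ratios, se_r = self._ratios()
        weights = 1.0 / se_r**2
        beta = _weighted_median(ratios, weights)
        se = float("nan")
        if n_boot > 0:
            bxs, bys = self._boot_draws(n_boot, seed)
            ests = np.empty(n_boot)
            for b in range(n_boot):
                bx = bxs[b]
                bx = np.where(bx == 0, np.finfo(float).tiny, bx)
                r = bys[b] / bx
                wgt = np.abs(bx) ** 2 / self.sy**2
                ests[b] = _weighted_median(r, wgt)
            se = float(np.std(ests, ddof=1))
        return MRResult("weighted_median", beta, se, _norm_p(beta, se), self.nsnp,
                        self.exposure, self.outcome, extra={"n_boot": n_boot})

    def mode_estimators(self, bandwidth_factor: float = 1.0,
                        n_boot: int = DEFAULT_N_BOOT,
                        seed: int | None = None) -> tuple[MRResult, MRResult]:
        """(simple mode, weighted mode) of the per-SNP ratio distribution."""
        if self.nsnp < 3:
            na = lambda m: _na_result(m, self.nsnp, self.exposure, self.outcome,
                                      "mode estimators require >= 3 SNPs")
            return na("simple_mode"), na("weighted_mode")
        ratios, se_r = self._ratios()
        w_iv = 1.0 / se_r**2
        ones = np.ones_like(ratios)
        beta_s = _mode(ratios, ones, bandwidth_factor)
        beta_w = _mode(ratios, w_iv, bandwidth_factor)
        se_s = se_w = float("nan")
        if n_boot > 0:
            bxs, bys = self._boot_draws(n_boot, seed)
            est_s = np.empty(n_boot)
            est_w = np.empty(n_boot)
            for b in range(n_boot):
                bx = bxs[b]
                bx = np.where(bx == 0, np.finfo(float).tiny, bx)
                r = bys[b] / bx
                wgt = np.abs(bx) ** 2 / self.sy**2
                est_s[b] = _mode(r, np.ones_like(r), bandwidth_factor)
                est_w[b] = _mode(r, wgt, bandwidth_factor)
            se_s = float(np.std(est_s, ddof=1))
            se_w = float(np.std(est_w, ddof=1))
        simple = MRResult("simple_mode", beta_s, se_s, _norm_p(beta_s, se_s), self.nsnp,
                          self.exposure, self.outcome,
                          extra={"bandwidth_factor": bandwidth_factor, "n_boot": n_boot})
        weighted = MRResult("weighted_mode", beta_w, se_w, _norm_p(beta_w, se_w), self.nsnp,
                            self.exposure, self.outcome,
                            extra={"bandwidth_factor": bandwidth_factor, "n_boot": n_boot})
        return simple, weighted

    def sensitivity(self, n_exp: int | None = None, n_out: int | None = None):
        """Heterogeneity / pleiotropy / directionality diagnostics."""
        from .sensitivity import sensitivity_report

        return sensitivity_report(self.data, n_exp=n_exp, n_out=n_out)


# ------------------------------------------------------------------ wrappers

def wald_ratio(rec) -> MRResult:
    """Single-variant Wald ratio; `rec` is a HarmonizedDataset with one SNP
    or a one-row mapping with beta_exp/se_exp/beta_out/se_out."""
    if isinstance(rec, HarmonizedDataset):
        return MRModel(rec)._fit_wald()
    from .harmonize import from_arrays
    ds = from_arrays([rec["beta_exp"]], [rec["se_exp"]], [rec["beta_out"]], [rec["se_out"]])
    return MRModel(ds)._fit_wald()


def ivw(ds: HarmonizedDataset, effects_model: str = "fixed") -> MRResult:
    return MRModel(ds)._fit_ivw(effects_model)


def egger(ds: HarmonizedDataset) -> MRResult:
    return MRModel(ds)._fit_egger()


def weighted_median(ds: HarmonizedDataset, n_boot: int = DEFAULT_N_BOOT,
                    seed: int | None = None) -> MRResult:
    return MRModel(ds)._fit_weighted_median(n_boot, seed)


def mode_estimators(ds: HarmonizedDataset, bandwidth_factor: float = 1.0,
                    n_boot: int = DEFAULT_N_BOOT,
                    seed: int | None = None) -> tuple[MRResult, MRResult]:
    return MRModel(ds).mode_estimators(bandwidth_factor, n_boot, seed)
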