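"""Heterogeneity, pleiotropy, effects-model choice and directionality.

Cochran's Q is computed over per-SNP Wald ratios with first-order SEs
(the same weights the estimators use); I^2 = max(0, (Q - df)/Q).  The
random-effects IVW model is selected only under the dual criterion
``p_Q < 0.05 AND I^2 > 0.25`` (both thresholds configurable).  Causal
direction is checked with a Steiger-type test comparing instrument-explained
variance in exposure versus outcome via Fisher-z transformed correlation
magnitudes with variances 1/(n-3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .harmonize import HarmonizedDataset
from .instruments import snp_r2

HETEROGENEITY_P = 0.05
HETEROGENEITY_I2 = 0.25


@dataclass
class SensitivityReport:
    """Diagnostics accompanying an MR estimate."""

    q: float
    df: int
    p_q: float
    i2: float
    effects_model_chosen: str
    egger_intercept: float
    egger_intercept_se: float
    p_intercept: float
    steiger_direction_ok: bool
    p_steiger: float
    r2_exposure: float
    r2_outcome: float
    nsnp: int = 0
    notes: str = ""

    def to_row(self) -> dict:
        return {
            "method": "sensitivity", "nsnp": self.nsnp,
            "q": self.q, "q_df": self.df, "q_pvalue": self.p_q, "i2": self.i2,
            "effects_model": self.effects_model_chosen,
            "egger_intercept": self.egger_intercept,
            "egger_intercept_se": self.egger_intercept_se,
            "egger_intercept_pvalue": self.p_intercept,
            "steiger_direction_ok": self.steiger_direction_ok,
            "steiger_pvalue": self.p_steiger,
            "r2_exposure": self.r2_exposure, "r2_outcome": self.r2_outcome,
            "notes": self.notes,
        }


def cochran_q(ds: HarmonizedDataset) -> tuple[float, int, float, float]:
    """(Q, df, p, I^2) across per-SNP Wald ratios.

    Raises ValueError below 2 SNPs (a single ratio has no heterogeneity).
    """
    from .model import MRModel

    if ds.nsnp < 2:
        raise ValueError("cochran_q: not applicable below 2 SNPs")
    return MRModel(ds).cochran_q()


def select_effects_model(p_q: float, i2: float,
                         p_threshold: float = HETEROGENEITY_P,
                         i2_threshold: float = HETEROGENEITY_I2) -> str:
    """'random' iff p_Q < p_threshold AND I^2 > i2_threshold, else 'fixed'."""
    if np.isnan(p_q) or np.isnan(i2):
        return "fixed"
    return "random" if (p_q < p_threshold and i2 > i2_threshold) else "fixed"


def steiger_test(ds: HarmonizedDataset, n_exp: int | None = None,
                 n_out: int | None = None) -> tuple[bool, float, float, float]:
    """MR Steiger directionality test.

    Sums per-SNP explained variance over the instruments for each trait and
    compares the implied correlation magnitudes |r| = sqrt(R^2) via
    Fisher-z, z-variance 1/(n-3).  Returns
    (direction_ok, p, r2_exposure, r2_outcome).
    """
    t = ds.table
    if n_exp is None:
        n_exp = int(np.median(t["n_exp"]))
    if n_out is None:
        n_out = int(np.median(t["n_out"]))
    if n_exp <= 3 or n_out <= 3:
        raise ValueError("steiger_test: sample sizes must exceed 3")
    r2_exp = float(sum(snp_r2(beta=b, se=s, n=n_exp)
                       for b, s in zip(t["beta_exp"], t["se_exp"])))
    r2_out = float(sum(snp_r2(beta=b, se=s, n=n_out)
                       for b, s in zip(t["beta_out"], t["se_out"])))
    r2_exp = min(r2_exp, np.nextafter(1.0, 0.0))
    r2_out = min(r2_out, np.nextafter(1.0, 0.0))
    z_exp = np.arctanh(np.sqrt(r2_exp))
    z_out = np.arctanh(np.sqrt(r2_out))
    z = (z_exp - z_out) / np.sqrt(1.0 / (n_exp - 3) + 1.0 / (n_out - 3))
    p = float(2.0 * stats.norm.sf(abs(z)))
    return bool(r2_exp > r2_out), p, r2_exp, r2_out


def sensitivity_report(ds: HarmonizedDataset, n_exp: int | None = None,
                       n_out: int | None = None,
                       p_threshold: float = HETEROGENEITY_P,
                       i2_threshold: float = HETEROGENEITY_I2) -> SensitivityReport:
    """Full diagnostics for one harmonized dataset.

    Heterogeneity needs >= 2 SNPs and the Egger intercept >= 3; fields that
    do not apply are NaN and noted.
    """
    from .model import MRModel

    notes = []
    if ds.nsnp >= 2:
        q, df, p_q, i2 = cochran_q(ds)
        model = select_effects_model(p_q, i2, p_threshold, i2_threshold)
    else:
        q, df, p_q, i2, model = float("nan"), 0, float("nan"), float("nan"), "fixed"
        notes.append("heterogeneity not applicable (nsnp < 2)")
    if ds.nsnp >= 3:
        eg = MRModel(ds)._fit_egger()
        a = eg.extra["egger_intercept"]
        a_se = eg.extra["egger_intercept_se"]
        a_p = eg.extra["egger_intercept_pvalue"]
    else:
        a = a_se = a_p = float("nan")
        notes.append("Egger intercept not applicable (nsnp < 3)")
    ok, p_st, r2e, r2o = steiger_test(ds, n_exp, n_out)
    return SensitivityReport(q, df, p_q, i2, model, a, a_se, a_p, ok, p_st,
                             r2e, r2o, nsnp=ds.nsnp, notes="; ".join(notes))
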