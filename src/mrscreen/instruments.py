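"""Instrument selection and strength for two-sample MR.

Candidate variants must reach genome-wide significance (default p < 5e-8)
and survive greedy LD clumping (default r^2 < 0.001 within a 10,000 kb
window).  Instrument strength is summarised by the F-statistic
``F = ((N - K - 1)/K) * (R2 / (1 - R2))`` with the conventional weak-
instrument threshold of 10; weak sets are flagged, never auto-dropped.

Per-SNP explained variance is approximated from summary statistics as
``R2 = z^2 / (z^2 + n)`` with ``z = beta/se`` — algebraically identical to
the 2p(1-p)beta^2 form on the standardized scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import SnpAssociation, SummaryStatSet

logger = logging.getLogger(__name__)

DEFAULT_P_THRESHOLD = 5e-8
DEFAULT_CLUMP_R2 = 0.001
DEFAULT_CLUMP_KB = 10_000
WEAK_F_THRESHOLD = 10.0


@dataclass
class LdMatrix:
    """Pairwise LD r^2 between named SNPs (symmetric, unit diagonal)."""

    snp_ids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.snp_ids)
        if self.r2.shape != (k, k):
            raise ValueError(f"LD matrix shape {self.r2.shape} does not match {k} SNP ids")
        if np.any(self.r2 < 0) or np.any(self.r2 > 1):
            raise ValueError("LD r^2 values must lie in [0,1]")
        if not np.allclose(self.r2, self.r2.T):
            raise ValueError("LD matrix must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0):
            raise ValueError("LD matrix diagonal must be 1")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def lookup(self, a: str, b: str) -> float | None:
        """Pairwise r^2, or None when either SNP is absent."""
        ia, ib = self._index.get(a), self._index.get(b)
        if ia is None or ib is None:
            return None
        return float(self.r2[ia, ib])


def read_ld_matrix(path: str) -> LdMatrix:
    """Read a square TSV with SNP ids as header row and first column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError("LD matrix row and column SNP ids differ")
    return LdMatrix(list(df.columns), df.to_numpy(dtype=float))


def write_ld_matrix(ld: LdMatrix, path: str) -> None:
    pd.DataFrame(ld.r2, index=ld.snp_ids, columns=ld.snp_ids).to_csv(path, sep="\t")


@dataclass
class InstrumentSet:
    """Selected instruments for one exposure, with strength diagnostics."""

    exposure_name: str
    table: pd.DataFrame                      # canonical summary columns, retained SNPs
    r2_total: float
    f_statistic: float
    k: int
    no_instruments: bool = False
    weak: bool = False
    p_threshold: float = DEFAULT_P_THRESHOLD
    log: dict = field(default_factory=dict)

    def snp_ids(self) -> list[str]:
        return list(self.table["snp_id"])

    def records(self) -> list[SnpAssociation]:
        return SummaryStatSet(self.exposure_name, "quantitative", self.table).records()


def snp_r2(assoc: SnpAssociation | None = None, *, beta: float | None = None,
           se: float | None = None, n: int | None = None) -> float:
    """Per-SNP explained variance R2 = z^2/(z^2+n), clipped to [0,1).

    Accepts a SnpAssociation or explicit beta/se/n keyword values.
    """
    if assoc is not None:
        beta, se, n = assoc.beta, assoc.se, assoc.n
    if n is None or beta is None or se is None:
        raise ValueError("snp_r2 requires beta, se and n")
    if n <= 2:
        raise ValueError(f"snp_r2: sample size n={n} too small (need n > 2)")
    z2 = (beta / se) ** 2
    return float(np.clip(z2 / (z2 + n), 0.0, np.nextafter(1.0, 0.0)))


def f_statistic(n: int, k: int, r2_total: float) -> float:
    """Instrument-strength F = ((N - K - 1)/K) * (R2/(1 - R2))."""
    if k < 1:
        raise ValueError("f_statistic: k must be >= 1")
    if n <= k + 1:
        raise ValueError(f"f_statistic: need n > k+1 (n={n}, k={k})")
    if not 0.0 <= r2_total < 1.0:
        raise ValueError(f"f_statistic: r2_total must be in [0,1), got {r2_total}")
    return ((n - k - 1) / k) * (r2_total / (1.0 - r2_total))


def _clump(cand: pd.DataFrame, r2_threshold: float, window_kb: int,
           ld: LdMatrix | None) -> list[int]:
    """Greedy clumping over a candidate frame already sorted by priority.

    A candidate is dropped when it lies within window_kb of a retained SNP
    on the same chromosome AND either no LD information is available for the
    pair (conservative distance-only rule) or the pairwise r^2 is >= the
    threshold.
    """
    window_bp = window_kb * 1000
    kept: list[int] = []
    for i in range(len(cand)):
        chrom_i = cand["chrom"].iat[i]
        pos_i = cand["pos"].iat[i]
        sid_i = cand["snp_id"].iat[i]
        ok = True
        for j in kept:
            if cand["chrom"].iat[j] != chrom_i:
                continue
            if abs(int(cand["pos"].iat[j]) - int(pos_i)) > window_bp:
                continue
            pair_r2 = None if ld is None else ld.lookup(sid_i, cand["snp_id"].iat[j])
            if pair_r2 is None or pair_r2 >= r2_threshold:
                ok = False
                break
        if ok:
            kept.append(i)
    return kept


def select_instruments(
    stats: SummaryStatSet,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    r2_threshold: float = DEFAULT_CLUMP_R2,
    window_kb: int = DEFAULT_CLUMP_KB,
    ld: LdMatrix | None = None,
) -> InstrumentSet:
    """Select independent genome-wide-significant instruments for one exposure.

    Candidates are ordered by ascending p-value (ties broken by chrom, pos,
    snp_id for determinism) and greedily clumped.  When no SNP reaches the
    p threshold an empty set is returned with ``no_instruments`` set — the
    screening loop skips such exposures rather than aborting.
    """
    if not 0 < p_threshold < 1:
        raise ValueError("p_threshold must be in (0,1)")
    if not 0 <= r2_threshold <= 1:
        raise ValueError("r2_threshold must be in [0,1]")
    if window_kb <= 0:
        raise ValueError("window_kb must be positive")

    df = stats.table
    cand = df[df["pvalue"] < p_threshold].copy()
    if cand.empty:
        logger.info("select_instruments(%s): no SNP passes p < %g", stats.trait_name, p_threshold)
        return InstrumentSet(stats.trait_name, df.iloc[0:0], 0.0, float("nan"), 0,
                             no_instruments=True, p_threshold=p_threshold,
                             log={"n_candidates": 0})
    cand = cand.sort_values(["pvalue", "chrom", "pos", "snp_id"],
                            kind="mergesort").reset_index(drop=True)
    kept_idx = _clump(cand, r2_threshold, window_kb, ld)
    kept = cand.iloc[kept_idx].reset_index(drop=True)
    if ld is None and len(kept) < len(cand):
        logger.info("select_instruments(%s): no LD matrix — distance-only clumping "
                    "(conservative) removed %d SNPs", stats.trait_name, len(cand) - len(kept))

    z2 = (kept["beta"] / kept["se"]) ** 2
    r2_each = z2 / (z2 + kept["n"])
    r2_total = float(np.clip(r2_each.sum(), 0.0, np.nextafter(1.0, 0.0)))
    k = len(kept)
    n_eff = int(np.median(kept["n"]))
    f = f_statistic(n_eff, k, r2_total)
    weak = f < WEAK_F_THRESHOLD
    if weak:
        logger.warning("select_instruments(%s): weak instruments, F=%.2f < %.0f",
                       stats.trait_name, f, WEAK_F_THRESHOLD)
    return InstrumentSet(stats.trait_name, kept, r2_total, f, k, weak=weak,
                         p_threshold=p_threshold,
                         log={"n_candidates": len(cand), "n_clumped_out": len(cand) - k,
                              "n_effective": n_eff})
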