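"""GWAS summary-statistics containers and tabular I/O.

Summary statistics are held as a :class:`pandas.DataFrame` with one row per
SNP and a canonical column set (``snp_id, chrom, pos, effect_allele,
other_allele, eaf, beta, se, pvalue, n``).  All effects are per copy of the
effect allele; for binary traits ``beta`` is on the log-odds scale.
Positions are 1-based, following GWAS summary-file convention.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: canonical column order for summary-statistic tables
COLUMNS = [
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
]

VALID_ALLELES = frozenset("ACGT")

#: built-in column dialects: canonical name -> file column name
DIALECTS: dict[str, dict[str, str]] = {
    # the package's own canonical headers
    "generic": {c: c for c in COLUMNS},
    # headers mirroring common GWAS release files (FinnGen-style)
    "gwas": {
        "snp_id": "rsids",
        "chrom": "#chrom",
        "pos": "pos",
        "effect_allele": "alt",
        "other_allele": "ref",
        "eaf": "af_alt",
        "beta": "beta",
        "se": "sebeta",
        "pvalue": "pval",
        "n": "n",
    },
}

# factor of 10 on the p-value before the normal |beta/se| check warns
PVALUE_CHECK_LOG10_TOL = 1.0


@dataclass(frozen=True)
class SnpAssociation:
    """One SNP's summary association with one trait."""

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pvalue: float
    n: int

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            raise ValueError(f"{self.snp_id}: alleles must be single characters in A/C/G/T")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele identical")
        if not self.se > 0:
            raise ValueError(f"{self.snp_id}: se must be positive")
        if not 0 < self.eaf < 1:
            raise ValueError(f"{self.snp_id}: eaf must be in (0,1)")
        if not 0 < self.pvalue <= 1:
            raise ValueError(f"{self.snp_id}: pvalue must be in (0,1]")


@dataclass
class SummaryStatSet:
    """GWAS summary statistics for a single trait.

    Parameters
    ----------
    trait_name : str
        Label of the trait (e.g. a metabolite name or disease endpoint).
    trait_type : {"quantitative", "binary"}
        Binary traits carry log-odds betas.
    table : pandas.DataFrame
        One row per SNP with the canonical :data:`COLUMNS`.
    """

    trait_name: str
    trait_type: str = "quantitative"
    table: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=COLUMNS))

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "binary"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        missing = [c for c in COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"summary table missing columns: {missing}")
        self.table = self.table.loc[:, COLUMNS].reset_index(drop=True)
        if self.table["snp_id"].duplicated().any():
            dups = self.table.loc[self.table["snp_id"].duplicated(), "snp_id"].tolist()
            raise ValueError(f"duplicate snp_id in {self.trait_name!r}: {dups[:5]}")

    def __len__(self) -> int:
        return len(self.table)

    def __iter__(self) -> Iterator[SnpAssociation]:
        return iter(self.records())

    def records(self) -> list[SnpAssociation]:
        return [SnpAssociation(**{**row, "chrom": str(row["chrom"]), "pos": int(row["pos"]), "n": int(row["n"])})
                for row in self.table.to_dict("records")]

    def get(self, snp_id: str) -> SnpAssociation:
        sub = self.table[self.table["snp_id"] == snp_id]
        if sub.empty:
            raise KeyError(snp_id)
        return SummaryStatSet(self.trait_name, self.trait_type, sub).records()[0]

    @classmethod
    def from_records(cls, trait_name: str, records: Iterable[SnpAssociation],
                     trait_type: str = "quantitative") -> "SummaryStatSet":
        rows = [vars(r) for r in records]
        return cls(trait_name, trait_type, pd.DataFrame(rows, columns=COLUMNS))


def _resolve_dialect(dialect: str | Mapping[str, str] | None) -> dict[str, str]:
    if dialect is None:
        return DIALECTS["generic"]
    if isinstance(dialect, str):
        try:
            return DIALECTS[dialect]
        except KeyError:
            raise ValueError(f"unknown dialect {dialect!r}; built-ins: {sorted(DIALECTS)}") from None
    mapping = dict(dialect)
    missing = [c for c in COLUMNS if c not in mapping]
    if missing:
        raise ValueError(f"dialect mapping missing canonical columns: {missing}")
    return mapping


def _detect_sep(path: str) -> str:
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def validate_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Split a canonical-column frame into valid rows and per-reason drop counts."""
    drops: dict[str, int] = {}
    mask = pd.Series(True, index=df.index)

    def _drop(cond: pd.Series, reason: str) -> None:
        bad = cond & mask
        if bad.any():
            drops[reason] = int(bad.sum())
        mask[bad] = False

    num = df[["eaf", "beta", "se", "pvalue", "n", "pos"]].apply(pd.to_numeric, errors="coerce")
    _drop(num.isna().any(axis=1) | df["snp_id"].isna(), "missing_or_nonnumeric")
    ea = df["effect_allele"].astype(str).str.upper()
    oa = df["other_allele"].astype(str).str.upper()
    _drop(~(ea.isin(list(VALID_ALLELES)) & oa.isin(list(VALID_ALLELES))), "non_snv_allele")
    _drop(ea == oa, "identical_alleles")
    _drop(~(num["se"] > 0), "nonpositive_se")
    _drop(~((num["eaf"] > 0) & (num["eaf"] < 1)), "eaf_out_of_range")
    _drop(~((num["pvalue"] > 0) & (num["pvalue"] <= 1)), "pvalue_out_of_range")
    _drop(~(num["n"] > 0), "nonpositive_n")
    _drop(df["snp_id"].duplicated(), "duplicate_snp_id")

    out = df[mask].copy()
    out["effect_allele"] = ea[mask]
    out["other_allele"] = oa[mask]
    for c in ("eaf", "beta", "se", "pvalue"):
        out[c] = num.loc[mask, c].astype(float)
    out["pos"] = num.loc[mask, "pos"].astype(np.int64)
    out["n"] = num.loc[mask, "n"].astype(np.int64)
    out["chrom"] = out["chrom"].astype(str)
    out["snp_id"] = out["snp_id"].astype(str)
    return out.reset_index(drop=True), drops


def read_summary_stats(
    path: str,
    dialect: str | Mapping[str, str] | None = None,
    trait_name: str | None = None,
    trait_type: str = "quantitative",
) -> SummaryStatSet:
    """Read a delimited (TSV/CSV, optionally gzipped) GWAS summary table.

    The delimiter is auto-detected from the header line.  Rows violating the
    per-SNP invariants (non-SNV alleles, se<=0, eaf outside (0,1), ...) are
    dropped and counted in the log; a missing mandatory column or an empty
    valid set is a hard error.  A warn-only consistency check compares the
    reported p-value with 2*Phi(-|beta/se|) within a factor of
    10**PVALUE_CHECK_LOG10_TOL.
    """
    mapping = _resolve_dialect(dialect)
    sep = _detect_sep(path)
    raw = pd.read_csv(path, sep=sep, dtype={mapping["chrom"]: str, mapping["snp_id"]: str})
    for canon, col in mapping.items():
        if col not in raw.columns:
            raise ValueError(f"missing mandatory column {col!r} (for {canon!r}) in {path}")
    df = raw.rename(columns={v: k for k, v in mapping.items()})[COLUMNS]
    valid, drops = validate_rows(df)
    if drops:
        logger.info("read_summary_stats(%s): dropped rows %s", path, drops)
    if valid.empty:
        raise ValueError(f"no valid summary-statistic rows in {path}")

    z = np.abs(valid["beta"] / valid["se"])
    p_z = 2.0 * stats.norm.sf(z)
    with np.errstate(divide="ignore"):
        off = np.abs(np.log10(np.maximum(valid["pvalue"], 5e-324)) - np.log10(np.maximum(p_z, 5e-324)))
    n_incons = int((off > PVALUE_CHECK_LOG10_TOL).sum())
    if n_incons:
        logger.warning(
            "read_summary_stats(%s): %d rows with p-value inconsistent with |beta/se| "
            "beyond a factor of 10 (kept)", path, n_incons,
        )
    return SummaryStatSet(trait_name or str(path), trait_type, valid)


def write_summary_stats(stats_set: SummaryStatSet, path: str) -> None:
    """Write a SummaryStatSet as a canonical-header TSV (gzip by suffix)."""
    stats_set.table.to_csv(path, sep="\t", index=False)


def write_results_table(results: Iterable, path: str) -> None:
    """Write MR/sensitivity/mediation results as a fixed-column TSV report.

    Column order: ``exposure, outcome, method, nsnp, beta, se, ci_low,
    ci_high, odds_ratio, or_ci_low, or_ci_high, pvalue`` followed by any
    method-specific extras serialized as ``key=value`` pairs.  Numbers are
    written with 6 significant digits.
    """
    rows = []
    for res in results:
        row = res.to_row() if hasattr(res, "to_row") else dict(res)
        rows.append(row)
    if not rows:
        raise ValueError("write_results_table: empty results")
    lead = ["exposure", "outcome", "method", "nsnp", "beta", "se", "ci_low",
            "ci_high", "odds_ratio", "or_ci_low", "or_ci_high", "pvalue"]
    extra_cols = sorted({k for r in rows for k in r} - set(lead))
    df = pd.DataFrame(rows, columns=lead + extra_cols)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def or_from_beta(beta: float, se: float) -> tuple[float, float, float]:
    """(OR, OR 95% CI low, high) from a log-odds estimate."""
    from .model import Z_95

    return math.exp(beta), math.exp(beta - Z_95 * se), math.exp(beta + Z_95 * se)
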