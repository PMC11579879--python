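"""Allele harmonization of exposure and outcome summary statistics.

Exposure and outcome sets are merged on shared SNP ids and every outcome
record is re-expressed on the exposure's effect-allele coding:

* same alleles -> unchanged;
* swapped alleles -> outcome beta negated, EAF complemented;
* strand-complemented alleles (A<->T, C<->G), possibly also swapped ->
  relabelled (and negated/complemented when swapped);
* palindromic SNPs (A/T or C/G pairs), where labels cannot distinguish a
  swap from a strand flip, are oriented by allele frequency: both EAFs must
  lie outside the ambiguity window [0.5-w, 0.5+w] (default w=0.08); when the
  label-implied alignment disagrees on which allele is minor the outcome is
  re-oriented.  Ambiguous or frequency-less palindromes are dropped;
* irreconcilable allele pairs and (chrom,pos) conflicts are dropped.

All drops are counted; an empty intersection is a hard error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import SummaryStatSet

logger = logging.getLogger(__name__)

DEFAULT_PALINDROME_EAF_WINDOW = 0.08

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

ACTION_NONE = "none"
ACTION_FLIPPED = "outcome_flipped"
ACTION_STRAND = "strand_complemented"
ACTION_STRAND_FLIPPED = "strand_complemented_and_flipped"

#: columns of the harmonized table
HARMONIZED_COLUMNS = [
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "beta_exp", "se_exp", "eaf_exp", "n_exp",
    "beta_out", "se_out", "eaf_out", "n_out",
    "action", "palindromic",
]


@dataclass
class HarmonizedDataset:
    """Exposure/outcome associations aligned to a common effect allele."""

    exposure_name: str
    outcome_name: str
    table: pd.DataFrame
    n_dropped_palindromic: int = 0
    n_dropped_unmatched: int = 0
    audit: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        missing = [c for c in HARMONIZED_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"harmonized table missing columns: {missing}")
        self.table = self.table.loc[:, HARMONIZED_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def nsnp(self) -> int:
        return len(self.table)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(beta_exp, se_exp, beta_out, se_out) as float arrays."""
        t = self.table
        return (t["beta_exp"].to_numpy(float), t["se_exp"].to_numpy(float),
                t["beta_out"].to_numpy(float), t["se_out"].to_numpy(float))

    def as_summary_sets(self) -> tuple[SummaryStatSet, SummaryStatSet]:
        """Re-export the harmonized records as two SummaryStatSets."""
        base = self.table[["snp_id", "chrom", "pos", "effect_allele", "other_allele"]]
        exp = base.assign(eaf=self.table["eaf_exp"], beta=self.table["beta_exp"],
                          se=self.table["se_exp"], n=self.table["n_exp"])
        out = base.assign(eaf=self.table["eaf_out"], beta=self.table["beta_out"],
                          se=self.table["se_out"], n=self.table["n_out"])
        z_e = np.abs(exp["beta"] / exp["se"])
        z_o = np.abs(out["beta"] / out["se"])
        from scipy import stats as _st
        exp = exp.assign(pvalue=np.maximum(2 * _st.norm.sf(z_e), 5e-324))
        out = out.assign(pvalue=np.maximum(2 * _st.norm.sf(z_o), 5e-324))
        return (SummaryStatSet(self.exposure_name, "quantitative", exp),
                SummaryStatSet(self.outcome_name, "binary", out))

    def write_audit(self, path: str) -> None:
        if self.audit is not None:
            self.audit.to_csv(path, sep="\t", index=False)


def _is_palindromic(a1: pd.Series, a2: pd.Series) -> pd.Series:
    return ((a1 == "A") & (a2 == "T")) | ((a1 == "T") & (a2 == "A")) | \
           ((a1 == "C") & (a2 == "G")) | ((a1 == "G") & (a2 == "C"))


def harmonize(
    exposure: SummaryStatSet,
    outcome: SummaryStatSet,
    palindrome_eaf_window: float = DEFAULT_PALINDROME_EAF_WINDOW,
) -> HarmonizedDataset:
    """Merge and align outcome associations onto the exposure's allele coding.

    ``palindrome_eaf_window=0.5`` drops every palindromic SNP (the
    conservative alternative when frequencies cannot be trusted).
    """
    if not 0 <= palindrome_eaf_window < 0.5:
        if palindrome_eaf_window == 0.5:
            pass  # drop-all-palindromes convention
        else:
            raise ValueError("palindrome_eaf_window must be in [0, 0.5]")
    if len(exposure) == 0 or len(outcome) == 0:
        raise ValueError("harmonize: empty summary set")

    m = exposure.table.merge(outcome.table, on="snp_id", suffixes=("_exp", "_out"), how="inner")
    if m.empty:
        raise ValueError(
            f"no shared SNPs between {exposure.trait_name!r} and {outcome.trait_name!r}")

    audit_rows = []
    # positional conflicts: same id, different locus
    pos_conflict = (m["chrom_exp"] != m["chrom_out"]) | (m["pos_exp"] != m["pos_out"])
    n_pos_conflict = int(pos_conflict.sum())
    if n_pos_conflict:
        for sid in m.loc[pos_conflict, "snp_id"]:
            audit_rows.append((sid, "dropped", "position_conflict"))
        m = m[~pos_conflict].reset_index(drop=True)

    ea_x, oa_x = m["effect_allele_exp"], m["other_allele_exp"]
    ea_y, oa_y = m["effect_allele_out"], m["other_allele_out"]
    cea_y = ea_y.map(_COMPLEMENT)
    coa_y = oa_y.map(_COMPLEMENT)

    pal = _is_palindromic(ea_x, oa_x)
    same = (ea_y == ea_x) & (oa_y == oa_x)
    swapped = (ea_y == oa_x) & (oa_y == ea_x)
    comp_same = (cea_y == ea_x) & (coa_y == oa_x)
    comp_swapped = (cea_y == oa_x) & (coa_y == ea_x)

    w = palindrome_eaf_window
    eaf_x = m["eaf_exp"].to_numpy(float)
    eaf_y = m["eaf_out"].to_numpy(float)
    beta_y = m["beta_out"].to_numpy(float)

    action = np.full(len(m), "", dtype=object)
    keep = np.zeros(len(m), dtype=bool)
    flip = np.zeros(len(m), dtype=bool)   # negate beta_out, complement eaf_out
    drop_reason = np.full(len(m), "", dtype=object)

    nonpal = ~pal
    keep[nonpal & same] = True
    action[nonpal & same] = ACTION_NONE
    sel = (nonpal & swapped).to_numpy()
    keep[sel], flip[sel] = True, True
    action[sel] = ACTION_FLIPPED
    sel = (nonpal & ~same & ~swapped & comp_same).to_numpy()
    keep[sel] = True
    action[sel] = ACTION_STRAND
    sel = (nonpal & ~same & ~swapped & comp_swapped).to_numpy()
    keep[sel], flip[sel] = True, True
    action[sel] = ACTION_STRAND_FLIPPED
    unmatched = (nonpal & ~same & ~swapped & ~comp_same & ~comp_swapped).to_numpy()
    drop_reason[unmatched] = "incompatible_alleles"

    # palindromic: labels are strand-ambiguous; orient by frequency
    pal_np = pal.to_numpy()
    pal_same_set = (same | swapped).to_numpy() & pal_np
    pal_bad = pal_np & ~pal_same_set
    drop_reason[pal_bad] = "incompatible_alleles"

    with np.errstate(invalid="ignore"):
        informative = (np.abs(eaf_x - 0.5) > w) & (np.abs(eaf_y - 0.5) > w)
    informative &= ~np.isnan(eaf_x) & ~np.isnan(eaf_y)
    pal_amb = pal_same_set & ~informative
    drop_reason[pal_amb] = "palindromic_ambiguous"

    pal_ok = pal_same_set & informative
    # label-implied alignment first (a swap relabels the effect allele)
    lbl_flip = swapped.to_numpy() & pal_ok
    eaf_aligned = np.where(lbl_flip, 1.0 - eaf_y, eaf_y)
    minor_disagree = (eaf_x < 0.5) != (eaf_aligned < 0.5)
    # disagreement after label alignment means an unlabelled strand flip
    flip[pal_ok] = np.logical_xor(lbl_flip, minor_disagree)[pal_ok]
    keep[pal_ok] = True
    action[pal_ok & ~minor_disagree & ~lbl_flip] = ACTION_NONE
    action[pal_ok & ~minor_disagree & lbl_flip] = ACTION_FLIPPED
    action[pal_ok & minor_disagree & ~lbl_flip] = ACTION_STRAND_FLIPPED
    action[pal_ok & minor_disagree & lbl_flip] = ACTION_STRAND

    out = pd.DataFrame({
        "snp_id": m["snp_id"],
        "chrom": m["chrom_exp"].astype(str),
        "pos": m["pos_exp"],
        "effect_allele": ea_x,
        "other_allele": oa_x,
        "beta_exp": m["beta_exp"].astype(float),
        "se_exp": m["se_exp"].astype(float),
        "eaf_exp": eaf_x,
        "n_exp": m["n_exp"],
        "beta_out": np.where(flip, -beta_y, beta_y),
        "se_out": m["se_out"].astype(float),
        "eaf_out": np.where(flip, 1.0 - eaf_y, eaf_y),
        "n_out": m["n_out"],
        "action": action,
        "palindromic": pal_np,
    })

    n_drop_pal = int((drop_reason == "palindromic_ambiguous").sum())
    n_drop_unmatched = int((drop_reason == "incompatible_alleles").sum()) + n_pos_conflict

    for i in np.flatnonzero(~keep):
        audit_rows.append((m["snp_id"].iat[i], "dropped", drop_reason[i]))
    for i in np.flatnonzero(keep):
        audit_rows.append((m["snp_id"].iat[i], "kept", action[i]))
    audit = pd.DataFrame(audit_rows, columns=["snp_id", "status", "detail"])

    kept = out[keep].reset_index(drop=True)
    if n_drop_pal or n_drop_unmatched:
        logger.info("harmonize(%s, %s): kept %d, dropped %d palindromic-ambiguous, %d unmatched",
                    exposure.trait_name, outcome.trait_name, len(kept), n_drop_pal, n_drop_unmatched)
    return HarmonizedDataset(exposure.trait_name, outcome.trait_name, kept,
                             n_dropped_palindromic=n_drop_pal,
                             n_dropped_unmatched=n_drop_unmatched,
                             audit=audit)


def from_arrays(
    beta_exp, se_exp, beta_out, se_out,
    exposure_name: str = "exposure", outcome_name: str = "outcome",
    eaf=None, n_exp: int = 100_000, n_out: int = 100_000,
) -> HarmonizedDataset:
    """Build a HarmonizedDataset directly from effect arrays.

    Convenience constructor for already-aligned effects (simulation studies,
    unit tests, or externally harmonized tables).
    """
    beta_exp = np.asarray(beta_exp, float)
    k = len(beta_exp)
    eaf = np.full(k, 0.25) if eaf is None else np.asarray(eaf, float)
    tbl = pd.DataFrame({
        "snp_id": [f"snp_{i:05d}" for i in range(k)],
        "chrom": "1",
        "pos": np.arange(1, k + 1) * 20_000_000,
        "effect_allele": "A",
        "other_allele": "G",
        "beta_exp": beta_exp, "se_exp": np.asarray(se_exp, float),
        "eaf_exp": eaf, "n_exp": n_exp,
        "beta_out": np.asarray(beta_out, float), "se_out": np.asarray(se_out, float),
        "eaf_out": eaf, "n_out": n_out,
        "action": ACTION_NONE, "palindromic": False,
    })
    return HarmonizedDataset(exposure_name, outcome_name, tbl)
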