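"""Synthetic GWAS summary statistics with known causal ground truth.

The generator emulates the data structure two-sample MR consumes: per-SNP
effect/SE/p/alleles/frequency tables for an exposure, a mediator and an
outcome drawn from the causal diagram

    G_x -> X -> M -> Y,   X -> Y (direct effect theta),
    G_m -> M              (the mediator's own instruments),

so the exposure SNP i has true effects (gamma_i, b2*gamma_i,
(theta + b2*b3)*gamma_i + alpha_i) on X, M, Y, with alpha_i the horizontal-
pleiotropy term, and a mediator SNP j has effects (0, delta_j, b3*delta_j).
Summary statistics are generated directly (no individual-level genotypes):
reported betas are the true effects plus independent normal noise with
SE = 1/sqrt(2 maf (1-maf) n) per trait, the standard large-sample SE of a
per-allele regression coefficient on a standardized trait; samples are
non-overlapping across traits.  Binary outcomes are emulated on the log-OR
scale with the same machinery.

Allele codings can then be corrupted (effect/other swaps, strand
relabelling, palindromic pairs) while the uncorrupted twin tables are kept,
so harmonization can be verified against an exact oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .data import COLUMNS, SummaryStatSet
from .instruments import LdMatrix

_BASES = np.array(list("ACGT"))
_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}
_NONPALINDROMIC_PAIRS = [("A", "C"), ("A", "G"), ("C", "T"), ("G", "T"),
                         ("C", "A"), ("G", "A"), ("T", "C"), ("T", "G")]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass(frozen=True)
class Pleiotropy:
    """Horizontal-pleiotropy model for exposure SNPs.

    kind 'none': alpha_i = 0.  'balanced': alpha_i ~ N(0, sd) (InSIDE holds,
    zero mean).  'directional': alpha_i ~ N(mean, sd).  ``frac`` is the
    fraction of SNPs carrying a pleiotropic path (invalid instruments);
    the remainder get alpha_i = 0.
    """

    kind: Literal["none", "balanced", "directional"] = "none"
    mean: float = 0.0
    sd: float = 0.0
    frac: float = 1.0

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "none":
            return np.zeros(n)
        if self.kind == "balanced":
            alpha = rng.normal(0.0, self.sd, n)
        elif self.kind == "directional":
            alpha = rng.normal(self.mean, self.sd, n)
        else:
            raise ValueError(f"unknown pleiotropy kind {self.kind!r}")
        if self.frac < 1.0:
            invalid = rng.random(n) < self.frac
            alpha = np.where(invalid, alpha, 0.0)
        return alpha


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters of one simulated two-sample MR study.

    Defaults encode the package's reference study conditions: 30 independent
    instruments each explaining 1% of exposure variance in GWAS of 10,000
    individuals per trait, a direct causal effect theta=0.3, an
    exposure->mediator effect b2=0.4 and mediator->outcome effect b3=0.5
    (so 40% of the total effect is mediated), no pleiotropy, minor-allele
    frequencies uniform on (0.05, 0.45), and realistic allele-coding
    discordance between sources (15% palindromic SNPs, 30% swapped
    effect/other coding, 10% strand-relabelled).
    """

    n_snps: int = 30
    n_exp: int = 10_000
    n_med: int = 10_000
    n_out: int = 10_000
    maf_range: tuple[float, float] = (0.05, 0.45)
    exposure_r2_per_snp: float = 0.01
    theta: float = 0.3
    b2: float = 0.4
    b3: float = 0.5
    pleiotropy: Pleiotropy = field(default_factory=Pleiotropy)
    frac_palindromic: float = 0.15
    frac_allele_swapped: float = 0.30
    frac_strand_flipped: float = 0.10
    n_snps_med: int = 0                 # mediator-specific instruments
    mediator_r2_per_snp: float = 0.01
    exposure_name: str = "exposure"
    mediator_name: str = "mediator"
    outcome_name: str = "outcome"
    seed: int = 0

    def __post_init__(self) -> None:
        for frac in (self.frac_palindromic, self.frac_allele_swapped, self.frac_strand_flipped):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("corruption fractions must lie in [0,1]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("maf_range must lie within (0,1)")
        if self.exposure_r2_per_snp * self.n_snps >= 1.0:
            raise ValueError("exposure_r2_per_snp * n_snps >= 1: total variance over-explained")
        if self.n_snps_med and self.mediator_r2_per_snp * self.n_snps_med >= 1.0:
            raise ValueError("mediator_r2_per_snp * n_snps_med >= 1: total variance over-explained")


@dataclass
class SimulatedStudy:
    """Three corrupted summary sets, their uncorrupted twins, and the truth."""

    exposure: SummaryStatSet
    mediator: SummaryStatSet
    outcome: SummaryStatSet
    truth: dict
    uncorrupted: dict = field(default_factory=dict)   # trait name -> SummaryStatSet
    true_effects: pd.DataFrame | None = None          # per-SNP noiseless effects

    def __iter__(self):
        return iter((self.exposure, self.mediator, self.outcome, self.truth))


def _p_from_z(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta / se))
    return np.maximum(p, 5e-324)


def _allele_pairs(n: int, frac_palindromic: float, rng: np.random.Generator):
    pal = rng.random(n) < frac_palindromic
    ea = np.empty(n, dtype=object)
    oa = np.empty(n, dtype=object)
    for i in range(n):
        pool = _PALINDROMIC_PAIRS if pal[i] else _NONPALINDROMIC_PAIRS
        ea[i], oa[i] = pool[rng.integers(len(pool))]
    return ea, oa, pal


def _trait_table(ids, chrom, pos, ea, oa, eaf, true_beta, n, rng) -> pd.DataFrame:
    se = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * n)
    beta = true_beta + rng.normal(0.0, se)
    return pd.DataFrame({
        "snp_id": ids, "chrom": chrom, "pos": pos,
        "effect_allele": ea, "other_allele": oa, "eaf": eaf,
        "beta": beta, "se": se, "pvalue": _p_from_z(beta, se),
        "n": np.full(len(ids), n, dtype=np.int64),
    }, columns=COLUMNS)


def _corrupt(table: pd.DataFrame, frac_swapped: float, frac_flipped: float,
             rng: np.random.Generator) -> pd.DataFrame:
    """Swap effect/other coding and/or relabel the strand on random rows.

    Both operations report the same underlying association differently, so a
    correct harmonization must undo them exactly.
    """
    t = table.copy()
    swap = rng.random(len(t)) < frac_swapped
    flip = rng.random(len(t)) < frac_flipped
    ea = t["effect_allele"].to_numpy(object).copy()
    oa = t["other_allele"].to_numpy(object).copy()
    ea[swap], oa[swap] = oa[swap], ea[swap].copy()
    t.loc[swap, "beta"] = -t.loc[swap, "beta"]
    t.loc[swap, "eaf"] = 1.0 - t.loc[swap, "eaf"]
    ea[flip] = [_COMP[a] for a in ea[flip]]
    oa[flip] = [_COMP[a] for a in oa[flip]]
    t["effect_allele"] = ea
    t["other_allele"] = oa
    return t


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate exposure, mediator and outcome GWAS summary statistics.

    SNPs are truly independent (spaced 20 Mb apart across 22 chromosomes,
    far beyond any clumping window) so instrument selection is exactly
    testable without an LD reference.  Returns corrupted mediator/outcome
    tables plus their uncorrupted twins and the ground truth
    ``{theta_total, theta_direct, b2, b3, proportion_mediated}``.
    """
    c = config
    rng = np.random.default_rng(c.seed)
    n_tot = c.n_snps + c.n_snps_med

    ids = np.array([f"rs{900000 + i}" for i in range(n_tot)])
    chrom = np.array([str(1 + i % 22) for i in range(n_tot)])
    pos = np.array([1 + (i // 22) * 20_000_000 + i for i in range(n_tot)], dtype=np.int64)
    ea, oa, _ = _allele_pairs(n_tot, c.frac_palindromic, rng)
    maf = rng.uniform(c.maf_range[0], c.maf_range[1], n_tot)

    # exposure SNPs: gamma scaled so per-SNP R^2 on the standardized scale
    # equals exposure_r2_per_snp: R^2 = 2 maf (1-maf) gamma^2
    het = 2.0 * maf * (1.0 - maf)
    sign = rng.choice([-1.0, 1.0], n_tot)
    gamma = np.zeros(n_tot)
    gamma[: c.n_snps] = sign[: c.n_snps] * np.sqrt(c.exposure_r2_per_snp / het[: c.n_snps])
    delta = np.zeros(n_tot)
    if c.n_snps_med:
        delta[c.n_snps:] = sign[c.n_snps:] * np.sqrt(c.mediator_r2_per_snp / het[c.n_snps:])

    # pleiotropy is defined in the exposure-increasing allele orientation
    # (the convention the Egger intercept estimates); re-expressed on the
    # arbitrary reported coding it carries the sign of gamma
    alpha = np.zeros(n_tot)
    alpha[: c.n_snps] = sign[: c.n_snps] * c.pleiotropy.draw(c.n_snps, rng)

    true_exp = gamma
    true_med = c.b2 * gamma + delta
    true_out = (c.theta + c.b2 * c.b3) * gamma + c.b3 * delta + alpha

    exp_t = _trait_table(ids, chrom, pos, ea, oa, maf, true_exp, c.n_exp, rng)
    med_t = _trait_table(ids, chrom, pos, ea, oa, maf, true_med, c.n_med, rng)
    out_t = _trait_table(ids, chrom, pos, ea, oa, maf, true_out, c.n_out, rng)

    med_c = _corrupt(med_t, c.frac_allele_swapped, c.frac_strand_flipped, rng)
    out_c = _corrupt(out_t, c.frac_allele_swapped, c.frac_strand_flipped, rng)

    theta_total = c.theta + c.b2 * c.b3
    truth = {
        "theta_total": theta_total,
        "theta_direct": c.theta,
        "b2": c.b2,
        "b3": c.b3,
        "proportion_mediated": (c.b2 * c.b3 / theta_total) if theta_total != 0 else float("nan"),
    }
    true_effects = pd.DataFrame({
        "snp_id": ids, "chrom": chrom, "pos": pos,
        "effect_allele": ea, "other_allele": oa, "eaf": maf,
        "true_exp": true_exp, "true_med": true_med, "true_out": true_out,
    })
    return SimulatedStudy(
        exposure=SummaryStatSet(c.exposure_name, "quantitative", exp_t),
        mediator=SummaryStatSet(c.mediator_name, "binary", med_c),
        outcome=SummaryStatSet(c.outcome_name, "binary", out_c),
        truth=truth,
        uncorrupted={
            c.mediator_name: SummaryStatSet(c.mediator_name, "binary", med_t),
            c.outcome_name: SummaryStatSet(c.outcome_name, "binary", out_t),
        },
        true_effects=true_effects,
    )


def resample_outcome(study: SimulatedStudy, n_out: int, seed: int,
                     name: str | None = None) -> SummaryStatSet:
    """An independent outcome cohort: same variants and true effects as
    ``study``, fresh sampling noise (the replication-cohort model)."""
    te = study.true_effects
    if te is None:
        raise ValueError("study carries no true-effect table")
    rng = np.random.default_rng(seed)
    tbl = _trait_table(te["snp_id"].to_numpy(), te["chrom"].to_numpy(),
                       te["pos"].to_numpy(), te["effect_allele"].to_numpy(),
                       te["other_allele"].to_numpy(), te["eaf"].to_numpy(float),
                       te["true_out"].to_numpy(float), n_out, rng)
    return SummaryStatSet(name or (study.outcome.trait_name + "_replication"),
                          "binary", tbl)


def simulate_panel(
    n_exposures: int,
    base_config: SimulationConfig,
    causal: dict[int, float] | None = None,
    replication: bool = False,
    seed: int = 0,
) -> tuple[dict[str, SummaryStatSet], SummaryStatSet, SummaryStatSet | None, dict]:
    """A panel of exposures sharing one outcome GWAS (the screening layout).

    Each exposure gets its own independent SNP set; the single outcome table
    is the union of all per-exposure outcome rows, as in a real outcome GWAS
    covering every instrument.  ``causal`` maps exposure index -> total
    causal effect (others are null).  With ``replication`` a second outcome
    cohort with independent noise (same true effects) is also returned.

    Returns (exposures, outcome, replication_outcome_or_None, truth_by_name).
    """
    causal = causal or {}
    rng = np.random.default_rng(seed)
    exposures: dict[str, SummaryStatSet] = {}
    out_parts, rep_parts = [], []
    truth: dict[str, float] = {}
    for i in range(n_exposures):
        name = f"exposure_{i:03d}"
        theta = float(causal.get(i, 0.0))
        cfg = replace(base_config, theta=theta, b2=0.0, b3=0.0,
                      exposure_name=name, seed=int(rng.integers(2**31 - 1)))
        study = simulate_study(cfg)
        # distinct ids per exposure so the shared outcome GWAS is well formed
        for s in (study.exposure, study.outcome):
            s.table["snp_id"] = [f"{sid}_{i:03d}" for sid in s.table["snp_id"]]
        exposures[name] = study.exposure
        out_parts.append(study.outcome.table)
        truth[name] = theta
        if replication:
            rep = resample_outcome(study, base_config.n_out, int(rng.integers(2**31 - 1)))
            rep.table["snp_id"] = [f"{sid}_{i:03d}" for sid in rep.table["snp_id"]]
            rep_parts.append(rep.table)
    outcome = SummaryStatSet(base_config.outcome_name, "binary",
                             pd.concat(out_parts, ignore_index=True))
    rep_out = None
    if replication:
        rep_out = SummaryStatSet(base_config.outcome_name + "_replication", "binary",
                                 pd.concat(rep_parts, ignore_index=True))
    return exposures, outcome, rep_out, truth


def simulate_ld_block(n_snps: int, r2_profile, seed: int = 0,
                      snp_ids: list[str] | None = None) -> LdMatrix:
    """Build an LdMatrix from a pairwise r^2 specification.

    ``r2_profile`` is either a full (n,n) array or a mapping
    ``{(i,j): r2}`` of off-diagonal entries (symmetrized; unspecified pairs
    are 0).  The seed names default SNP ids reproducibly.
    """
    if snp_ids is None:
        snp_ids = [f"rs{900000 + i}" for i in range(n_snps)]
    if len(snp_ids) != n_snps:
        raise ValueError("snp_ids length does not match n_snps")
    if isinstance(r2_profile, dict):
        r2 = np.zeros((n_snps, n_snps))
        for (i, j), v in r2_profile.items():
            if not (0 <= i < n_snps and 0 <= j < n_snps):
                raise ValueError(f"r2_profile index ({i},{j}) out of range")
            r2[i, j] = r2[j, i] = v
        np.fill_diagonal(r2, 1.0)
    else:
        r2 = np.asarray(r2_profile, dtype=float)
        if r2.shape != (n_snps, n_snps):
            raise ValueError(f"r2_profile shape {r2.shape} does not match n_snps={n_snps}")
    if np.any(r2 < 0) or np.any(r2 > 1):
        raise ValueError("r2 values must lie in [0,1]")
    return LdMatrix(snp_ids, r2)
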