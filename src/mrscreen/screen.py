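"""Multi-exposure MR screening with replication and mediation stages.

The pipeline mirrors a discovery/replication screening design: for every
exposure, instruments are selected and harmonized with the outcome, the
causal effect is estimated (Wald ratio for a single instrument, IVW with a
heterogeneity-driven fixed/random switch otherwise) and sensitivity
diagnostics are computed where the SNP count permits.  Exposures passing
the Bonferroni threshold are re-tested in an independent outcome cohort at
``alpha / n_hits`` with a same-direction requirement, and surviving hits
enter two-step mediation MR against a supplied mediator GWAS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

from .data import SummaryStatSet
from .harmonize import DEFAULT_PALINDROME_EAF_WINDOW, harmonize
from .instruments import (DEFAULT_CLUMP_KB, DEFAULT_CLUMP_R2,
                          DEFAULT_P_THRESHOLD, LdMatrix, select_instruments)
from .mediation import MediationResult, two_step_mediation
from .model import MRModel, MRResult
from .sensitivity import SensitivityReport, sensitivity_report

logger = logging.getLogger(__name__)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance threshold alpha/m."""
    if m < 1:
        raise ValueError(f"bonferroni_threshold: m must be >= 1, got {m}")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0,1)")
    return alpha / m


@dataclass
class ScreenConfig:
    """Parameters driving one screening run.

    ``m_nominal`` is the nominal panel size used as the Bonferroni
    denominator (the study-design convention: divide by the full panel even
    when fewer exposures are analyzable); when None the number of analyzable
    exposures (``m_tested``) is used instead.
    """

    alpha: float = 0.05
    p_threshold: float = DEFAULT_P_THRESHOLD
    clump_r2: float = DEFAULT_CLUMP_R2
    clump_kb: int = DEFAULT_CLUMP_KB
    palindrome_eaf_window: float = DEFAULT_PALINDROME_EAF_WINDOW
    m_nominal: int | None = None
    n_boot: int = 0                    # bootstrap draws for median/mode SEs
    seed: int = 0
    # file-based runs (CLI): paths resolved by run_screen_files
    exposure_paths: list[str] = field(default_factory=list)
    outcome_path: str | None = None
    replication_outcome_path: str | None = None
    mediator_path: str | None = None
    dialect: str = "generic"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0,1)")


@dataclass
class ExposureResult:
    """Per-exposure outcome of the discovery stage."""

    exposure: str
    status: str                        # "ok" | "no_instruments" | "no_shared_snps" | "weak_flagged"
    primary: MRResult | None = None
    sensitivity: SensitivityReport | None = None
    nsnp: int = 0
    f_statistic: float = float("nan")
    notes: str = ""


@dataclass
class ScreenReport:
    """Everything one screening run produced."""

    results: dict[str, ExposureResult]
    m_tested: int
    bonferroni: float
    hits: list[str]
    replication: dict[str, dict] = field(default_factory=dict)
    mediation: dict[str, MediationResult] = field(default_factory=dict)
    manifest: list[str] = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            f"Screened {len(self.results)} exposures; {self.m_tested} analyzable",
            f"Bonferroni threshold: {self.bonferroni:.3g}",
            f"Hits ({len(self.hits)}): {', '.join(self.hits) or '-'}",
        ]
        for name, rep in self.replication.items():
            lines.append(
                f"  {name}: replicated={rep['replicated']} "
                f"direction_consistent={rep['direction_consistent']} p={rep['pvalue']:.3g}")
        for name, med in self.mediation.items():
            lines.append(f"  {name}: proportion mediated = {med.proportion_mediated:.3g}")
        return "\n".join(lines)


def analyze_exposure(
    exposure: SummaryStatSet,
    outcome: SummaryStatSet,
    config: ScreenConfig,
    ld: LdMatrix | None = None,
) -> ExposureResult:
    """Instrument selection -> harmonization -> estimation -> diagnostics
    for a single exposure/outcome pair."""
    inst = select_instruments(exposure, config.p_threshold, config.clump_r2,
                              config.clump_kb, ld)
    if inst.no_instruments:
        return ExposureResult(exposure.trait_name, "no_instruments",
                              notes="no SNP passed the p threshold")
    inst_set = SummaryStatSet(exposure.trait_name, exposure.trait_type, inst.table)
    try:
        ds = harmonize(inst_set, outcome, config.palindrome_eaf_window)
    except ValueError as exc:
        return ExposureResult(exposure.trait_name, "no_shared_snps", notes=str(exc))
    if ds.nsnp == 0:
        return ExposureResult(exposure.trait_name, "no_shared_snps",
                              notes="all shared SNPs dropped at harmonization")
    model = MRModel(ds)
    if ds.nsnp == 1:
        primary = model.fit(method="wald_ratio")
        sens = None
    else:
        primary = model.fit(method="ivw", effects_model="auto")
        sens = sensitivity_report(ds)
    notes = f"F={inst.f_statistic:.1f}" + (" (weak, F<10)" if inst.weak else "")
    return ExposureResult(exposure.trait_name,
                          "weak_flagged" if inst.weak else "ok",
                          primary=primary, sensitivity=sens, nsnp=ds.nsnp,
                          f_statistic=inst.f_statistic, notes=notes)


def run_screen(
    exposures: Mapping[str, SummaryStatSet],
    outcome: SummaryStatSet,
    config: ScreenConfig | None = None,
    replication_outcome: SummaryStatSet | None = None,
    mediator: SummaryStatSet | None = None,
    ld: LdMatrix | None = None,
) -> ScreenReport:
    """Run the full screen -> replicate -> mediate workflow.

    ``m_tested`` counts exposures with at least one instrument shared with
    the outcome; the Bonferroni denominator is ``config.m_nominal`` when
    given (nominal-panel convention), else ``m_tested``.  The run is a pure
    function of its inputs and config (seed included), so reports are
    reproducible.
    """
    config = config or ScreenConfig()
    if not exposures:
        raise ValueError("run_screen: no exposures supplied")
    manifest = [f"screen: {len(exposures)} exposures vs {outcome.trait_name}"]
    results: dict[str, ExposureResult] = {}
    for name in sorted(exposures):
        res = analyze_exposure(exposures[name], outcome, config, ld)
        results[name] = res
        manifest.append(
            f"  {name}: status={res.status} nsnp={res.nsnp} "
            + (f"method={res.primary.method} beta={res.primary.beta:.4g} p={res.primary.pvalue:.3g}"
               if res.primary else res.notes))
    analyzable = [n for n, r in results.items() if r.primary is not None]
    m_tested = len(analyzable)
    if m_tested == 0:
        diag = "; ".join(f"{n}: {r.status}" for n, r in results.items())
        raise ValueError(f"run_screen: no exposure yielded instruments ({diag})")
    m = config.m_nominal if config.m_nominal is not None else m_tested
    thr = bonferroni_threshold(config.alpha, m)
    hits = [n for n in analyzable if results[n].primary.pvalue < thr]
    manifest.append(f"m_tested={m_tested} bonferroni={thr:.3g} hits={len(hits)}")

    replication: dict[str, dict] = {}
    if replication_outcome is not None and hits:
        rep_thr = bonferroni_threshold(config.alpha, len(hits))
        for name in hits:
            rep = analyze_exposure(exposures[name], replication_outcome, config, ld)
            if rep.primary is None:
                replication[name] = {"replicated": False, "direction_consistent": False,
                                     "pvalue": float("nan"), "beta": float("nan"),
                                     "note": rep.status}
                continue
            same_dir = (rep.primary.beta > 0) == (results[name].primary.beta > 0)
            replication[name] = {
                "replicated": bool(rep.primary.pvalue < rep_thr and same_dir),
                "direction_consistent": bool(same_dir),
                "pvalue": rep.primary.pvalue, "beta": rep.primary.beta,
            }
            manifest.append(f"  replication {name}: p={rep.primary.pvalue:.3g} "
                            f"same_direction={same_dir} threshold={rep_thr:.3g}")

    mediation: dict[str, MediationResult] = {}
    if mediator is not None and hits:
        surviving = [n for n in hits
                     if not replication or replication.get(n, {}).get("replicated")]
        step2_res = analyze_exposure(mediator, outcome, config, ld)
        for name in surviving:
            step1_res = analyze_exposure(exposures[name], mediator, config, ld)
            if step1_res.primary is None or step2_res.primary is None:
                manifest.append(f"  mediation {name}: skipped "
                                f"(step1={step1_res.status}, step2={step2_res.status})")
                continue
            med = two_step_mediation(results[name].primary, step1_res.primary,
                                     step2_res.primary)
            mediation[name] = med
            manifest.append(f"  mediation {name}: proportion={med.proportion_mediated:.3g}"
                            + (f" [{med.proportion_flag}]" if med.proportion_flag else ""))

    return ScreenReport(results, m_tested, thr, hits, replication, mediation, manifest)


def run_screen_files(config: ScreenConfig, ld: LdMatrix | None = None) -> ScreenReport:
    """File-based entry point used by the CLI: loads every table named in
    the config, then delegates to :func:`run_screen`."""
    from .data import read_summary_stats

    if not config.exposure_paths or config.outcome_path is None:
        raise ValueError("config must name exposure_paths and outcome_path")
    exposures = {}
    for path in config.exposure_paths:
        s = read_summary_stats(path, dialect=config.dialect)
        exposures[s.trait_name] = s
    outcome = read_summary_stats(config.outcome_path, dialect=config.dialect,
                                 trait_type="binary")
    rep = (read_summary_stats(config.replication_outcome_path, dialect=config.dialect,
                              trait_type="binary")
           if config.replication_outcome_path else None)
    med = (read_summary_stats(config.mediator_path, dialect=config.dialect,
                              trait_type="binary")
           if config.mediator_path else None)
    return run_screen(exposures, outcome, config, rep, med, ld)
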