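"""Replicated simulation experiments validating the estimator suite.

These are the package's reference study conditions: independent instruments
each explaining 1% of exposure variance in GWAS of n=10,000, analysed with
the full pipeline (generation -> harmonization -> estimation).  Each
function runs a seeded replicate loop and returns summary statistics
(means, Monte-Carlo standard errors sd/sqrt(R), rates); they back both the
test suite and the reproducibility script.
"""

from __future__ import annotations

import numpy as np

from .harmonize import harmonize
from .model import MRModel
from .sensitivity import steiger_test
from .simulate import Pleiotropy, SimulationConfig, simulate_study

#: corruption-free study conditions (harmonization is exercised separately)
_CLEAN = dict(frac_palindromic=0.0, frac_allele_swapped=0.0, frac_strand_flipped=0.0)


def _seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2**31 - 1)


def _dataset(theta: float, n_snps: int, seed: int,
             pleiotropy: Pleiotropy | None = None,
             exposure_r2_per_snp: float = 0.01, n: int = 10_000):
    cfg = SimulationConfig(n_snps=n_snps, n_exp=n, n_out=n, theta=theta,
                           b2=0.0, b3=0.0,
                           exposure_r2_per_snp=exposure_r2_per_snp,
                           pleiotropy=pleiotropy or Pleiotropy(),
                           seed=seed, **_CLEAN)
    study = simulate_study(cfg)
    return harmonize(study.exposure, study.outcome)


def mc_se(values: np.ndarray) -> float:
    """Monte-Carlo standard error of the replicate mean."""
    return float(np.std(values, ddof=1) / np.sqrt(len(values)))


def estimator_recovery(n_reps: int = 1000, seed: int = 0, theta: float = 0.3,
                       n_snps: int = 30) -> dict:
    """Bias and IVW CI coverage for the five-method panel under valid
    instruments (no pleiotropy)."""
    methods = ["ivw", "weighted_median", "egger", "simple_mode", "weighted_mode"]
    est = {m: np.empty(n_reps) for m in methods}
    covered = np.empty(n_reps, dtype=bool)
    for i, s in enumerate(_seeds(seed, n_reps)):
        ds = _dataset(theta, n_snps, int(s))
        model = MRModel(ds)
        r_ivw = model.fit(method="ivw", effects_model="fixed")
        est["ivw"][i] = r_ivw.beta
        covered[i] = r_ivw.ci_low <= theta <= r_ivw.ci_high
        est["weighted_median"][i] = model.fit(method="weighted_median", n_boot=0).beta
        est["egger"][i] = model.fit(method="egger").beta
        sm_, wm_ = model.mode_estimators(n_boot=0)
        est["simple_mode"][i] = sm_.beta
        est["weighted_mode"][i] = wm_.beta
    out = {"theta": theta, "n_reps": n_reps,
           "ivw_coverage": float(np.mean(covered))}
    for m in methods:
        out[m] = {"mean": float(np.mean(est[m])), "mc_se": mc_se(est[m]),
                  "bias": float(np.mean(est[m]) - theta)}
    return out


def ivw_type1_error(n_reps: int = 1000, seed: int = 0, n_snps: int = 30,
                    alpha: float = 0.05) -> dict:
    """Fixed-effects IVW rejection rate under the causal null."""
    rej = np.empty(n_reps, dtype=bool)
    for i, s in enumerate(_seeds(seed, n_reps)):
        ds = _dataset(0.0, n_snps, int(s))
        rej[i] = MRModel(ds).fit(method="ivw", effects_model="fixed").pvalue < alpha
    return {"rate": float(np.mean(rej)), "n_reps": n_reps, "alpha": alpha}


def egger_pleiotropy_detection(n_reps: int = 500, seed: int = 0,
                               n_snps: int = 50, mean: float = 0.02,
                               sd: float | None = None,
                               theta: float = 0.3) -> dict:
    """Directional pleiotropy: Egger intercept recovery and test power.

    ``sd`` defaults to mean/4 (concentrated directional bias).
    """
    sd = mean / 4 if sd is None else sd
    plei = Pleiotropy("directional", mean=mean, sd=sd)
    inter = np.empty(n_reps)
    covered = np.empty(n_reps, dtype=bool)
    reject = np.empty(n_reps, dtype=bool)
    from .model import Z_95

    for i, s in enumerate(_seeds(seed, n_reps)):
        ds = _dataset(theta, n_snps, int(s), pleiotropy=plei)
        res = MRModel(ds).fit(method="egger")
        a, a_se = res.extra["egger_intercept"], res.extra["egger_intercept_se"]
        inter[i] = a
        covered[i] = (a - Z_95 * a_se) <= mean <= (a + Z_95 * a_se)
        reject[i] = res.extra["egger_intercept_pvalue"] < 0.05
    return {"true_intercept": mean, "intercept_mean": float(np.mean(inter)),
            "intercept_mc_se": mc_se(inter),
            "intercept_ci_coverage": float(np.mean(covered)),
            "power": float(np.mean(reject)), "n_reps": n_reps}


def egger_intercept_type1(n_reps: int = 500, seed: int = 0, n_snps: int = 50,
                          sd: float = 0.02, theta: float = 0.3) -> dict:
    """Balanced pleiotropy: false-positive rate of the intercept test."""
    plei = Pleiotropy("balanced", sd=sd)
    reject = np.empty(n_reps, dtype=bool)
    for i, s in enumerate(_seeds(seed, n_reps)):
        ds = _dataset(theta, n_snps, int(s), pleiotropy=plei)
        res = MRModel(ds).fit(method="egger")
        reject[i] = res.extra["egger_intercept_pvalue"] < 0.05
    return {"rate": float(np.mean(reject)), "n_reps": n_reps}


def weighted_median_robustness(n_reps: int = 500, seed: int = 0,
                               n_snps: int = 30, theta: float = 0.3,
                               frac_invalid: float = 0.4,
                               pleiotropy_mean: float = 0.1) -> dict:
    """40% invalid instruments with directional pleiotropy: how often is the
    weighted median closer to the truth than IVW?"""
    plei = Pleiotropy("directional", mean=pleiotropy_mean,
                      sd=pleiotropy_mean / 4, frac=frac_invalid)
    wins = np.empty(n_reps, dtype=bool)
    for i, s in enumerate(_seeds(seed, n_reps)):
        ds = _dataset(theta, n_snps, int(s), pleiotropy=plei)
        model = MRModel(ds)
        b_ivw = model.fit(method="ivw", effects_model="fixed").beta
        b_wm = model.fit(method="weighted_median", n_boot=0).beta
        wins[i] = abs(b_wm - theta) < abs(b_ivw - theta)
    return {"wm_beats_ivw": float(np.mean(wins)), "n_reps": n_reps}


def steiger_direction_rate(n_reps: int = 500, seed: int = 0,
                           n_snps: int = 5, theta: float = 0.3) -> dict:
    """Fraction of replicates with the correct inferred causal direction
    (outcome R^2 is ~theta^2 of exposure R^2, ~11x smaller at theta=0.3)."""
    ok = np.empty(n_reps, dtype=bool)
    for i, s in enumerate(_seeds(seed, n_reps)):
        ds = _dataset(theta, n_snps, int(s))
        ok[i] = steiger_test(ds)[0]
    return {"rate": float(np.mean(ok)), "n_reps": n_reps}


def mediation_recovery(n_reps: int = 300, seed: int = 0, theta: float = 0.3,
                       b2: float = 0.4, b3: float = 0.5,
                       n_snps: int = 30, n_snps_med: int = 30) -> dict:
    """Two-step mediation on a full X -> M -> Y chain with mediator-specific
    instruments; truth: proportion mediated b2*b3/(theta + b2*b3)."""
    from .mediation import two_step_mediation
    from .screen import ScreenConfig, analyze_exposure

    cfg_screen = ScreenConfig()
    props = np.empty(n_reps)
    for i, s in enumerate(_seeds(seed, n_reps)):
        cfg = SimulationConfig(n_snps=n_snps, n_snps_med=n_snps_med,
                               theta=theta, b2=b2, b3=b3, seed=int(s), **_CLEAN)
        study = simulate_study(cfg)
        total = analyze_exposure(study.exposure, study.outcome, cfg_screen).primary
        step1 = analyze_exposure(study.exposure, study.mediator, cfg_screen).primary
        step2 = analyze_exposure(study.mediator, study.outcome, cfg_screen).primary
        props[i] = two_step_mediation(total, step1, step2).proportion_mediated
    truth = b2 * b3 / (theta + b2 * b3)
    return {"truth": truth, "proportion_mean": float(np.mean(props)),
            "proportion_mc_se": mc_se(props), "n_reps": n_reps}
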