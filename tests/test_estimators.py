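"""MR estimators: closed-form examples, independent oracles, invariances."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from mrscreen.model import (MRModel, Z_95, egger, ivw, mode_estimators,
                            wald_ratio, weighted_median)

from conftest import make_harmonized


def _random_instance(rng, k):
    bx = rng.normal(0.2, 0.08, k)
    bx[np.abs(bx) < 0.02] = 0.05
    by = rng.normal(0.3 * bx, 0.05)
    sx = rng.uniform(0.005, 0.02, k)
    sy = rng.uniform(0.02, 0.08, k)
    return make_harmonized(bx, by, sx, sy)


# ------------------------------------------------------------------- Wald

def test_wald_ratio_direct_arithmetic():
    ds = make_harmonized([0.5], [0.25], [0.01], [0.1])
    res = wald_ratio(ds)
    assert res.beta == pytest.approx(0.5, abs=1e-12)
    assert res.se == pytest.approx(0.2, abs=1e-12)
    assert res.nsnp == 1


def test_wald_ratio_null_outcome():
    res = wald_ratio(make_harmonized([0.5], [0.0], [0.01], [0.1]))
    assert res.beta == 0.0 and res.pvalue == 1.0


def test_wald_ratio_joint_sign_flip_invariant():
    a = wald_ratio(make_harmonized([0.5], [0.25], [0.01], [0.1]))
    b = wald_ratio(make_harmonized([-0.5], [-0.25], [0.01], [0.1]))
    assert a.beta == b.beta and a.se == b.se


def test_wald_ratio_zero_exposure_is_error():
    with pytest.raises(ValueError, match="ratio"):
        wald_ratio(make_harmonized([0.0], [0.25], [0.01], [0.1]))


# -------------------------------------------------------------------- IVW

def test_ivw_single_snp_reduces_to_wald():
    ds = make_harmonized([0.4], [0.3], [0.01], [0.06])
    a, b = ivw(ds), wald_ratio(ds)
    assert a.beta == pytest.approx(b.beta, abs=1e-12)
    assert a.se == pytest.approx(b.se, abs=1e-12)


def test_ivw_duplicate_snp_halves_variance():
    one = make_harmonized([0.4], [0.3], [0.01], [0.06])
    two = make_harmonized([0.4, 0.4], [0.3, 0.3], [0.01, 0.01], [0.06, 0.06])
    r1, r2 = ivw(one), ivw(two)
    assert r2.beta == pytest.approx(r1.beta, abs=1e-12)
    assert r2.se == pytest.approx(r1.se / np.sqrt(2), abs=1e-12)


@pytest.mark.parametrize("seed", [1, 2, 3])
def test_ivw_equals_weighted_least_squares_oracle(rng, seed):
    ds = _random_instance(np.random.default_rng(seed), 6)
    bx, _, by, sy = ds.arrays()
    fit = sm.WLS(by, bx[:, None], weights=1.0 / sy**2).fit()
    res = ivw(ds, effects_model="fixed")
    assert res.beta == pytest.approx(fit.params[0], abs=1e-9)
    # fixed-effect SE uses unit dispersion: rescale the WLS scale out
    se_unit = fit.bse[0] / np.sqrt(fit.scale)
    assert res.se == pytest.approx(se_unit, abs=1e-9)


def test_ivw_random_effects_floor_at_fixed():
    # homogeneous data: Q < df, multiplicative inflation floors at 1
    ds = make_harmonized([0.2, 0.3, 0.25], [0.10, 0.15, 0.125],
                         [0.01] * 3, [0.05] * 3)
    assert ivw(ds, "random").se == pytest.approx(ivw(ds, "fixed").se, abs=1e-12)


def test_ivw_random_effects_inflates_under_heterogeneity(rng):
    bx = rng.normal(0.25, 0.05, 10)
    by = 0.3 * bx + rng.normal(0, 0.3, 10)   # gross heterogeneity vs se=0.05
    ds = make_harmonized(bx, by, np.full(10, 0.01), np.full(10, 0.05))
    rf, rr = ivw(ds, "fixed"), ivw(ds, "random")
    q, df = rr.extra["q"], rr.extra["q_df"]
    assert q > df
    assert rr.se == pytest.approx(rf.se * np.sqrt(q / df), abs=1e-9)
    assert rr.beta == rf.beta


# ------------------------------------------------------------------ Egger

def test_egger_recovers_exact_line_through_origin():
    bx = np.array([0.1, 0.2, 0.3, 0.4])
    ds = make_harmonized(bx, 0.7 * bx, np.full(4, 0.01), np.full(4, 0.05))
    res = egger(ds)
    assert res.beta == pytest.approx(0.7, abs=1e-9)
    assert res.extra["egger_intercept"] == pytest.approx(0.0, abs=1e-9)


def test_egger_recovers_exact_affine_line():
    bx = np.array([0.1, 0.2, 0.3, 0.4])
    ds = make_harmonized(bx, 0.05 + 0.7 * bx, np.full(4, 0.01), np.full(4, 0.05))
    res = egger(ds)
    assert res.beta == pytest.approx(0.7, abs=1e-9)
    assert res.extra["egger_intercept"] == pytest.approx(0.05, abs=1e-9)


@pytest.mark.parametrize("seed", [4, 5, 6])
def test_egger_equals_weighted_regression_oracle(seed):
    ds = _random_instance(np.random.default_rng(seed), 8)
    bx, _, by, sy = ds.arrays()
    sign = np.where(bx < 0, -1.0, 1.0)
    X = sm.add_constant(sign * bx)
    fit = sm.WLS(sign * by, X, weights=1.0 / sy**2).fit()
    res = egger(ds)
    assert res.beta == pytest.approx(fit.params[1], abs=1e-9)
    assert res.extra["egger_intercept"] == pytest.approx(fit.params[0], abs=1e-9)
    # SEs match after applying the dispersion floor at 1
    adj = np.sqrt(max(1.0, fit.scale) / fit.scale)
    assert res.se == pytest.approx(fit.bse[1] * adj, abs=1e-9)
    assert res.extra["egger_intercept_se"] == pytest.approx(fit.bse[0] * adj, abs=1e-9)


def test_egger_below_three_snps_is_structured_na():
    res = egger(make_harmonized([0.2, 0.3], [0.1, 0.15]))
    assert res.status == "not_applicable" and np.isnan(res.beta)


# -------------------------------------------------------- weighted median

def _wm_oracle(ratios, weights):
    """Brute-force cumulative-weight scan over sorted ratios."""
    order = np.argsort(ratios)
    b, w = np.asarray(ratios)[order], np.asarray(weights)[order]
    w = w / w.sum()
    cum = np.cumsum(w) - 0.5 * w
    if cum[0] >= 0.5:
        return b[0]
    if cum[-1] < 0.5:
        return b[-1]
    for i in range(len(b) - 1):
        if cum[i] <= 0.5 <= cum[i + 1]:
            return b[i] + (b[i + 1] - b[i]) * (0.5 - cum[i]) / (cum[i + 1] - cum[i])
    raise AssertionError


def test_weighted_median_symmetric_equal_weights():
    bx = np.ones(3)
    by = np.array([0.1, 0.5, 0.9])
    ds = make_harmonized(bx, by, np.full(3, 0.01), np.full(3, 0.05))
    res = weighted_median(ds, n_boot=0)
    assert res.beta == pytest.approx(0.5, abs=1e-12)


def test_weighted_median_degenerate_identical_ratios():
    ds = make_harmonized([0.2, 0.4, 0.3], [0.1, 0.2, 0.15],
                         [0.01] * 3, [0.05, 0.05, 0.05])
    res = weighted_median(ds, n_boot=400, seed=11)
    assert res.beta == pytest.approx(0.5, abs=1e-12)
    assert 0 < res.se < 1


def test_weighted_median_matches_bruteforce_scan(rng):
    for _ in range(25):
        k = int(rng.integers(3, 9))
        ds = _random_instance(rng, k)
        bx, _, by, sy = ds.arrays()
        ratios = by / bx
        weights = bx**2 / sy**2
        res = weighted_median(ds, n_boot=0)
        assert res.beta == pytest.approx(_wm_oracle(ratios, weights), abs=1e-12)


def test_weighted_median_below_three_snps_is_na():
    assert weighted_median(make_harmonized([0.2], [0.1]), n_boot=0).status == "not_applicable"


# ------------------------------------------------------------------ modes

def test_mode_majority_cluster():
    ds = make_harmonized(np.ones(4), [0.5, 0.5, 0.5, 5.0],
                         np.full(4, 0.01), np.full(4, 0.05))
    simple, weighted = mode_estimators(ds, n_boot=0)
    assert simple.beta == pytest.approx(0.5, abs=1e-6)
    assert weighted.beta == pytest.approx(0.5, abs=1e-6)


def test_mode_symmetric_tie_breaks_to_smaller_ratio():
    # a narrow bandwidth keeps the two equal clusters bimodal; the
    # documented tie rule picks the smaller one
    ds = make_harmonized(np.ones(4), [0.2, 0.2, 0.8, 0.8],
                         np.full(4, 0.01), np.full(4, 0.05))
    simple, _ = mode_estimators(ds, bandwidth_factor=0.2, n_boot=0)
    assert simple.beta == pytest.approx(0.2, abs=0.02)


def test_weighted_mode_follows_the_weighted_cluster():
    # weight concentrated on the upper cluster moves only the weighted mode
    bx = np.ones(6)
    by = np.array([0.2, 0.21, 0.19, 0.8, 0.81, 0.79])
    sy = np.array([0.5, 0.5, 0.5, 0.01, 0.01, 0.01])
    ds = make_harmonized(bx, by, np.full(6, 0.001), sy)
    simple, weighted = mode_estimators(ds, bandwidth_factor=0.2, n_boot=0)
    assert weighted.beta == pytest.approx(0.8, abs=0.03)
    assert simple.beta == pytest.approx(0.2, abs=0.03)  # unweighted ties to the smaller cluster


def test_mode_matches_dense_grid_oracle(rng):
    from scipy.stats import norm

    for _ in range(10):
        ds = _random_instance(rng, 7)
        bx, _, by, sy = ds.arrays()
        ratios = by / bx
        w = bx**2 / sy**2
        med = np.median(ratios)
        h = 1.4826 * np.median(np.abs(ratios - med))
        grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 20_001)
        dens = norm.pdf((grid[:, None] - ratios[None, :]) / h) @ (w / w.sum())
        expect = grid[np.argmax(dens)]
        got = mode_estimators(ds, n_boot=0)[1].beta
        assert got == pytest.approx(expect, abs=(grid[1] - grid[0]) * 60)


# ------------------------------------------------------------- invariants

@pytest.mark.parametrize("c", [0.5, 2.0, 10.0])
def test_scale_equivariance_of_all_estimators(rng, c):
    ds = _random_instance(rng, 8)
    bx, sx, by, sy = ds.arrays()
    scaled = make_harmonized(c * bx, by, c * sx, sy)
    for fit, fit_scaled in [
        (ivw(ds), ivw(scaled)),
        (egger(ds), egger(scaled)),
        (weighted_median(ds, n_boot=0), weighted_median(scaled, n_boot=0)),
        (mode_estimators(ds, n_boot=0)[0], mode_estimators(scaled, n_boot=0)[0]),
    ]:
        assert fit_scaled.beta == pytest.approx(fit.beta / c, rel=1e-9)


def test_orientation_invariance_of_record_signs(rng):
    ds = _random_instance(rng, 8)
    bx, sx, by, sy = ds.arrays()
    flip = np.ones(8)
    flip[[1, 4, 6]] = -1.0
    flipped = make_harmonized(flip * bx, flip * by, sx, sy)
    assert ivw(flipped).beta == pytest.approx(ivw(ds).beta, abs=1e-12)
    assert egger(flipped).beta == pytest.approx(egger(ds).beta, abs=1e-12)
    assert egger(flipped).extra["egger_intercept"] == pytest.approx(
        egger(ds).extra["egger_intercept"], abs=1e-12)
    assert weighted_median(flipped, n_boot=0).beta == pytest.approx(
        weighted_median(ds, n_boot=0).beta, abs=1e-12)


def test_ci_and_pvalue_follow_the_normal_convention(rng):
    ds = _random_instance(rng, 6)
    res = ivw(ds)
    assert res.ci_low == pytest.approx(res.beta - 1.959964 * res.se, abs=1e-6 * res.se + 1e-12)
    assert res.ci_high == pytest.approx(res.beta + 1.959964 * res.se, abs=1e-6 * res.se + 1e-12)
    from scipy.stats import norm
    assert res.pvalue == pytest.approx(2 * norm.sf(abs(res.beta / res.se)), abs=1e-12)


@given(st.lists(st.floats(0.05, 0.5), min_size=3, max_size=8),
       st.integers(0, 10**6))
@settings(max_examples=30, deadline=None)
def test_weighted_median_always_within_ratio_range(bxs, seed):
    rng = np.random.default_rng(seed)
    bx = np.asarray(bxs)
    by = rng.normal(0.3 * bx, 0.05)
    ds = make_harmonized(bx, by, np.full(len(bx), 0.01), np.full(len(bx), 0.05))
    ratios = by / bx
    res = weighted_median(ds, n_boot=0)
    assert ratios.min() - 1e-12 <= res.beta <= ratios.max() + 1e-12
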