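"""Instrument selection, explained variance and the F-statistic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrscreen.data import SnpAssociation
from mrscreen.instruments import (LdMatrix, f_statistic, read_ld_matrix,
                                  select_instruments, snp_r2, write_ld_matrix)
from mrscreen.simulate import simulate_ld_block

from conftest import make_stats


# ------------------------------------------------------------------ snp_r2

def test_snp_r2_zero_effect():
    assert snp_r2(beta=0.0, se=0.01, n=10_000) == 0.0


def test_snp_r2_matches_both_algebraic_forms():
    beta, se, eaf, n = 0.1, 0.01, 0.5, 10_000
    got = snp_r2(beta=beta, se=se, n=n)
    # z^2/(z^2+n)
    assert got == pytest.approx(100.0 / 10100.0, abs=1e-12)
    # 2p(1-p)beta^2 / (2p(1-p)beta^2 + se^2 n 2p(1-p))
    het = 2 * eaf * (1 - eaf)
    full = het * beta**2 / (het * beta**2 + se**2 * n * het)
    assert got == pytest.approx(full, abs=1e-15)


def test_snp_r2_increases_with_effect_size():
    vals = [snp_r2(beta=b, se=0.01, n=5_000) for b in (0.01, 0.05, 0.1, 0.5)]
    assert all(a < b for a, b in zip(vals, vals[1:]))


def test_snp_r2_rejects_tiny_n():
    with pytest.raises(ValueError):
        snp_r2(beta=0.1, se=0.01, n=2)


def test_snp_r2_accepts_association_record():
    rec = SnpAssociation("rs1", "1", 100, "A", "G", 0.3, 0.1, 0.01, 1e-8, 10_000)
    assert snp_r2(rec) == snp_r2(beta=0.1, se=0.01, n=10_000)


# -------------------------------------------------------------- f_statistic

def test_f_statistic_zero_variance():
    assert f_statistic(1000, 3, 0.0) == 0.0


def test_f_statistic_printed_formula():
    assert f_statistic(1001, 1, 0.01) == pytest.approx(999 * (0.01 / 0.99), abs=1e-9)


def test_f_statistic_decreases_with_k():
    vals = [f_statistic(10_000, k, 0.05) for k in (1, 5, 20, 50)]
    assert all(a > b for a, b in zip(vals, vals[1:]))


@pytest.mark.parametrize("n,k,r2", [(5, 4, 0.1), (100, 1, 1.0), (100, 0, 0.1)])
def test_f_statistic_domain_errors(n, k, r2):
    with pytest.raises(ValueError):
        f_statistic(n, k, r2)


# -------------------------------------------------------------- selection

def test_no_significant_snp_gives_flagged_empty_set():
    stats = make_stats([{"pvalue": 1e-4}, {"pvalue": 0.5}])
    inst = select_instruments(stats)
    assert inst.no_instruments and inst.k == 0


def test_single_significant_snp_retained():
    stats = make_stats([{"pvalue": 1e-9, "beta": 0.1, "se": 0.015}, {"pvalue": 0.5}])
    inst = select_instruments(stats)
    assert inst.k == 1 and inst.snp_ids() == ["rs1"]
    assert inst.f_statistic == pytest.approx(
        f_statistic(10_000, 1, inst.r2_total), abs=1e-9)


def test_two_close_snps_in_ld_keep_smaller_p():
    stats = make_stats([
        {"snp_id": "rsA", "pos": 1_000_000, "pvalue": 1e-10},
        {"snp_id": "rsB", "pos": 1_005_000, "pvalue": 1e-9},
    ])
    stats.table.loc[:, "snp_id"] = ["rsA", "rsB"]
    ld = LdMatrix(["rsA", "rsB"], np.array([[1.0, 0.5], [0.5, 1.0]]))
    inst = select_instruments(stats, r2_threshold=0.001, ld=ld)
    assert inst.snp_ids() == ["rsA"]


def test_distance_only_clumping_is_conservative_without_ld():
    stats = make_stats([
        {"snp_id": "rsA", "pos": 1_000_000, "pvalue": 1e-10},
        {"snp_id": "rsB", "pos": 1_005_000, "pvalue": 1e-9},
    ])
    inst = select_instruments(stats, ld=None)
    assert inst.snp_ids() == ["rsA"]


def test_r2_threshold_one_keeps_all_but_exact_duplicates():
    stats = make_stats([
        {"snp_id": "rsA", "pos": 1_000_000, "pvalue": 1e-10},
        {"snp_id": "rsB", "pos": 1_005_000, "pvalue": 1e-9},
        {"snp_id": "rsC", "pos": 1_006_000, "pvalue": 1e-8},
    ])
    r2 = np.array([[1.0, 0.99, 1.0], [0.99, 1.0, 0.99], [1.0, 0.99, 1.0]])
    ld = LdMatrix(["rsA", "rsB", "rsC"], r2)
    inst = select_instruments(stats, r2_threshold=1.0, ld=ld)
    assert inst.snp_ids() == ["rsA", "rsB"]


def _brute_force_clump(stats, p_threshold, r2_threshold, window_kb, ld):
    """Independent greedy reference: explicit p-ordered retain/drop scan."""
    cand = [r for r in stats.records() if r.pvalue < p_threshold]
    cand.sort(key=lambda r: (r.pvalue, r.chrom, r.pos, r.snp_id))
    kept = []
    for r in cand:
        conflict = False
        for k in kept:
            if k.chrom != r.chrom or abs(k.pos - r.pos) > window_kb * 1000:
                continue
            pair = ld.lookup(r.snp_id, k.snp_id) if ld is not None else None
            if pair is None or pair >= r2_threshold:
                conflict = True
        if not conflict:
            kept.append(r)
    return [r.snp_id for r in kept]


@pytest.mark.parametrize("use_ld", [False, True])
def test_clumping_matches_exhaustive_oracle_on_small_instances(rng, use_ld):
    for _ in range(30):
        k = int(rng.integers(2, 9))
        rows = []
        for i in range(k):
            rows.append({
                "snp_id": f"rs{i}",
                "chrom": str(rng.integers(1, 3)),
                "pos": int(rng.integers(1, 30_000_000)),
                "pvalue": float(10.0 ** rng.uniform(-12, -5)),
            })
        stats = make_stats(rows)
        stats.table["chrom"] = [r["chrom"] for r in rows]
        stats.table["pos"] = [r["pos"] for r in rows]
        stats.table["snp_id"] = [r["snp_id"] for r in rows]
        ld = None
        if use_ld:
            m = rng.uniform(0, 1, (k, k))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 1.0)
            ld = LdMatrix([f"rs{i}" for i in range(k)], m)
        inst = select_instruments(stats, 5e-8, 0.3, 10_000, ld)
        assert inst.snp_ids() == _brute_force_clump(stats, 5e-8, 0.3, 10_000, ld)


def test_clumping_invariant_to_row_order(rng):
    rows = [{"snp_id": f"rs{i}", "chrom": "1", "pos": int(rng.integers(1, 50_000_000)),
             "pvalue": float(10.0 ** rng.uniform(-12, -8))} for i in range(6)]
    stats = make_stats(rows)
    stats.table["pos"] = [r["pos"] for r in rows]
    shuffled = make_stats(rows)
    shuffled.table["pos"] = [r["pos"] for r in rows]
    shuffled.table = shuffled.table.sample(frac=1, random_state=3).reset_index(drop=True)
    assert (select_instruments(stats).snp_ids()
            == select_instruments(shuffled).snp_ids())


@given(st.integers(min_value=0, max_value=10**6))
@settings(max_examples=25, deadline=None)
def test_clumping_never_retains_close_ld_pairs(seed):
    rng = np.random.default_rng(seed)
    k = int(rng.integers(2, 8))
    rows = [{"snp_id": f"rs{i}", "pos": int(rng.integers(1, 20_000_000)),
             "pvalue": float(10.0 ** rng.uniform(-12, -8))} for i in range(k)]
    stats = make_stats(rows)
    stats.table["chrom"] = "1"
    stats.table["pos"] = [r["pos"] for r in rows]
    inst = select_instruments(stats, window_kb=5_000)
    kept = inst.table
    pos = kept["pos"].to_numpy()
    for i in range(len(pos)):
        for j in range(i + 1, len(pos)):
            assert abs(int(pos[i]) - int(pos[j])) > 5_000_000


# --------------------------------------------------------------- LD matrix

def test_ld_matrix_validates_shape_and_symmetry():
    with pytest.raises(ValueError):
        LdMatrix(["a", "b"], np.array([[1.0, 0.2], [0.3, 1.0]]))
    with pytest.raises(ValueError):
        LdMatrix(["a"], np.array([[1.0, 0.0], [0.0, 1.0]]))


def test_ld_matrix_tsv_round_trip(tmp_path):
    ld = simulate_ld_block(3, {(0, 1): 0.9, (1, 2): 0.2})
    path = str(tmp_path / "ld.tsv")
    write_ld_matrix(ld, path)
    back = read_ld_matrix(path)
    assert back.snp_ids == ld.snp_ids
    np.testing.assert_allclose(back.r2, ld.r2, atol=1e-12)
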