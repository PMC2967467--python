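"""Group statistics: per-level t values, the cluster-based permutation
test (against an exhaustive-repartition oracle), regional difference
maps and block summaries."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from slnet.registry import make_registry
from slnet.sl import SyncMatrix
from slnet.stats import (block_summary, cluster_permutation_test,
                         level_tstats, regional_difference_map)

# ------------------------------------------------------------- t values


def test_tstat_hand_computed_value():
    g1 = np.array([[1.0], [2.0], [3.0]])
    g2 = np.array([[4.0], [5.0], [6.0]])
    ls = level_tstats(g1, g2)
    # pooled SD 1, SE = sqrt(2/3): t = -3 / 0.8165 = -3.674
    assert ls.t_values[0] == pytest.approx(-3.674, abs=1e-3)
    assert ls.df == 4
    # cross-check against scipy's pooled-variance t-test
    ref = sps.ttest_ind(g1.ravel(), g2.ravel(), equal_var=True).statistic
    assert ls.t_values[0] == pytest.approx(ref)


def test_tstat_identical_groups_zero_with_warning():
    g = np.tile([[1.0, 2.0]], (3, 1))
    with pytest.warns(RuntimeWarning, match="zero pooled variance"):
        ls = level_tstats(g, g.copy())
    assert np.all(ls.t_values == 0.0)


def test_tstat_label_swap_antisymmetry(rng):
    g1 = rng.normal(size=(5, 4))
    g2 = rng.normal(size=(7, 4))
    a = level_tstats(g1, g2).t_values
    b = level_tstats(g2, g1).t_values
    assert np.allclose(a, -b)


def test_tstat_requires_two_subjects():
    with pytest.raises(ValueError):
        level_tstats(np.ones((1, 3)), np.ones((4, 3)))


# ----------------------------------------------------- permutation test


def exhaustive_pvalue_oracle(g1, g2):
    """Independent re-derivation of the exhaustive cluster-permutation
    p-value using only scipy t-tests and itertools."""
    import itertools

    pooled = np.vstack([g1, g2])
    n1 = g1.shape[0]
    n = pooled.shape[0]
    df = n - 2
    lo, hi = sps.t.ppf(0.025, df), sps.t.ppf(0.975, df)

    def max_cluster(tvals):
        best, run, state = 0.0, 0.0, 0
        for v in list(tvals) + [0.0]:
            s = 1 if v > hi else (-1 if v < lo else 0)
            if state != 0 and s != state:
                best = max(best, abs(run))
                run = 0.0
            if s != 0:
                if state != s:
                    run = 0.0
                run += v
            state = s
        return best

    def tprofile(idx):
        mask = np.zeros(n, dtype=bool)
        mask[list(idx)] = True
        a, b = pooled[mask], pooled[~mask]
        res = sps.ttest_ind(a, b, axis=0, equal_var=True).statistic
        return np.nan_to_num(res)

    obs = max_cluster(tprofile(range(n1)))
    stats = [max_cluster(tprofile(idx))
             for idx in itertools.combinations(range(n), n1)]
    return obs, sum(s >= obs - 1e-12 for s in stats) / len(stats)


def test_exhaustive_p_matches_independent_oracle(rng):
    g1 = rng.normal(0.0, 1.0, size=(4, 6))
    g2 = rng.normal(0.8, 1.0, size=(4, 6))
    res = cluster_permutation_test(g1, g2, method="exhaustive")
    obs, p_oracle = exhaustive_pvalue_oracle(g1, g2)
    assert res.method == "exhaustive"
    assert res.n_permutations == math.comb(8, 4)
    assert res.max_stat == pytest.approx(obs)
    assert res.p_value == pytest.approx(p_oracle)


def test_montecarlo_agrees_with_exhaustive_4plus4(rng):
    """Monte-Carlo permutation p matches the exact p over all C(8,4)
    repartitions within 3 Monte-Carlo standard errors."""
    g1 = rng.normal(0.0, 1.0, size=(4, 6))
    g2 = rng.normal(1.2, 1.0, size=(4, 6))
    exact = cluster_permutation_test(g1, g2, method="exhaustive").p_value
    n_mc = 4000
    mc = cluster_permutation_test(g1, g2, method="montecarlo",
                                  n_permutations=n_mc, seed=5).p_value
    se = math.sqrt(exact * (1 - exact) / n_mc)
    assert abs(mc - exact) < 3 * se + 2 / n_mc


def test_strong_shift_gives_minimal_p(rng):
    """A uniform 3-SD shift yields one cluster spanning every level and
    the smallest attainable Monte-Carlo p-value."""
    g1 = rng.normal(0.0, 1.0, size=(10, 5))
    g2 = rng.normal(3.0, 1.0, size=(10, 5))
    res = cluster_permutation_test(g1, g2, n_permutations=500, seed=2,
                                   method="montecarlo")
    assert len(res.clusters) == 1
    assert res.clusters[0].levels == (0, 1, 2, 3, 4)
    assert res.clusters[0].sign == -1
    assert res.p_value == pytest.approx(1 / 501)


def test_no_clusters_p_is_one():
    rng = np.random.default_rng(0)
    g = rng.normal(size=(6, 4))
    res = cluster_permutation_test(g[:3], g[3:] + 0.01, seed=1)
    if not res.clusters:  # the null-ish split should produce no clusters
        assert res.p_value == 1.0


def test_permutation_determinism_and_label_swap(rng):
    g1 = rng.normal(0.0, 1.0, size=(12, 5))
    g2 = rng.normal(0.7, 1.0, size=(11, 5))
    a = cluster_permutation_test(g1, g2, n_permutations=300, seed=9,
                                 method="montecarlo")
    b = cluster_permutation_test(g1, g2, n_permutations=300, seed=9,
                                 method="montecarlo")
    assert a.p_value == b.p_value and a.max_stat == b.max_stat
    # swapping labels flips cluster signs but preserves the statistic
    c = cluster_permutation_test(g2, g1, n_permutations=300, seed=9,
                                 method="montecarlo")
    assert c.max_stat == pytest.approx(a.max_stat)


def test_single_subject_group_rejected(rng):
    with pytest.raises(ValueError):
        cluster_permutation_test(rng.normal(size=(1, 4)),
                                 rng.normal(size=(5, 4)))


# ------------------------------------------------------- regional maps


def _matrices_from(rng, n_subjects, n_regions, shift=None):
    mats = []
    for _ in range(n_subjects):
        v = rng.uniform(0.2, 0.4, size=(n_regions, n_regions))
        if shift is not None:
            v = v + shift
        v = np.clip((v + v.T) / 2, 0, 1)
        np.fill_diagonal(v, 1.0)
        mats.append(SyncMatrix(values=v, region_labels=tuple(
            f"r{i}" for i in range(n_regions))))
    return mats


def test_regional_map_symmetric_zero_diagonal(rng):
    m1 = _matrices_from(rng, 5, 8)
    m2 = _matrices_from(rng, 6, 8)
    d = regional_difference_map(m1, m2)
    assert np.array_equal(d.signs, d.signs.T)
    assert np.all(np.diag(d.signs) == 0)
    assert set(np.unique(d.signs)) <= {-1, 0, 1}


def test_regional_map_recovers_planted_shift(rng):
    n = 10
    shift = np.zeros((n, n))
    shift[:4, :4] = 0.15  # planted increase within the first block
    m1 = _matrices_from(rng, 8, n, shift=shift)
    m2 = _matrices_from(rng, 8, n)
    d = regional_difference_map(m1, m2)
    planted = d.signs[:4, :4][np.triu_indices(4, k=1)]
    assert np.mean(planted == 1) > 0.8
    rest = d.signs[4:, 4:][np.triu_indices(6, k=1)]
    assert np.mean(rest != 0) < 0.3


def test_regional_map_label_mismatch_rejected(rng):
    m1 = _matrices_from(rng, 3, 5)
    m2 = _matrices_from(rng, 3, 6)
    with pytest.raises(ValueError):
        regional_difference_map(m1, m2)


def test_regional_map_null_false_positive_rate_near_alpha(rng):
    """Under the null the fraction of significant pairs matches alpha."""
    fps = []
    for _ in range(12):
        m1 = _matrices_from(rng, 8, 12)
        m2 = _matrices_from(rng, 8, 12)
        d = regional_difference_map(m1, m2, alpha=0.05)
        iu = np.triu_indices(12, k=1)
        fps.append(np.mean(d.signs[iu] != 0))
    rate = np.mean(fps)
    n_tests = 12 * 66
    band = 3 * math.sqrt(0.05 * 0.95 / n_tests)
    assert abs(rate - 0.05) < band + 0.01


# -------------------------------------------------------- block summary


def _diffmap_with_signs(signs, labels):
    n = len(labels)
    p = np.where(signs != 0, 0.01, 0.5)
    from slnet.stats import RegionalDiffMap
    return RegionalDiffMap(signs=signs, p_values=p,
                           t_values=signs.astype(float), alpha=0.05,
                           region_labels=tuple(labels))


def test_block_summary_counts():
    block_map = ("frontal", "frontal", "parieto-occipital",
                 "parieto-occipital", "cerebellar")
    reg = make_registry(block_map)
    labels = tuple(reg["region"])
    signs = np.zeros((5, 5), dtype=int)
    d = _diffmap_with_signs(signs, labels)
    summary = block_summary(d, reg)
    assert summary["n_increase"].sum() == 0
    assert summary["n_decrease"].sum() == 0

    signs[0, 1] = signs[1, 0] = 1     # frontal-frontal increase
    signs[0, 2] = signs[2, 0] = -1    # frontal-posterior decrease
    signs[0, 4] = signs[4, 0] = -1    # frontal-cerebellar decrease
    d = _diffmap_with_signs(signs, labels)
    summary = block_summary(d, reg).set_index(["block_a", "block_b"])
    assert summary.loc[("frontal", "frontal"), "n_increase"] == 1
    assert summary.loc[("frontal", "parieto-occipital"), "n_decrease"] == 1

    no_cereb = block_summary(d, reg, exclude_cerebellum=True)
    assert not (no_cereb["block_a"] == "cerebellar").any()
    assert not (no_cereb["block_b"] == "cerebellar").any()


def test_block_summary_missing_region_rejected():
    reg = make_registry(("frontal", "frontal"))
    signs = np.zeros((3, 3), dtype=int)
    d = _diffmap_with_signs(signs, ("a", "b", "c"))
    with pytest.raises(ValueError, match="missing"):
        block_summary(d, reg)
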