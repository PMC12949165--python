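"""Cluster permutation statistics: enumeration oracle, weighting, calibration."""

import numpy as np
import pytest
from scipy import stats

from gaitmep import cluster_stats as cl


def brute_force_clusters(t, t_crit):
    """Cyclic cluster enumeration via run search on the doubled array."""
    n = len(t)
    sig = np.abs(t) > t_crit
    sgn = np.sign(t)
    if sig.all() and len(np.unique(sgn)) == 1:
        return [(frozenset(range(n)), t.sum())]
    sig2 = np.concatenate([sig, sig])
    sgn2 = np.concatenate([sgn, sgn])
    t2 = np.concatenate([t, t])
    out = []
    i = 0
    while i < 2 * n:
        prev_ok = i > 0 and sig2[i - 1] and sgn2[i - 1] == sgn2[i]
        if sig2[i] and not prev_ok:
            j = i
            while j + 1 < 2 * n and sig2[j + 1] and sgn2[j + 1] == sgn2[i]:
                j += 1
            if i < n and (j - i + 1) <= n:  # runs starting in the first copy
                idx = frozenset(k % n for k in range(i, j + 1))
                # keep only maximal runs: a run fully inside [0, n) that is a
                # tail of a wrapped run would start at 0 with sig at n-1
                if not (i == 0 and sig2[2 * n - 1] and sgn2[2 * n - 1] == sgn2[0]):
                    out.append((idx, t2[i : j + 1].sum()))
            i = j + 1
        else:
            i += 1
    return out


class TestPointwiseT:
    def test_identical_conditions_zero(self):
        a = np.random.default_rng(0).normal(size=(6, 50))
        t, df = cl.pointwise_paired_t(a, a.copy())
        assert np.all(t == 0.0) and df == 5

    def test_matches_scipy_per_point(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=(10, 30)), rng.normal(size=(10, 30))
        t, _ = cl.pointwise_paired_t(a, b)
        ref = stats.ttest_rel(a, b, axis=0).statistic
        np.testing.assert_allclose(t, ref, atol=1e-10)

    def test_equal_weights_reduce_to_classical(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=(8, 40)), rng.normal(size=(8, 40))
        tu, _ = cl.pointwise_paired_t(a, b, "unweighted")
        tw, _ = cl.pointwise_paired_t(a, b, "weighted", weights=np.full((8, 40), 0.3))
        np.testing.assert_allclose(tu, tw, atol=1e-12)

    def test_zero_variance_shift_capped(self):
        a = np.zeros((5, 10))
        b = np.full((5, 10), 1.0)
        t, _ = cl.pointwise_paired_t(a, b)
        assert np.all(t == -cl.T_CAP)

    def test_too_few_participants(self):
        with pytest.raises(ValueError):
            cl.pointwise_paired_t(np.zeros((1, 5)), np.zeros((1, 5)))


class TestClusterEnumeration:
    def test_full_cycle_single_cluster(self):
        t = np.full(40, 5.0)
        clusters = cl.find_clusters_cyclic(t, 2.0)
        assert len(clusters) == 1 and clusters[0].size == 40

    def test_wrapped_cluster(self):
        t = np.zeros(200)
        t[[0, 1, 198, 199]] = 4.0
        clusters = cl.find_clusters_cyclic(t, 2.0)
        assert len(clusters) == 1
        assert clusters[0].size == 4
        assert list(clusters[0].indices) == [198, 199, 0, 1]

    def test_opposite_signs_not_merged_across_wrap(self):
        t = np.zeros(50)
        t[0] = 4.0
        t[49] = -4.0
        clusters = cl.find_clusters_cyclic(t, 2.0)
        assert len(clusters) == 2

    def test_matches_doubled_array_brute_force(self):
        rng = np.random.default_rng(3)
        t_crit = 2.0
        for _ in range(100):
            t = rng.normal(0, 1.6, int(rng.integers(8, 220)))
            clusters = cl.find_clusters_cyclic(t, t_crit)
            ref = brute_force_clusters(t, t_crit)
            assert {frozenset(int(i) for i in c.indices) for c in clusters} == {
                idx for idx, _ in ref
            }
            np.testing.assert_allclose(
                sorted(c.mass for c in clusters), sorted(m for _, m in ref), atol=1e-9
            )

    def test_tie_at_threshold_not_significant(self):
        t = np.array([2.0, 2.0001, 0.0, 0.0])
        clusters = cl.find_clusters_cyclic(t, 2.0)
        assert len(clusters) == 1 and clusters[0].size == 1


class TestPermutation:
    def test_p_floor(self):
        assert cl.min_attainable_p(1000) == 0.001

    def test_identical_conditions_no_clusters(self):
        a = np.random.default_rng(4).normal(size=(8, 60))
        res = cl.permutation_null(a, a.copy(), n_permutations=100, seed=1)
        assert res.clusters == []

    def test_reproducible_from_seed(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=(8, 60)), rng.normal(size=(8, 60))
        r1 = cl.permutation_null(a, b, n_permutations=200, seed=7)
        r2 = cl.permutation_null(a, b, n_permutations=200, seed=7)
        np.testing.assert_array_equal(r1.null_max_mass, r2.null_max_mass)

    def test_participant_relabelling_invariance(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(size=(8, 60)), rng.normal(size=(8, 60))
        perm = rng.permutation(8)
        r1 = cl.permutation_null(a, b, n_permutations=150, seed=3)
        r2 = cl.permutation_null(a[perm], b[perm], n_permutations=150, seed=3)
        # the observed t curve (hence clusters) is permutation invariant;
        # the null differs only through which participants flip per draw
        np.testing.assert_allclose(r1.t_observed, r2.t_observed, atol=1e-10)
        assert sorted(c.mass for c in r1.clusters) == pytest.approx(
            sorted(c.mass for c in r2.clusters)
        )

    def test_p_values_never_below_floor(self):
        rng = np.random.default_rng(7)
        a = rng.normal(size=(10, 80))
        b = a + 3.0 + 0.1 * rng.normal(size=(10, 80))
        res = cl.permutation_null(a, b, n_permutations=250, seed=2)
        assert res.clusters
        assert all(c.p_value >= 1 / 250 for c in res.clusters)

    def test_few_permutations_warn(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(size=(4, 20)), rng.normal(size=(4, 20))
        with pytest.warns(UserWarning):
            cl.permutation_null(a, b, n_permutations=50, seed=0)


class TestScalarT:
    def test_identical_pairs(self):
        t, df, p = cl.paired_t_scalar(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0]))
        assert t == 0.0 and p == 1.0 and df == 2

    def test_constant_shift_degenerate(self):
        t, _, p = cl.paired_t_scalar(np.array([1.0, 2.0, 3.0]), np.array([2.0, 3.0, 4.0]))
        assert t == -cl.T_CAP and p == 0.0

    def test_matches_scipy_on_random_pairs(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            n = int(rng.integers(3, 30))
            a, b = rng.normal(size=n), rng.normal(size=n)
            t, df, p = cl.paired_t_scalar(a, b)
            ref_t, ref_p = stats.ttest_rel(a, b)
            assert t == pytest.approx(ref_t, abs=1e-10)
            assert p == pytest.approx(ref_p, abs=1e-10)
            assert df == n - 1
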