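"""Von Mises kernel regression: normalisation, equivariance, density rule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy.special import i0

from gaitmep import cyclic_smoothing as cs


def brute_force_smooth(pcts, vals, grid, kappa):
    """Independent double-loop evaluation of the kernel regression."""
    values = np.empty(grid.n_points)
    density = np.empty(grid.n_points)
    for gi, gp in enumerate(grid.pcts):
        w = np.array(
            [np.exp(kappa * np.cos(2 * np.pi * (gp - p) / 100.0)) / (2 * np.pi * i0(kappa))
             for p in pcts]
        )
        density[gi] = w.sum()
        values[gi] = (w * vals).sum() / w.sum()
    return values, density


class TestKappaFromSigma:
    def test_two_percent_sigma(self):
        assert cs.kappa_from_sigma(2.0) == pytest.approx(1.0 / (0.04 * np.pi) ** 2)
        assert cs.kappa_from_sigma(2.0, rounded=True) == 60.0

    def test_unit_sigma_in_radians(self):
        sigma_pct = 100.0 / (2 * np.pi)  # sigma_rad = 1
        assert cs.kappa_from_sigma(sigma_pct) == pytest.approx(1.0)

    def test_halving_sigma_quadruples_kappa(self):
        assert cs.kappa_from_sigma(1.0) == pytest.approx(4 * cs.kappa_from_sigma(2.0))

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            cs.kappa_from_sigma(0.0)


class TestWeights:
    def test_maximal_at_coincidence(self):
        grid = cs.CyclicGrid(0.5)
        w = cs.vonmises_weights(np.array([25.0]), grid, kappa=60.0)
        assert np.argmax(w[:, 0]) == 50  # grid point 25%

    def test_kernel_integrates_to_one(self):
        grid = cs.CyclicGrid(0.05)  # fine grid for quadrature
        w = cs.vonmises_weights(np.array([40.0]), grid, kappa=60.0)
        dtheta = 2 * np.pi * grid.resolution / 100.0
        assert w[:, 0].sum() * dtheta == pytest.approx(1.0, abs=1e-6)

    def test_periodic_symmetry(self):
        grid = cs.CyclicGrid(0.5)
        w = cs.vonmises_weights(np.array([1.0, 99.0]), grid, kappa=60.0)
        assert w[0, 0] == pytest.approx(w[0, 1], rel=1e-12)


class TestSmoothing:
    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        grid = cs.CyclicGrid(0.5)
        for _ in range(5):
            n = int(rng.integers(5, 120))
            pcts = rng.uniform(0, 100, n)
            vals = rng.normal(0, 10, n)
            kappa = float(rng.uniform(5, 120))
            sm = cs.smooth_participant(pcts, vals, grid, kappa)
            bv, bw = brute_force_smooth(pcts, vals, grid, kappa)
            np.testing.assert_allclose(sm.values, bv, atol=1e-12)
            np.testing.assert_allclose(sm.density, bw, atol=1e-12)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        c=hst.floats(-100, 100),
        kappa=hst.floats(1.0, 200.0),
        n=hst.integers(1, 50),
    )
    def test_constant_inputs_give_constant_output(self, c, kappa, n):
        grid = cs.CyclicGrid(2.0)
        rng = np.random.default_rng(n)
        sm = cs.smooth_participant(rng.uniform(0, 100, n), np.full(n, c), grid, kappa)
        np.testing.assert_allclose(sm.values, c, atol=1e-9 * max(1, abs(c)))

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(1)
        grid = cs.CyclicGrid(0.5)
        pcts = rng.uniform(0, 100, 80)
        vals = rng.normal(0, 5, 80)
        a = cs.smooth_participant(pcts, vals, grid, 60.0)
        b = cs.smooth_participant((pcts + 10.0) % 100.0, vals, grid, 60.0)
        shift = int(10.0 / grid.resolution)
        np.testing.assert_allclose(np.roll(a.values, shift), b.values, atol=1e-9)

    def test_large_kappa_interpolates_sample(self):
        grid = cs.CyclicGrid(0.5)
        sm = cs.smooth_participant(
            np.array([30.0, 70.0]), np.array([1.0, 9.0]), grid, kappa=1e5
        )
        assert sm.values[int(30 / 0.5)] == pytest.approx(1.0, abs=1e-6)

    def test_nan_values_dropped(self):
        grid = cs.CyclicGrid(1.0)
        sm = cs.smooth_participant(
            np.array([10.0, 50.0]), np.array([5.0, np.nan]), grid, 30.0
        )
        np.testing.assert_allclose(sm.values, 5.0)

    def test_empty_samples_rejected(self):
        with pytest.raises(ValueError):
            cs.smooth_participant(np.array([]), np.array([]), cs.CyclicGrid(1.0), 60.0)


class TestDensityRule:
    def test_six_samples_at_grid_point_valid(self):
        grid = cs.CyclicGrid(0.5)
        valid = cs.check_density_rule(np.full(6, 40.0), grid, sigma_pct=2.0)
        assert valid[int(40 / 0.5)]
        valid5 = cs.check_density_rule(np.full(5, 40.0), grid, sigma_pct=2.0)
        assert not valid5[int(40 / 0.5)]

    def test_empty_region_invalid(self):
        grid = cs.CyclicGrid(0.5)
        pcts = np.concatenate([np.linspace(0, 40, 120), np.linspace(60, 99.5, 120)])
        valid = cs.check_density_rule(pcts, grid, sigma_pct=2.0)
        assert not valid[int(50 / 0.5)]

    def test_uniform_density_two_per_percent_all_valid(self):
        # ~2 samples/1% puts ~16 >= 6 samples inside +-2 sigma of every point
        rng = np.random.default_rng(2)
        grid = cs.CyclicGrid(0.5)
        pcts = rng.uniform(0, 100, 200)
        valid = cs.check_density_rule(pcts, grid, sigma_pct=2.0)
        assert valid.mean() > 0.95


class TestGroupAverage:
    def _series(self, grid, values, density):
        return cs.SmoothedCyclicSeries(
            grid=grid, values=np.asarray(values, float), density=np.asarray(density, float)
        )

    def test_equal_densities_weighted_equals_unweighted(self):
        grid = cs.CyclicGrid(10.0)
        n = grid.n_points
        s1 = self._series(grid, np.ones(n), np.full(n, 2.0))
        s2 = self._series(grid, 3 * np.ones(n), np.full(n, 2.0))
        gw, _ = cs.group_average([s1, s2], "weighted")
        gu, _ = cs.group_average([s1, s2], "unweighted")
        np.testing.assert_allclose(gw, gu)

    def test_high_density_participant_dominates(self):
        grid = cs.CyclicGrid(10.0)
        n = grid.n_points
        s1 = self._series(grid, np.zeros(n), np.full(n, 10.0))
        s2 = self._series(grid, np.ones(n), np.full(n, 1.0))
        gw, w = cs.group_average([s1, s2], "weighted")
        assert np.all(gw < 0.15)
        np.testing.assert_allclose(w.sum(axis=0), 1.0)

    def test_single_participant_rejected(self):
        grid = cs.CyclicGrid(10.0)
        s = self._series(grid, np.zeros(grid.n_points), np.ones(grid.n_points))
        with pytest.raises(ValueError):
            cs.group_average([s], "weighted")
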