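"""EMG filtering, MEP extraction windows, rigid-body coil check, exclusions."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from gaitmep import emg_mep as em

RATE = 2000.0


class TestBandpassFilter:
    def test_in_band_tone_preserved(self):
        t = np.arange(0, 4, 1 / RATE)
        x = np.sin(2 * np.pi * 100.0 * t)
        y = em.bandpass_filter(x, RATE)
        core = slice(2000, -2000)
        assert np.abs(y[core]).max() == pytest.approx(1.0, abs=0.01)

    def test_dc_removed(self):
        y = em.bandpass_filter(np.full(8000, 50.0), RATE)
        assert abs(y[2000:-2000].mean()) < 1e-6

    def test_stopband_tone_attenuated(self):
        t = np.arange(0, 8, 1 / RATE)
        y = em.bandpass_filter(np.sin(2 * np.pi * 5.0 * t), RATE)
        assert np.abs(y[4000:-4000]).max() < 0.1

    def test_low_rate_rejected(self):
        with pytest.raises(ValueError):
            em.bandpass_filter(np.zeros(100), 800.0)


class TestOngoingEmg:
    def test_constant_signal_regardless_of_artifact(self):
        x = np.full(4000, 3.0)
        x[2000] = 12345.0
        assert em.compute_ongoing_emg(x, 2000, RATE) == pytest.approx(3.0)

    def test_zero_signal_with_artifact_spike(self):
        x = np.zeros(4000)
        x[2000] = 1000.0
        assert em.compute_ongoing_emg(x, 2000, RATE) == 0.0

    def test_window_sample_count(self):
        # -20..+10 ms at 2000 Hz = 61 samples inclusive, minus the artifact
        x = np.zeros(4000)
        x[2000 - 40 : 2000 + 20 + 1] = 1.0
        x[2000] = 999.0
        assert em.compute_ongoing_emg(x, 2000, RATE) == pytest.approx(1.0)
        x[2000 - 41] = 500.0  # just outside the window: no effect
        x[2000 + 21] = 500.0
        assert em.compute_ongoing_emg(x, 2000, RATE) == pytest.approx(1.0)

    def test_window_out_of_range(self):
        with pytest.raises(ValueError):
            em.compute_ongoing_emg(np.zeros(100), 10, RATE)


class TestAbsoluteMep:
    def test_flat_signal_zero(self):
        assert em.compute_absolute_mep(np.zeros(4000), 2000, RATE) == 0.0

    def test_sinusoid_inside_window(self):
        x = np.zeros(4000)
        t = np.arange(60) / RATE
        x[2000 + 40 : 2000 + 100] = 100.0 * np.sin(2 * np.pi * 100 * t[:60])
        assert em.compute_absolute_mep(x, 2000, RATE) == pytest.approx(200.0, rel=0.001)

    def test_early_deflection_outside_window(self):
        x = np.zeros(4000)
        x[2000 + 10] = 500.0  # 5 ms latency: before the 10 ms window start
        assert em.compute_absolute_mep(x, 2000, RATE) == 0.0

    def test_artifact_sample_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 10, 4000)
        y = x.copy()
        y[2000] += 5000.0
        assert em.compute_absolute_mep(x, 2000, RATE) == em.compute_absolute_mep(y, 2000, RATE)
        assert em.compute_ongoing_emg(x, 2000, RATE) == em.compute_ongoing_emg(y, 2000, RATE)


class TestMepGain:
    def test_ratio(self):
        assert em.compute_mep_gain(200.0, 10.0) == 20.0
        assert em.compute_mep_gain(0.0, 10.0) == 0.0

    def test_zero_background_flagged_missing(self):
        assert np.isnan(em.compute_mep_gain(100.0, 0.0))

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 20, 4000)
        g1 = em.compute_mep_gain(
            em.compute_absolute_mep(x, 2000, RATE), em.compute_ongoing_emg(x, 2000, RATE)
        )
        g2 = em.compute_mep_gain(
            em.compute_absolute_mep(3.7 * x, 2000, RATE),
            em.compute_ongoing_emg(3.7 * x, 2000, RATE),
        )
        assert g1 == pytest.approx(g2, rel=1e-9)


class TestVirtualMarker:
    def _sets(self, rng):
        helmet = rng.uniform(-80, 80, (4, 3))
        head = rng.uniform(-90, 90, (4, 3))
        virtual = np.array([0.0, 0.0, 120.0])
        return helmet, head, virtual

    def test_identical_motion_zero_displacement(self):
        rng = np.random.default_rng(3)
        helmet, head, virtual = self._sets(rng)
        r = Rotation.from_rotvec([0.1, -0.2, 0.3]).as_matrix()
        t = np.array([12.0, -5.0, 40.0])
        vert, horz = em.compute_virtual_marker_displacement(
            helmet, head, virtual, helmet @ r.T + t, head @ r.T + t
        )
        assert vert == pytest.approx(0.0, abs=1e-9)
        assert horz == pytest.approx(0.0, abs=1e-9)

    def test_pure_vertical_translation(self):
        rng = np.random.default_rng(4)
        helmet, head, virtual = self._sets(rng)
        vert, horz = em.compute_virtual_marker_displacement(
            helmet, head, virtual, helmet, head + np.array([0.0, 0.0, 6.0])
        )
        assert vert == pytest.approx(6.0, abs=1e-9)
        assert horz == pytest.approx(0.0, abs=1e-9)

    def test_injected_offset_recovered_under_rigid_motion(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            helmet, head, virtual = self._sets(rng)
            r = Rotation.from_rotvec(rng.uniform(-0.4, 0.4, 3)).as_matrix()
            t = rng.uniform(-50, 50, 3)
            offset = rng.uniform(-8, 8, 3)
            vert, horz = em.compute_virtual_marker_displacement(
                helmet, head, virtual, helmet @ r.T + t, (head + offset) @ r.T + t
            )
            expected = r @ offset
            assert vert == pytest.approx(abs(expected[2]), abs=1e-6)
            assert horz == pytest.approx(np.hypot(expected[0], expected[1]), abs=1e-6)

    def test_collinear_markers_rejected(self):
        line = np.column_stack([np.arange(4.0), np.zeros(4), np.zeros(4)])
        with pytest.raises(ValueError):
            em.compute_virtual_marker_displacement(
                line, line, np.zeros(3), line, line
            )


class TestExclusions:
    def _rec(self, v, h):
        return em.StimulationRecord(stim_time=1.0, cycle_pct=50.0, coil_vertical=v,
                                    coil_horizontal=h)

    def test_boundary_values_included(self):
        surviving, ok = em.apply_exclusions([self._rec(5.0, 10.0)], min_per_condition=1)
        assert len(surviving) == 1 and ok

    def test_strictly_above_threshold_excluded(self):
        surviving, _ = em.apply_exclusions(
            [self._rec(5.1, 0.0), self._rec(0.0, 10.1)], min_per_condition=1
        )
        assert len(surviving) == 0

    def test_participant_flag_from_surviving_count(self):
        # 120 pulses, 30 with 6 mm vertical displacement -> 90 survive < 100
        records = [self._rec(6.0 if i < 30 else 1.0, 2.0) for i in range(120)]
        surviving, included = em.apply_exclusions(records)
        assert len(surviving) == 90
        assert not included

    def test_exclusion_monotone_in_thresholds(self):
        rng = np.random.default_rng(6)
        records = [self._rec(rng.uniform(0, 8), rng.uniform(0, 14)) for _ in range(60)]
        loose, _ = em.apply_exclusions(records, min_per_condition=1)
        tight, _ = em.apply_exclusions(
            records, min_per_condition=1, vertical_threshold=3.0, horizontal_threshold=6.0
        )
        assert len(tight) <= len(loose)


class TestCyclePercentage:
    def test_linear_interpolation(self):
        hs = np.array([0.0, 1.2, 2.4])
        assert em.assign_cycle_percentage(0.3, hs) == pytest.approx(25.0)

    def test_pulse_at_heel_strike_is_zero(self):
        assert em.assign_cycle_percentage(1.2, np.array([0.0, 1.2, 2.4])) == 0.0

    def test_outside_span_warns_and_returns_none(self):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert em.assign_cycle_percentage(5.0, np.array([0.0, 1.2])) is None

    def test_generator_pulses_match_schedule(self, short_config):
        from gaitmep import synthetic as syn

        _, truth, _ = syn.generate_gait_kinematics(short_config, "steady", seed=2)
        _, stim_times, stim_truth = syn.generate_emg_with_meps(
            short_config, "steady", truth, seed=2
        )
        pcts = np.array([em.assign_cycle_percentage(t, truth.hs_right) for t in stim_times])
        np.testing.assert_allclose(pcts, stim_truth.cycle_pct, atol=1e-9)
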