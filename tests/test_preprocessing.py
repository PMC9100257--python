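"""Filtering, cycle extraction, time/amplitude normalization, local frame."""

import numpy as np
import pytest

from insolecg import (cg_to_local_frame, extract_cycle, lowpass_filter,
                      normalize_cg_by_leg_length,
                      normalize_pressure_by_weight, preprocess_trial,
                      time_normalize)
from insolecg.evaluation import pv_range, trajectory_metrics


class TestLowpassFilter:
    def test_dc_passes_unchanged(self):
        x = np.full(200, 3.7)
        np.testing.assert_allclose(lowpass_filter(x, 100, 7), x, atol=1e-9)

    @pytest.mark.parametrize("freq,keeps", [(1.0, True), (30.0, False)])
    def test_passband_and_stopband(self, freq, keeps):
        t = np.arange(1000) / 100.0
        x = np.sin(2 * np.pi * freq * t)
        y = lowpass_filter(x, 100, 7)
        # measure amplitude away from the edges
        amp = np.abs(y[200:800]).max()
        if keeps:
            assert amp == pytest.approx(1.0, rel=0.01)
        else:
            assert amp < 0.05

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            lowpass_filter(np.zeros(100), 100, 60)


class TestExtractCycle:
    def test_basic_segments(self):
        x = np.arange(120.0)[:, None]
        seg = extract_cycle(x, (0, 100))
        assert seg.shape[0] == 100
        np.testing.assert_array_equal(seg[:, 0], np.arange(100.0))
        assert extract_cycle(x, (10, 20)).shape[0] == 10

    def test_consecutive_cycles_tile(self, rng):
        x = rng.normal(size=(90, 4))
        parts = [extract_cycle(x, (a, b)) for a, b in ((0, 30), (30, 60),
                                                       (60, 90))]
        np.testing.assert_array_equal(np.vstack(parts), x)

    def test_reversed_indices_rejected(self):
        with pytest.raises(ValueError):
            extract_cycle(np.zeros((50, 1)), (20, 10))


class TestTimeNormalize:
    def test_identity_at_100(self, rng):
        x = rng.normal(size=(100, 3))
        np.testing.assert_array_equal(time_normalize(x, 100), x)

    def test_linear_ramp_exact(self):
        ramp = np.linspace(0.0, 1.0, 113)
        out = time_normalize(ramp, 100)
        expected = np.linspace(0.0, 1.0, 100)
        assert out.shape == (100,)
        np.testing.assert_allclose(out, expected, atol=1e-9)

    @pytest.mark.parametrize("n_in", [2, 57, 100, 113, 350])
    def test_output_always_100_with_endpoints(self, rng, n_in):
        x = rng.normal(size=(n_in, 2))
        out = time_normalize(x, 100)
        assert out.shape == (100, 2)
        np.testing.assert_allclose(out[0], x[0], atol=1e-12)
        np.testing.assert_allclose(out[-1], x[-1], atol=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            time_normalize(np.zeros((1, 2)))


class TestWeightNormalization:
    def test_body_weight_force_maps_to_one(self):
        out = normalize_pressure_by_weight(np.array([[70.0 * 9.81]]), 70.0)
        assert out[0, 0] == pytest.approx(1.0)

    def test_zeros_stay_zero_and_scaling(self, rng):
        p = rng.uniform(0, 500, size=(10, 18))
        np.testing.assert_allclose(
            normalize_pressure_by_weight(p, 80.0),
            normalize_pressure_by_weight(p, 40.0) / 2.0)
        assert normalize_pressure_by_weight(np.zeros((5, 2)), 70.0).sum() == 0

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValueError):
            normalize_pressure_by_weight(np.ones((2, 2)), 0.0)


class TestLocalFrame:
    def test_origin_maps_to_zero(self):
        mid = np.array([5.0, 3.0, 1.0])
        out = cg_to_local_frame(mid[None, :], mid, np.array([1.0, 0, 0]))
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_point_ahead_maps_to_x(self):
        out = cg_to_local_frame(np.array([[1.0, 0, 0]]), np.zeros(3),
                                np.array([1.0, 0, 0]))
        np.testing.assert_allclose(out, [[1.0, 0, 0]], atol=1e-12)

    def test_right_handed_axes(self):
        # walking along +y: local x=+y, z=+z, so local y = z x x = -x
        out = cg_to_local_frame(np.array([[1.0, 0, 0]]), np.zeros(3),
                                np.array([0.0, 1.0, 0]))
        np.testing.assert_allclose(out, [[0.0, -1.0, 0.0]], atol=1e-12)

    def test_translation_affects_origin_term_only(self, rng):
        cg = rng.normal(size=(20, 3))
        shift = np.array([3.0, -2.0, 1.0])
        direction = rng.normal(size=3)
        a = cg_to_local_frame(cg + shift, np.zeros(3), direction)
        b = cg_to_local_frame(cg, -shift, direction)
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_vertical_walking_direction_rejected(self):
        with pytest.raises(ValueError):
            cg_to_local_frame(np.zeros((1, 3)), np.zeros(3),
                              np.array([0.0, 0, 1.0]))


class TestLegLengthNormalization:
    def test_trivial_cases(self):
        out = normalize_cg_by_leg_length(np.array([[900.0, 0, 0]]), 900.0)
        np.testing.assert_allclose(out, [[1.0, 0, 0]])
        with pytest.raises(ValueError):
            normalize_cg_by_leg_length(np.zeros((1, 3)), -5.0)

    def test_rrmse_invariant_to_leg_normalization(self, rng):
        ref = rng.normal(size=(100, 3)) * 20
        pred = ref + rng.normal(size=(100, 3))
        m_mm = trajectory_metrics(pred, ref)
        m_norm = trajectory_metrics(pred / 912.0, ref / 912.0)
        for axis in m_mm:
            assert m_mm[axis]["rrmse_pct"] == pytest.approx(
                m_norm[axis]["rrmse_pct"], rel=1e-12)


class TestPreprocessTrial:
    def test_shapes_and_nonnegativity(self, noise_free_trial):
        sample = preprocess_trial(noise_free_trial)
        assert sample.cycle.pressures.shape == (100, 18)
        assert sample.cg.cg.shape == (100, 3)
        assert np.all(sample.cycle.pressures >= 0)

    def test_filtering_preserves_pv_range(self, noise_free_trial):
        """Filtering + time normalization changes the CG PV range < 2%."""
        sample = preprocess_trial(noise_free_trial)
        # reference: the same local-frame path without filtering
        cg = time_normalize(noise_free_trial.cg_global, 100)
        lto = noise_free_trial.events.lto_frame
        origin = np.array([*np.mean(cg[: lto + 1, :2], axis=0), 0.0])
        ref = cg_to_local_frame(cg, origin, cg[-1] - cg[0])
        for axis in (1, 2):
            assert pv_range(sample.cg.cg_mm[:, axis]) == pytest.approx(
                pv_range(ref[:, axis]), rel=0.02)

    def test_deterministic(self, noise_free_trial):
        a = preprocess_trial(noise_free_trial)
        b = preprocess_trial(noise_free_trial)
        np.testing.assert_array_equal(a.cycle.pressures, b.cycle.pressures)
        np.testing.assert_array_equal(a.cg.cg, b.cg.cg)
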