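"""The synthetic gait generator: determinism, phase locking, group structure."""

import numpy as np
import pytest

from insolecg import (GaitEventSchedule, SubjectProfile,
                      generate_cohort, generate_trial, read_trials,
                      write_trials)
from insolecg.evaluation import group_difference_test, pv_range
from insolecg.preprocessing import preprocess_trial, time_normalize
from insolecg.synthetic import GROUP_DEFAULTS


def local_maxima(x):
    """Brute-force interior local maxima indices."""
    return [i for i in range(1, len(x) - 1)
            if x[i] > x[i - 1] and x[i] > x[i + 1]]


class TestEventSchedule:
    def test_default_ordering(self):
        ev = GaitEventSchedule()
        assert 0 < ev.lto_frame < ev.r_midstance_frame < ev.lhs_frame \
            < ev.l_midstance_frame < 100

    @pytest.mark.parametrize("bad", [
        dict(lto_frame=0), dict(lhs_frame=25), dict(l_midstance_frame=100),
        dict(lto_frame=40, r_midstance_frame=30),
    ])
    def test_invalid_schedules_rejected(self, bad):
        with pytest.raises(ValueError):
            GaitEventSchedule(**bad)


class TestGenerateTrial:
    def test_deterministic_given_seed(self, young_profile,
                                      noise_free_generator):
        a = generate_trial(young_profile, 3, config=noise_free_generator)
        b = generate_trial(young_profile, 3, config=noise_free_generator)
        np.testing.assert_array_equal(a.pressures, b.pressures)
        np.testing.assert_array_equal(a.cg_global, b.cg_global)
        assert a.events == b.events

    def test_vertical_cg_peaks_at_midstances(self, noise_free_trial):
        """The double-bump vertical CG has its two maxima exactly at the
        mid-stance events of the resampled cycle."""
        z = time_normalize(noise_free_trial.cg_global[:, 2], 100)
        peaks = local_maxima(z)
        ev = noise_free_trial.events
        assert peaks == [ev.r_midstance_frame, ev.l_midstance_frame]

    def test_ml_pv_range_matches_profile(self, noise_free_trial,
                                         young_profile):
        sample = preprocess_trial(noise_free_trial)
        pv = pv_range(sample.cg.cg_mm[:, 1])
        assert pv == pytest.approx(young_profile.ml_pv_amplitude, rel=0.10)

    def test_ap_monotone_increasing(self, noise_free_trial):
        sample = preprocess_trial(noise_free_trial)
        assert np.all(np.diff(sample.cg.cg_mm[:, 0]) > 0)

    def test_pressures_nonnegative_and_swing_silent(self, noise_free_trial):
        p = noise_free_trial.pressures
        assert np.all(p >= 0)
        n_raw = p.shape[0]
        phi = np.linspace(0.0, 99.0, n_raw)
        ev = noise_free_trial.events
        right = p[:, 9:]
        swing = phi > ev.rto_frame
        assert right[swing].max() < 0.01 * p.max()
        left = p[:, :9]
        left_swing = (phi > ev.lto_frame) & (phi < ev.lhs_frame)
        assert left[left_swing].max() < 0.01 * p.max()

    def test_peak_load_near_body_weight(self, noise_free_trial,
                                        young_profile):
        total = noise_free_trial.pressures.sum(axis=1)
        expected = 1.1 * young_profile.weight * 9.81
        assert total.max() == pytest.approx(expected, rel=1e-6)

    def test_invalid_inputs_rejected(self, young_profile):
        with pytest.raises(ValueError):
            generate_trial(young_profile, 0, n_raw_frames=10)
        with pytest.raises(ValueError):
            SubjectProfile(subject_id="x", group="young", weight=-1,
                           leg_length=900, ml_pv_amplitude=45,
                           pd_pv_amplitude=41)


class TestGenerateCohort:
    def test_counts(self):
        trials = generate_cohort(15, 15, 3, seed=5)
        assert len(trials) == 90
        young = [t for t in trials if t.profile.group == "young"]
        assert len(young) == 45

    def test_train_split_emulation_counts(self):
        assert len(generate_cohort(13, 13, 3, seed=5)) == 78

    def test_group_ml_amplitude_gap(self, noise_free_generator):
        """Mean old-minus-young ML PV range tracks the configured
        group defaults (64.32 - 45.25 = 19.07 mm)."""
        trials = generate_cohort(15, 15, 1, seed=9,
                                 config=noise_free_generator)
        pv = {"young": [], "old": []}
        for t in trials:
            sample = preprocess_trial(t)
            pv[t.profile.group].append(pv_range(sample.cg.cg_mm[:, 1]))
        diff = np.mean(pv["old"]) - np.mean(pv["young"])
        assert diff == pytest.approx(
            GROUP_DEFAULTS["old"]["ml_pv_mean"]
            - GROUP_DEFAULTS["young"]["ml_pv_mean"], abs=3.0)

    def test_group_separation_significant(self):
        """With 15 subjects per group the old group's ML sway is larger
        (p < 0.05), mirroring the young/old contrast the generator encodes."""
        trials = generate_cohort(15, 15, 1, seed=21)
        pv = {"young": [], "old": []}
        for t in trials:
            sample = preprocess_trial(t)
            pv[t.profile.group].append(pv_range(sample.cg.cg_mm[:, 1]))
        res = group_difference_test(pv["young"], pv["old"])
        assert res["direction"] == "old_gt_young"
        assert res["p_value"] < 0.05

    def test_deterministic(self):
        a = generate_cohort(2, 2, 2, seed=3)
        b = generate_cohort(2, 2, 2, seed=3)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.pressures, tb.pressures)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            generate_cohort(0, 1, 1, seed=1)


class TestTrialIO:
    def test_round_trip_bit_exact(self, tmp_path):
        trials = generate_cohort(2, 1, 2, seed=13)
        write_trials(trials, tmp_path / "trials")
        back = read_trials(tmp_path / "trials")
        assert len(back) == len(trials)
        for a, b in zip(trials, back):
            np.testing.assert_array_equal(a.pressures, b.pressures)
            np.testing.assert_array_equal(a.cg_global, b.cg_global)
            assert a.events == b.events
            assert a.profile == b.profile
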