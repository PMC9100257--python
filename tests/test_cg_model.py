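"""The phase-branched CG network: assembly, normalization, training."""

import numpy as np
import pytest

from insolecg import (MinMaxNormalizer, ModelSpec, build_model,
                      train_cg_model)
from insolecg.cg_model import (PhaseBranchedNet, TrainedCGModel,
                               assemble_branched)
from insolecg.phases import PHASES
from insolecg.synthetic import GaitEventSchedule
from insolecg.phases import label_phases


SMALL = dict(branch_units=(8, 6), trunk_units=(6, 6))


def make_trials(n, rng, k_features=240):
    """Tiny synthetic (features, labels, cg) triples with a learnable map."""
    feats, labels, cgs = [], [], []
    for i in range(n):
        ev = GaitEventSchedule(12 + (i % 3), 30, 50 + (i % 2), 80)
        lab = label_phases(ev)
        t = np.arange(100) / 100.0
        base = np.column_stack([
            np.sin(2 * np.pi * t + 0.3 * i),
            np.cos(2 * np.pi * t),
            np.sin(4 * np.pi * t),
        ])
        cg = np.column_stack([t, 0.4 * base[:, 0], 0.3 * base[:, 2] + 0.5])
        f = rng.normal(scale=0.05, size=(100, k_features))
        f[:, 0] += t
        f[:, 1] += base[:, 0]
        f[:, 2] += base[:, 2]
        feats.append(f)
        labels.append(lab)
        cgs.append(cg)
    return feats, labels, cgs


class TestBuildModel:
    def test_branch_widths_follow_feature_counts(self):
        spec = build_model([10, 13, 14, 15])
        net = PhaseBranchedNet(spec, seed=0)
        widths = [b[0].fwd.p.W.shape[0] for b in net.branches]
        assert widths == [10, 13, 14, 15]

    def test_zero_feature_count_rejected(self):
        with pytest.raises(ValueError):
            build_model([10, 0, 14, 15])

    def test_forward_bounded_and_shaped(self, rng):
        spec = build_model([3, 3, 3, 3], **SMALL)
        net = PhaseBranchedNet(spec, seed=1)
        feats, labels, cgs = make_trials(4, rng, k_features=3)
        norm = MinMaxNormalizer.fit(np.vstack(cgs))
        data = assemble_branched(
            feats, labels, cgs,
            {p: np.arange(3) for p in PHASES},
            {p: MinMaxNormalizer.fit(np.vstack(feats)) for p in PHASES},
            norm)
        out = net.predict_normalized(data)
        assert out.shape == (100, 4, 3)
        assert np.all((out > 0) & (out < 1))


class TestMinMaxNormalizer:
    def test_round_trip_exact(self, rng):
        x = rng.normal(size=(50, 4)) * 100
        norm = MinMaxNormalizer.fit(x)
        np.testing.assert_allclose(norm.inverse(norm.transform(x)), x,
                                   atol=1e-12)

    def test_train_extrema_map_to_unit_interval(self, rng):
        x = rng.normal(size=(50, 2))
        norm = MinMaxNormalizer.fit(x)
        t = norm.transform(x)
        np.testing.assert_allclose(t.min(axis=0), 0.0, atol=1e-15)
        np.testing.assert_allclose(t.max(axis=0), 1.0, atol=1e-15)

    def test_out_of_range_values_not_clipped(self):
        norm = MinMaxNormalizer.fit(np.array([[0.0], [1.0]]))
        assert norm.transform(np.array([[2.0]]))[0, 0] == pytest.approx(2.0)
        assert norm.transform(np.array([[-1.0]]))[0, 0] == pytest.approx(-1.0)

    def test_constant_channel_maps_to_zero(self):
        norm = MinMaxNormalizer.fit(np.full((10, 1), 7.0))
        np.testing.assert_allclose(norm.transform(np.full((3, 1), 7.0)), 0.0)


@pytest.fixture(scope="module")
def trained_pair():
    """A small branched model fitted on a noise-free learnable set."""
    rng = np.random.default_rng(8)
    feats, labels, cgs = make_trials(8, rng, k_features=6)
    spec = build_model([6, 6, 6, 6], branch_units=(12, 8),
                       trunk_units=(8, 8), max_epochs=400,
                       early_stop_patience=400, batch_size=4)
    cols = {p: np.arange(6) for p in PHASES}
    model = train_cg_model(spec, feats, labels, cgs, feats[:2], labels[:2],
                           cgs[:2], seed=5, phase_columns=cols)
    return model, (feats, labels, cgs)


class TestTraining:
    def test_loss_decreases(self, trained_pair):
        model, _ = trained_pair
        hist = model.history
        assert hist.train_loss[10] < hist.train_loss[0]

    def test_self_fit_correlation_on_ap_axis(self, trained_pair):
        model, (feats, labels, cgs) = trained_pair
        pred = model.predict(feats[0], labels[0], leg_length=900.0)
        r = np.corrcoef(pred.cg[:, 0], cgs[0][:, 0])[0, 1]
        assert r > 0.99

    def test_predictions_deterministic(self, trained_pair):
        model, (feats, labels, _) = trained_pair
        a = model.predict(feats[1], labels[1], 900.0)
        b = model.predict(feats[1], labels[1], 900.0)
        np.testing.assert_array_equal(a.cg, b.cg)
        assert a.cg.shape == (100, 3)

    def test_training_deterministic_given_seed(self, rng):
        feats, labels, cgs = make_trials(4, np.random.default_rng(3),
                                         k_features=4)
        cols = {p: np.arange(4) for p in PHASES}
        spec = build_model([4, 4, 4, 4], **SMALL, max_epochs=5,
                           batch_size=2)
        runs = []
        for _ in range(2):
            m = train_cg_model(spec, feats, labels, cgs, feats[:1],
                               labels[:1], cgs[:1], seed=9,
                               phase_columns=cols)
            runs.append((m.history.stop_epoch,
                         m.predict(feats[0], labels[0], 900.0).cg))
        assert runs[0][0] == runs[1][0]
        np.testing.assert_array_equal(runs[0][1], runs[1][1])

    def test_save_load_round_trip(self, trained_pair, tmp_path):
        model, (feats, labels, _) = trained_pair
        model.save(tmp_path / "model")
        back = TrainedCGModel.load(tmp_path / "model")
        a = model.predict(feats[0], labels[0], 900.0)
        b = back.predict(feats[0], labels[0], 900.0)
        np.testing.assert_allclose(a.cg, b.cg, atol=1e-12)

    def test_overlong_phase_segment_rejected(self, trained_pair):
        model, (feats, labels, _) = trained_pair
        stretched = label_phases(GaitEventSchedule(12, 70, 80, 90))
        with pytest.raises(ValueError, match="re-pad"):
            model.predict(feats[0], stretched, 900.0)


class TestUnbranched:
    def test_train_and_predict_shapes(self, rng):
        feats, labels, cgs = make_trials(4, rng, k_features=5)
        spec = ModelSpec(feature_counts=(5,), **SMALL, max_epochs=3,
                         batch_size=2)
        model = train_cg_model(spec, feats, None, cgs, feats[:1], None,
                               cgs[:1], seed=2,
                               whole_cycle_columns=np.arange(5))
        pred = model.predict(feats[0], None, 900.0)
        assert pred.cg.shape == (100, 3)
        np.testing.assert_allclose(pred.cg_mm, pred.cg * 900.0)
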