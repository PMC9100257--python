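"""Phase-branched bidirectional recurrent regression of the CG trajectory.

The proposed architecture routes each gait phase's frames, restricted to
that phase's selected features, through an independent stack of two
bidirectional LSTM layers ({64, 32} units). The four per-frame branch
outputs are reassembled in time into one 100-frame sequence, passed through
a combined trunk of two bidirectional LSTM layers ({32, 32} units), and
mapped per frame to the 3-axis CG by an affine head with sigmoid
activation. Inputs and targets are min-max normalized to [0, 1] with
training-set constants; training minimizes mean squared error with Adam
(batch 10, initial learning rate 0.001), learning-rate reduction on
validation plateau, and early stopping.

An unbranched variant with the same layer budget ({64, 32} then {32, 32})
over the whole cycle serves as the comparative baseline.

Because phase lengths vary between trials, each branch is padded to the
phase's maximum training length with masked frames and cropped back to the
true lengths before temporal reassembly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .bilstm import BiLSTMLayer, SigmoidDense, TrainingHistory, fit_model
from .phases import PHASES
from .preprocessing import CGTrajectory

__all__ = [
    "ModelSpec",
    "MinMaxNormalizer",
    "build_model",
    "BranchedDataset",
    "WholeCycleDataset",
    "PhaseBranchedNet",
    "UnbranchedNet",
    "TrainedCGModel",
    "train_cg_model",
]

N_FRAMES = 100
N_AXES = 3


@dataclass(frozen=True)
class ModelSpec:
    """Architecture and training hyperparameters of the CG network."""

    feature_counts: tuple[int, ...]  # per-phase input widths (len 4), or
    # a single width for the unbranched variant
    branch_units: tuple[int, int] = (64, 32)
    trunk_units: tuple[int, int] = (32, 32)
    batch_size: int = 10
    learning_rate: float = 1e-3
    max_epochs: int = 1000
    plateau_patience: int = 20
    plateau_factor: float = 0.5
    min_lr: float = 1e-5
    early_stop_patience: int = 50
    #: extra masked frames on every branch beyond the longest training
    #: segment, so unseen cycles with slightly longer phases still fit
    phase_length_margin: int = 6

    def __post_init__(self) -> None:
        if any(k < 1 for k in self.feature_counts):
            raise ValueError("every branch needs at least one input feature")


def build_model(feature_counts: Sequence[int], **overrides) -> ModelSpec:
    """Spec for the phase-branched network with the given input widths."""
    counts = tuple(int(k) for k in feature_counts)
    if len(counts) != 4:
        raise ValueError("the phase-branched model has exactly 4 branches")
    return ModelSpec(feature_counts=counts, **overrides)


class MinMaxNormalizer:
    """Per-channel min-max scaling to [0, 1] with exact inverse.

    Constants come from the fitting data only; values outside the fitted
    range map outside [0, 1] (no clipping). Constant channels are flagged
    and map to 0.
    """

    def __init__(self, mins: np.ndarray, ranges: np.ndarray):
        self.mins = np.asarray(mins, dtype=float)
        ranges = np.asarray(ranges, dtype=float)
        self.constant = ranges == 0
        self.ranges = np.where(self.constant, 1.0, ranges)

    @classmethod
    def fit(cls, data: np.ndarray) -> "MinMaxNormalizer":
        """Fit per-column constants from an (n, channels) array."""
        mins = data.min(axis=0)
        return cls(mins, data.max(axis=0) - mins)

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.mins) / self.ranges

    def inverse(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, dtype=float) * self.ranges + self.mins

    def to_dict(self) -> dict:
        return {"mins": self.mins.tolist(),
                "ranges": np.where(self.constant, 0.0, self.ranges).tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "MinMaxNormalizer":
        return cls(np.array(d["mins"]), np.array(d["ranges"]))


def _phase_spans(labels: np.ndarray) -> list[tuple[int, int]]:
    """(start, length) of each phase's contiguous block in a label series."""
    spans = []
    for phase in PHASES:
        idx = np.flatnonzero(labels == phase)
        if idx.size == 0:
            raise ValueError(f"phase {phase} absent from the label series")
        if idx[-1] - idx[0] + 1 != idx.size:
            raise ValueError(f"phase {phase} frames are not contiguous")
        spans.append((int(idx[0]), int(idx.size)))
    return spans


@dataclass
class BranchedDataset:
    """Padded per-phase tensors for the phase-branched network.

    ``X[p]`` is (Lmax_p, N, k_p) with mask ``M[p]`` (Lmax_p, N); ``spans``
    holds each sample's (start, length) per phase on the 100-frame cycle;
    ``Y`` is (100, N, 3) normalized targets.
    """

    X: list[np.ndarray]
    M: list[np.ndarray]
    spans: np.ndarray  # (N, 4, 2)
    Y: np.ndarray

    @property
    def n(self) -> int:
        return self.Y.shape[1]


@dataclass
class WholeCycleDataset:
    """Whole-cycle tensors for the unbranched baseline."""

    X: np.ndarray  # (100, N, F)
    Y: np.ndarray  # (100, N, 3)

    @property
    def n(self) -> int:
        return self.Y.shape[1]


def assemble_branched(
    feature_rows: Sequence[np.ndarray],  # per trial (100, 240)
    labels: Sequence[np.ndarray],
    targets: Sequence[np.ndarray],  # per trial (100, 3), normalized CG
    phase_columns: dict[int, np.ndarray],
    input_normalizers: dict[int, MinMaxNormalizer],
    output_normalizer: MinMaxNormalizer,
    max_lengths: dict[int, int] | None = None,
) -> BranchedDataset:
    """Build padded branch tensors from per-trial features and labels.

    With ``max_lengths`` given (inference on a trained model), a phase
    segment longer than the trained maximum raises an error advising to
    re-pad (retrain with longer padding).
    """
    n = len(feature_rows)
    spans = np.zeros((n, 4, 2), dtype=int)
    for i, lab in enumerate(labels):
        for p, span in enumerate(_phase_spans(np.asarray(lab))):
            spans[i, p] = span
    if max_lengths is None:
        max_lengths = {phase: int(spans[:, p, 1].max())
                       for p, phase in enumerate(PHASES)}
    X, M = [], []
    for p, phase in enumerate(PHASES):
        Lmax = max_lengths[phase]
        too_long = spans[:, p, 1] > Lmax
        if too_long.any():
            raise ValueError(
                f"phase {phase} segment of length {spans[too_long, p, 1].max()} "
                f"exceeds the trained maximum {Lmax}; re-pad (retrain with "
                f"longer phase padding) to accept this cycle")
        cols = phase_columns[phase]
        Xp = np.zeros((Lmax, n, cols.size))
        Mp = np.zeros((Lmax, n))
        for i in range(n):
            start, length = spans[i, p]
            seg = feature_rows[i][start : start + length][:, cols]
            Xp[:length, i] = input_normalizers[phase].transform(seg)
            Mp[:length, i] = 1.0
        X.append(Xp)
        M.append(Mp)
    Y = np.stack([output_normalizer.transform(t) for t in targets], axis=1)
    return BranchedDataset(X=X, M=M, spans=spans, Y=Y)


class _NetBase:
    """Shared mini-batch plumbing over a list of layers."""

    layers: list

    def param_arrays(self) -> list[np.ndarray]:
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def loss_and_grads(self, data, idx):
        yhat = self._forward(data, idx)
        ytrue = data.Y[:, idx]
        resid = yhat - ytrue
        loss = float(np.mean(resid**2))
        grads = self._backward(2.0 * resid / resid.size)
        return loss, grads

    def evaluate(self, data) -> float:
        yhat = self.predict_normalized(data)
        return float(np.mean((yhat - data.Y) ** 2))

    def predict_normalized(self, data, batch: int = 64) -> np.ndarray:
        outs = []
        for start in range(0, data.n, batch):
            idx = np.arange(start, min(start + batch, data.n))
            outs.append(self._forward(data, idx))
        return np.concatenate(outs, axis=1)

    def n_samples(self, data) -> int:
        return data.n


class PhaseBranchedNet(_NetBase):
    """The proposed four-branch bidirectional LSTM with a combined trunk."""

    def __init__(self, spec: ModelSpec, seed: int):
        if len(spec.feature_counts) != 4:
            raise ValueError("phase-branched spec needs 4 feature counts")
        rng = np.random.default_rng(seed)
        self.spec = spec
        u1, u2 = spec.branch_units
        self.branches = []
        for k in spec.feature_counts:
            self.branches.append([
                BiLSTMLayer(rng, k, u1),
                BiLSTMLayer(rng, 2 * u1, u2),
            ])
        t1, t2 = spec.trunk_units
        self.trunk = [BiLSTMLayer(rng, 2 * u2, t1),
                      BiLSTMLayer(rng, 2 * t1, t2)]
        self.head = SigmoidDense(rng, 2 * t2, N_AXES)
        self.layers = [l for b in self.branches for l in b] + self.trunk \
            + [self.head]

    def _forward(self, data: BranchedDataset, idx: np.ndarray) -> np.ndarray:
        B = len(idx)
        width = 2 * self.spec.branch_units[1]
        trunk_in = np.zeros((N_FRAMES, B, width))
        self._spans = data.spans[idx]
        self._branch_shapes = []
        for p in range(4):
            h = data.X[p][:, idx]
            m = data.M[p][:, idx]
            for layer in self.branches[p]:
                h = layer.forward(h, m)
            self._branch_shapes.append(h.shape)
            for j in range(B):
                start, length = self._spans[j, p]
                trunk_in[start : start + length, j] = h[:length, j]
        h = trunk_in
        for layer in self.trunk:
            h = layer.forward(h)
        return self.head.forward(h)

    def _backward(self, dY: np.ndarray) -> list[np.ndarray]:
        dh, g_head = self.head.backward(dY)
        g_trunk = []
        for layer in reversed(self.trunk):
            dh, g = layer.backward(dh)
            g_trunk = g + g_trunk
        B = dh.shape[1]
        g_branches = []
        for p in range(3, -1, -1):
            dbr = np.zeros(self._branch_shapes[p])
            for j in range(B):
                start, length = self._spans[j, p]
                dbr[:length, j] = dh[start : start + length, j]
            g_p = []
            dcur = dbr
            for layer in reversed(self.branches[p]):
                dcur, g = layer.backward(dcur)
                g_p = g + g_p
            g_branches = g_p + g_branches
        return g_branches + g_trunk + g_head


class UnbranchedNet(_NetBase):
    """Whole-cycle baseline: the same layer budget without phase branches."""

    def __init__(self, spec: ModelSpec, seed: int):
        if len(spec.feature_counts) != 1:
            raise ValueError("unbranched spec takes a single feature count")
        rng = np.random.default_rng(seed)
        self.spec = spec
        u1, u2 = spec.branch_units
        t1, t2 = spec.trunk_units
        self.layers = [
            BiLSTMLayer(rng, spec.feature_counts[0], u1),
            BiLSTMLayer(rng, 2 * u1, u2),
            BiLSTMLayer(rng, 2 * u2, t1),
            BiLSTMLayer(rng, 2 * t1, t2),
            SigmoidDense(rng, 2 * t2, N_AXES),
        ]

    def _forward(self, data: WholeCycleDataset, idx: np.ndarray) -> np.ndarray:
        h = data.X[:, idx]
        for layer in self.layers[:-1]:
            h = layer.forward(h)
        return self.layers[-1].forward(h)

    def _backward(self, dY: np.ndarray) -> list[np.ndarray]:
        dh, grads = self.layers[-1].backward(dY)
        for layer in reversed(self.layers[:-1]):
            dh, g = layer.backward(dh)
            grads = g + grads
        return grads


@dataclass
class TrainedCGModel:
    """A fitted CG network with everything needed to predict new cycles."""

    net: PhaseBranchedNet | UnbranchedNet
    spec: ModelSpec
    phase_columns: dict[int, np.ndarray] | None  # None for unbranched
    feature_names: dict[int, list[str]] | None
    whole_cycle_columns: np.ndarray | None  # for the unbranched variant
    input_normalizers: dict[int, MinMaxNormalizer] | None
    whole_input_normalizer: MinMaxNormalizer | None
    output_normalizer: MinMaxNormalizer
    max_lengths: dict[int, int] | None
    history: TrainingHistory

    def predict(self, features: np.ndarray, labels: np.ndarray | None,
                leg_length: float) -> CGTrajectory:
        """Predict one cycle's CG from its (100, 240) feature matrix.

        Returns the trajectory in leg-length-normalized units with the mm
        version attached. The branched variant requires valid contiguous
        phase ``labels``.
        """
        if isinstance(self.net, PhaseBranchedNet):
            if labels is None:
                raise ValueError("the phase-branched model needs phase labels")
            data = assemble_branched(
                [features], [labels], [np.zeros((N_FRAMES, N_AXES))],
                self.phase_columns, self.input_normalizers,
                self.output_normalizer, self.max_lengths)
        else:
            x = self.whole_input_normalizer.transform(
                features[:, self.whole_cycle_columns])
            data = WholeCycleDataset(X=x[:, None, :],
                                     Y=np.zeros((N_FRAMES, 1, N_AXES)))
        yhat = self.net.predict_normalized(data)[:, 0]
        cg = self.output_normalizer.inverse(yhat)
        return CGTrajectory(cg=cg, cg_mm=cg * leg_length)

    def save(self, path: str | Path) -> None:
        """Write weights (npz) plus a JSON sidecar of everything else."""
        path = Path(path)
        arrays = {f"p{i}": a for i, a in enumerate(self.net.param_arrays())}
        np.savez(path.with_suffix(".npz"), **arrays)
        branched = isinstance(self.net, PhaseBranchedNet)
        sidecar = {
            "kind": "branched" if branched else "unbranched",
            "spec": asdict(self.spec),
            "output_normalizer": self.output_normalizer.to_dict(),
            "history": {"stop_epoch": self.history.stop_epoch,
                        "best_epoch": self.history.best_epoch,
                        "train_loss": self.history.train_loss,
                        "val_loss": self.history.val_loss},
        }
        if branched:
            sidecar["phase_columns"] = {
                str(p): c.tolist() for p, c in self.phase_columns.items()}
            sidecar["feature_names"] = (
                {str(p): n for p, n in self.feature_names.items()}
                if self.feature_names else None)
            sidecar["input_normalizers"] = {
                str(p): nm.to_dict() for p, nm in self.input_normalizers.items()}
            sidecar["max_lengths"] = {str(p): int(v)
                                      for p, v in self.max_lengths.items()}
        else:
            sidecar["whole_cycle_columns"] = self.whole_cycle_columns.tolist()
            sidecar["whole_input_normalizer"] = \
                self.whole_input_normalizer.to_dict()
        path.with_suffix(".json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, path: str | Path, seed: int = 0) -> "TrainedCGModel":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        spec_d = sidecar["spec"]
        for key in ("feature_counts", "branch_units", "trunk_units"):
            spec_d[key] = tuple(spec_d[key])
        spec = ModelSpec(**spec_d)
        branched = sidecar["kind"] == "branched"
        net = PhaseBranchedNet(spec, seed) if branched \
            else UnbranchedNet(spec, seed)
        with np.load(path.with_suffix(".npz")) as arc:
            for i, p in enumerate(net.param_arrays()):
                p[...] = arc[f"p{i}"]
        hist = TrainingHistory(
            train_loss=sidecar["history"]["train_loss"],
            val_loss=sidecar["history"]["val_loss"],
            stop_epoch=sidecar["history"]["stop_epoch"],
            best_epoch=sidecar["history"]["best_epoch"])
        kwargs = dict(net=net, spec=spec, phase_columns=None,
                      feature_names=None, whole_cycle_columns=None,
                      input_normalizers=None, whole_input_normalizer=None,
                      output_normalizer=MinMaxNormalizer.from_dict(
                          sidecar["output_normalizer"]),
                      max_lengths=None, history=hist)
        if branched:
            kwargs["phase_columns"] = {
                int(p): np.array(c)
                for p, c in sidecar["phase_columns"].items()}
            if sidecar.get("feature_names"):
                kwargs["feature_names"] = {
                    int(p): n for p, n in sidecar["feature_names"].items()}
            kwargs["input_normalizers"] = {
                int(p): MinMaxNormalizer.from_dict(d)
                for p, d in sidecar["input_normalizers"].items()}
            kwargs["max_lengths"] = {int(p): v for p, v in
                                     sidecar["max_lengths"].items()}
        else:
            kwargs["whole_cycle_columns"] = np.array(
                sidecar["whole_cycle_columns"])
            kwargs["whole_input_normalizer"] = MinMaxNormalizer.from_dict(
                sidecar["whole_input_normalizer"])
        return cls(**kwargs)


def train_cg_model(
    spec: ModelSpec,
    train_features: Sequence[np.ndarray],
    train_labels: Sequence[np.ndarray] | None,
    train_cg: Sequence[np.ndarray],
    val_features: Sequence[np.ndarray],
    val_labels: Sequence[np.ndarray] | None,
    val_cg: Sequence[np.ndarray],
    seed: int,
    phase_columns: dict[int, np.ndarray] | None = None,
    feature_names: Sequence[str] | None = None,
    whole_cycle_columns: np.ndarray | None = None,
) -> TrainedCGModel:
    """Fit the branched (``phase_columns`` given) or unbranched CG network.

    Features are per-trial (100, 240) matrices; ``train_cg``/``val_cg`` are
    leg-length-normalized trajectories. Normalization constants are fitted
    on the training set only. Deterministic for a fixed seed.
    """
    out_norm = MinMaxNormalizer.fit(np.vstack(train_cg))
    branched = phase_columns is not None
    if branched:
        if train_labels is None or val_labels is None:
            raise ValueError("phase labels required for the branched model")
        in_norms = {}
        for phase in PHASES:
            cols = phase_columns[phase]
            pooled = np.vstack([
                f[np.asarray(lab) == phase][:, cols]
                for f, lab in zip(train_features, train_labels)])
            in_norms[phase] = MinMaxNormalizer.fit(pooled)
        observed = {}
        for phase in PHASES:
            observed[phase] = max(
                int(np.sum(np.asarray(lab) == phase))
                for lab in train_labels)
        max_lengths = {phase: observed[phase] + spec.phase_length_margin
                       for phase in PHASES}
        train_data = assemble_branched(train_features, train_labels, train_cg,
                                       phase_columns, in_norms, out_norm,
                                       max_lengths)
        val_data = assemble_branched(val_features, val_labels, val_cg,
                                     phase_columns, in_norms, out_norm,
                                     max_lengths)
        net = PhaseBranchedNet(spec, seed)
        names = None
        if feature_names is not None:
            names = {phase: [feature_names[i] for i in phase_columns[phase]]
                     for phase in PHASES}
        model = TrainedCGModel(
            net=net, spec=spec, phase_columns=phase_columns,
            feature_names=names, whole_cycle_columns=None,
            input_normalizers=in_norms, whole_input_normalizer=None,
            output_normalizer=out_norm, max_lengths=max_lengths,
            history=TrainingHistory())
    else:
        cols = (whole_cycle_columns if whole_cycle_columns is not None
                else np.arange(train_features[0].shape[1]))
        in_norm = MinMaxNormalizer.fit(np.vstack(train_features)[:, cols])
        train_data = WholeCycleDataset(
            X=np.stack([in_norm.transform(f[:, cols])
                        for f in train_features], axis=1),
            Y=np.stack([out_norm.transform(t) for t in train_cg], axis=1))
        val_data = WholeCycleDataset(
            X=np.stack([in_norm.transform(f[:, cols])
                        for f in val_features], axis=1),
            Y=np.stack([out_norm.transform(t) for t in val_cg], axis=1))
        net = UnbranchedNet(spec, seed)
        model = TrainedCGModel(
            net=net, spec=spec, phase_columns=None, feature_names=None,
            whole_cycle_columns=cols, input_normalizers=None,
            whole_input_normalizer=in_norm, output_normalizer=out_norm,
            max_lengths=None, history=TrainingHistory())
    model.history = fit_model(
        net, train_data, val_data, seed,
        batch_size=spec.batch_size, learning_rate=spec.learning_rate,
        max_epochs=spec.max_epochs, plateau_patience=spec.plateau_patience,
        plateau_factor=spec.plateau_factor, min_lr=spec.min_lr,
        early_stop_patience=spec.early_stop_patience)
    return model
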