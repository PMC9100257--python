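"""Windowed feature candidates, mutual-information ranking and selection.

From the 30 per-frame insole parameters, a 5-frame sliding window yields 7
time-domain statistics per parameter (average, max, min, range, mean
absolute deviation, kurtosis, skewness) = 210 windowed features; adding the
raw value at the window's last frame gives 240 candidates per frame.

Candidates are ranked per gait phase by the discrete mutual information
(MI) between each candidate and each CG axis over the phase's pooled
frames:

    I(X, Y) = sum_{x, y} p(x, y) log2[ p(x, y) / (p(x) p(y)) ]

with both variables discretized into equal-frequency bins. Per-axis MI
scores are min-max scaled to [0, 1] across the 240 candidates and averaged
over the three axes; the per-phase feature count is then chosen by
minimizing a support-vector-regression rRMSE objective on validation data.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.svm import SVR

from .gait_params import ParameterSeries
from .phases import PHASES

__all__ = [
    "STATISTICS",
    "FeatureMatrix",
    "MIEstimate",
    "PhaseFeatureSelection",
    "extract_window_features",
    "mutual_information",
    "rank_features_per_phase",
    "optimize_feature_count",
]

#: Window statistics, in column order within each parameter's block.
STATISTICS = ("average", "max", "min", "range", "mad", "kurtosis",
              "skewness", "raw")


@dataclass(frozen=True)
class FeatureMatrix:
    """Per-frame feature candidates of one cycle (100 x 240)."""

    values: np.ndarray
    names: tuple[str, ...]
    window: int = 5

    def __post_init__(self) -> None:
        if self.values.shape[1] != len(self.names):
            raise ValueError("feature values and names disagree")


def extract_window_features(params: ParameterSeries, window: int = 5
                            ) -> FeatureMatrix:
    """Sliding-window statistics of every parameter (stride 1).

    The window at frame ``t`` covers frames ``[t - window + 1, t]``; the
    first ``window - 1`` frames replicate frame 0 so the output stays
    frame-aligned with the input. Zero-variance windows take kurtosis and
    skewness 0 (the degenerate-window convention). Column order is
    parameter-major: for each of the 30 parameters, the 7 window statistics
    followed by the raw (window-last) value.
    """
    if window < 2:
        raise ValueError("window must span at least 2 frames")
    x = np.asarray(params.values, dtype=float)
    if x.shape[0] < window:
        raise ValueError("need at least one full window of frames")
    padded = np.vstack([np.repeat(x[:1], window - 1, axis=0), x])
    win = sliding_window_view(padded, window, axis=0)  # (T, 30, window)
    mean = win.mean(axis=2)
    mx = win.max(axis=2)
    mn = win.min(axis=2)
    dev = win - mean[..., None]
    mad = np.abs(dev).mean(axis=2)
    m2 = (dev**2).mean(axis=2)
    m3 = (dev**3).mean(axis=2)
    m4 = (dev**4).mean(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        skew = np.where(m2 > 1e-24, m3 / np.where(m2 > 0, m2, 1.0) ** 1.5, 0.0)
        kurt = np.where(m2 > 1e-24, m4 / np.where(m2 > 0, m2, 1.0) ** 2 - 3.0,
                        0.0)
    stats = {"average": mean, "max": mx, "min": mn, "range": mx - mn,
             "mad": mad, "kurtosis": kurt, "skewness": skew, "raw": x}
    cols = []
    names = []
    for j, pname in enumerate(params.names):
        for stat in STATISTICS:
            cols.append(stats[stat][:, j])
            names.append(f"{pname}:{stat}")
    return FeatureMatrix(values=np.column_stack(cols), names=tuple(names),
                         window=window)


@dataclass(frozen=True)
class MIEstimate:
    """A discrete mutual-information estimate with its histogram tables."""

    value: float  # bits
    joint: np.ndarray  # p(x, y)
    px: np.ndarray
    py: np.ndarray
    x_edges: np.ndarray
    y_edges: np.ndarray


def _equal_frequency_edges(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Interior quantile cut points (duplicates collapsed)."""
    qs = np.linspace(0.0, 1.0, n_bins + 1)[1:-1]
    return np.unique(np.quantile(x, qs))


def mutual_information(x: np.ndarray, y: np.ndarray, n_bins: int = 10
                       ) -> MIEstimate:
    """Discrete MI (bits) after equal-frequency binning of both series."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("series must have equal length")
    if x.size < n_bins:
        raise ValueError(f"need at least n_bins={n_bins} samples")
    ex = _equal_frequency_edges(x, n_bins)
    ey = _equal_frequency_edges(y, n_bins)
    if x.min() == x.max() or y.min() == y.max():
        warnings.warn("degenerate binning (constant series); MI is 0",
                      stacklevel=2)
    xi = np.searchsorted(ex, x, side="right")
    yi = np.searchsorted(ey, y, side="right")
    nx, ny = ex.size + 1, ey.size + 1
    joint = np.bincount(xi * ny + yi, minlength=nx * ny).reshape(nx, ny)
    joint = joint / joint.sum()
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    outer = np.outer(px, py)
    value = float(np.sum(joint[nz] * np.log2(joint[nz] / outer[nz])))
    return MIEstimate(value=max(value, 0.0), joint=joint, px=px, py=py,
                      x_edges=ex, y_edges=ey)


@dataclass
class PhaseFeatureSelection:
    """Per-phase candidate ranking, scores and chosen feature counts."""

    feature_names: tuple[str, ...]
    order: dict[int, np.ndarray] = field(default_factory=dict)  # ranked idx
    scores: dict[int, np.ndarray] = field(default_factory=dict)  # in rank order
    axis_mi: dict[int, np.ndarray] = field(default_factory=dict)  # (240, 3) raw
    chosen_k: dict[int, int] = field(default_factory=dict)
    error_curves: dict[int, dict[int, float]] = field(default_factory=dict)

    def selected(self, phase: int) -> np.ndarray:
        """Column indices of the chosen top-k candidates for ``phase``."""
        return self.order[phase][: self.chosen_k[phase]]

    def selected_names(self, phase: int) -> list[str]:
        return [self.feature_names[i] for i in self.selected(phase)]

    def to_json(self, path: str | Path) -> None:
        payload = {
            str(p): {
                "ranked_names": [self.feature_names[i] for i in self.order[p]],
                "scores": self.scores[p].tolist(),
                "chosen_k": self.chosen_k.get(p),
                "error_curve": {str(k): v for k, v in
                                self.error_curves.get(p, {}).items()},
            }
            for p in self.order
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def rank_features_per_phase(
    features: np.ndarray,
    cg: np.ndarray,
    phase_labels: np.ndarray,
    feature_names: Sequence[str],
    n_bins: int = 10,
) -> PhaseFeatureSelection:
    """Rank the candidates per phase by axis-averaged, scaled MI.

    ``features`` (N x 240), ``cg`` (N x 3) and ``phase_labels`` (N,) are
    frames pooled over all training trials. For each phase and CG axis, the
    MI between every candidate and the axis is computed over the phase's
    frames, min-max scaled to [0, 1] across candidates, and averaged over
    the three axes. Ranking is by descending score, ties broken by
    candidate index.
    """
    features = np.asarray(features, dtype=float)
    cg = np.asarray(cg, dtype=float)
    phase_labels = np.asarray(phase_labels)
    sel = PhaseFeatureSelection(feature_names=tuple(feature_names))
    n_feat = features.shape[1]
    for phase in PHASES:
        rows = phase_labels == phase
        if rows.sum() < n_bins:
            raise ValueError(f"phase {phase} has fewer than {n_bins} frames")
        F = features[rows]
        Y = cg[rows]
        mi = np.empty((n_feat, 3))
        for a in range(3):
            for j in range(n_feat):
                mi[j, a] = mutual_information(F[:, j], Y[:, a], n_bins).value
        lo = mi.min(axis=0)
        span = mi.max(axis=0) - lo
        span[span == 0] = 1.0
        scaled = (mi - lo) / span
        score = scaled.mean(axis=1)
        order = np.lexsort((np.arange(n_feat), -score))
        sel.order[phase] = order
        sel.scores[phase] = score[order]
        sel.axis_mi[phase] = mi
    return sel


def _rrmse(pred: np.ndarray, ref: np.ndarray) -> float:
    rmse = float(np.sqrt(np.mean((pred - ref) ** 2)))
    span = float(ref.max() - ref.min())
    if span == 0:
        raise ValueError("reference range is zero; rRMSE undefined")
    return 100.0 * rmse / span


def optimize_feature_count(
    selection: PhaseFeatureSelection,
    candidate_counts: Sequence[int],
    train: tuple[np.ndarray, np.ndarray, np.ndarray],
    validation: tuple[np.ndarray, np.ndarray, np.ndarray],
    max_train_frames: int = 2000,
    svr_params: dict | None = None,
    seed: int = 0,
) -> PhaseFeatureSelection:
    """Choose each phase's feature count k by an SVR rRMSE objective.

    For every candidate count k, one RBF support-vector regressor per CG
    axis is fitted on the phase's training frames restricted to the top-k
    candidates, and the mean 3-axis rRMSE on the validation frames is
    recorded; the smallest k attaining the minimum is chosen. ``train`` and
    ``validation`` are (features, cg, phase_labels) triples pooled over
    disjoint subject sets. Training frames are subsampled to
    ``max_train_frames`` to bound the SVR cost.

    Features and targets are min-max scaled to [0, 1] with training-frame
    constants before the SVR fit (the protocol's normalization convention;
    without it the epsilon tube dwarfs the leg-length-normalized
    medial/lateral and vertical excursions and the objective goes blind on
    those axes). The rRMSE is computed on the scaled axes; range
    normalization makes it invariant to the scaling.
    """
    counts = sorted(set(int(k) for k in candidate_counts))
    if not counts:
        raise ValueError("candidate_counts must be non-empty")
    params = dict(kernel="rbf", C=1.0, epsilon=0.01, gamma="scale")
    if svr_params:
        params.update(svr_params)
    Xtr, Ytr, Ptr = train
    Xva, Yva, Pva = validation
    rng = np.random.default_rng(seed)
    for phase in PHASES:
        tr = np.flatnonzero(Ptr == phase)
        va = np.flatnonzero(Pva == phase)
        if tr.size == 0 or va.size == 0:
            raise ValueError(f"phase {phase} missing from train or validation")
        if tr.size > max_train_frames:
            tr = np.sort(rng.choice(tr, size=max_train_frames, replace=False))
        order = selection.order[phase]
        kmax = max(counts)
        cols = order[:kmax]
        Xtr_p = Xtr[np.ix_(tr, cols)]
        Xva_p = Xva[np.ix_(va, cols)]
        f_lo = Xtr_p.min(axis=0)
        f_span = Xtr_p.max(axis=0) - f_lo
        f_span[f_span == 0] = 1.0
        Xtr_p = (Xtr_p - f_lo) / f_span
        Xva_p = (Xva_p - f_lo) / f_span
        y_lo = Ytr[tr].min(axis=0)
        y_span = Ytr[tr].max(axis=0) - y_lo
        y_span[y_span == 0] = 1.0
        Ytr_p = (Ytr[tr] - y_lo) / y_span
        Yva_p = (Yva[va] - y_lo) / y_span
        curve: dict[int, float] = {}
        for k in counts:
            errs = []
            for a in range(3):
                svr = SVR(**params)
                svr.fit(Xtr_p[:, :k], Ytr_p[:, a])
                pred = svr.predict(Xva_p[:, :k])
                errs.append(_rrmse(pred, Yva_p[:, a]))
            curve[k] = float(np.mean(errs))
        best = min(curve, key=lambda k: (curve[k], k))
        selection.chosen_k[phase] = best
        selection.error_curves[phase] = curve
    return selection
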