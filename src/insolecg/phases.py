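"""Four-phase gait segmentation and the pressure-based phase classifier.

A gait cycle is split into four contiguous phases delimited by right heel
strike, right mid-stance, left heel strike and left mid-stance:

1. right heel strike -> right mid-stance,
2. right mid-stance -> left heel strike,
3. left heel strike -> left mid-stance,
4. left mid-stance -> next right heel strike.

Phase boundaries coincide with the poles of the vertical CG trajectory, so
each phase has homogeneous CG mechanics. At inference time, where no
kinematic events are available, an SVM trained on the 240 windowed feature
candidates assigns the phase from insole pressures alone; a contiguity
repair pass enforces the four-contiguous-blocks structure the downstream
phase-branched model requires.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support
from sklearn.model_selection import GridSearchCV, GroupKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC

from .synthetic import GaitEventSchedule

__all__ = [
    "PHASES",
    "label_phases",
    "full_search_grid",
    "PhaseClassifier",
    "train_phase_classifier",
    "classify_phases",
    "repair_contiguity",
    "phase_classification_report",
]

PHASES = (1, 2, 3, 4)


def label_phases(events: GaitEventSchedule, n_frames: int = 100) -> np.ndarray:
    """Per-frame phase labels {1..4} from a gait-event schedule."""
    bounds = (events.r_midstance_frame, events.lhs_frame,
              events.l_midstance_frame)
    labels = np.empty(n_frames, dtype=int)
    prev = 0
    for phase, b in zip((1, 2, 3), bounds):
        labels[prev:b] = phase
        prev = b
    labels[prev:] = 4
    return labels


def full_search_grid() -> list[dict]:
    """The full SVM hyperparameter candidate grid for grid search.

    C in {0.1, 1, 100, 1000}; kernels rbf/poly/sigmoid/linear; polynomial
    degrees 1-6; gamma in {1, 0.1, 0.01, 0.001, 0.0001}.
    """
    C = [0.1, 1, 100, 1000]
    gamma = [1, 0.1, 0.01, 0.001, 0.0001]
    return [
        {"svm__C": C, "svm__kernel": ["rbf", "sigmoid"], "svm__gamma": gamma},
        {"svm__C": C, "svm__kernel": ["poly"], "svm__gamma": gamma,
         "svm__degree": [1, 2, 3, 4, 5, 6]},
        {"svm__C": C, "svm__kernel": ["linear"]},
    ]


def default_search_grid() -> list[dict]:
    """Degenerate grid holding only the selected optimum (C=1, rbf, gamma=0.1)."""
    return [{"svm__C": [1], "svm__kernel": ["rbf"], "svm__gamma": [0.1]}]


@dataclass
class PhaseClassifier:
    """A fitted phase SVM with its hyperparameters and feature schema."""

    pipeline: Pipeline
    hyperparameters: dict
    feature_names: tuple[str, ...]
    cv_accuracy: float | None = None

    def save(self, path: str | Path) -> None:
        Path(path).write_bytes(pickle.dumps(self))

    @classmethod
    def load(cls, path: str | Path) -> "PhaseClassifier":
        obj = pickle.loads(Path(path).read_bytes())
        if not isinstance(obj, cls):
            raise TypeError(f"{path} does not hold a {cls.__name__}")
        return obj


def train_phase_classifier(
    features: np.ndarray,
    labels: np.ndarray,
    feature_names: Sequence[str],
    groups: np.ndarray | None = None,
    grid: list[dict] | None = None,
    n_folds: int = 5,
    evaluate_cv: bool = False,
) -> PhaseClassifier:
    """Grid-search and fit the phase SVM.

    ``features`` are pooled frames x 240 candidates; ``groups`` are
    subject identifiers per frame so that cross-validation folds split
    subjects, never frames. Inputs are min-max scaled to [0, 1] before the SVM (the
    candidate features span several orders of magnitude). With a
    single-combination grid the search degenerates to a plain fit.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("phase training needs at least two classes")
    if features.shape[0] != labels.shape[0]:
        raise ValueError("features and labels are not frame-aligned")
    grid = grid if grid is not None else default_search_grid()
    pipe = Pipeline([("scale", MinMaxScaler()), ("svm", SVC())])
    n_combos = sum(
        int(np.prod([len(v) for v in block.values()])) for block in grid
    )
    if n_combos == 1:
        params = {k: v[0] for block in grid for k, v in block.items()}
        pipe.set_params(**params)
        if evaluate_cv and groups is not None \
                and len(np.unique(groups)) >= 2:
            from sklearn.model_selection import cross_val_score

            cv = GroupKFold(n_splits=min(n_folds, len(np.unique(groups))))
            scores = cross_val_score(pipe, features, labels, cv=cv,
                                     groups=groups)
            cv_acc = float(np.mean(scores))
        else:
            cv_acc = None
        pipe.fit(features, labels)
        best_params = params
    else:
        if groups is None:
            raise ValueError("grid search requires subject groups for "
                             "subject-level folds")
        cv = GroupKFold(n_splits=min(n_folds, len(np.unique(groups))))
        search = GridSearchCV(pipe, grid, cv=cv, n_jobs=1)
        search.fit(features, labels, groups=groups)
        pipe = search.best_estimator_
        best_params = dict(search.best_params_)
        cv_acc = float(search.best_score_)
    hyper = {k.removeprefix("svm__"): v for k, v in best_params.items()
             if k.startswith("svm__")}
    return PhaseClassifier(pipeline=pipe, hyperparameters=hyper,
                           feature_names=tuple(feature_names),
                           cv_accuracy=cv_acc)


def repair_contiguity(labels: np.ndarray, window: int = 5) -> np.ndarray:
    """Enforce the four-contiguous-blocks phase structure.

    First a centered majority vote over ``window`` frames removes isolated
    flips, then dynamic programming finds the monotone 1->2->3->4 block
    sequence (each phase non-empty) minimizing disagreement with the
    smoothed labels. The block structure is only enforced when all four
    phases survive smoothing (a partial-cycle fragment keeps its smoothed
    labels).
    """
    labels = np.asarray(labels, dtype=int)
    n = len(labels)
    half = window // 2
    smoothed = np.empty_like(labels)
    for t in range(n):
        lo, hi = max(0, t - half), min(n, t + half + 1)
        vals, counts = np.unique(labels[lo:hi], return_counts=True)
        smoothed[t] = vals[np.argmax(counts)]
    if set(np.unique(smoothed)) != set(PHASES):
        return smoothed
    # cost[p][t]: frames in [0, t) mislabeled, ending inside phase block p
    mismatch = np.stack([(smoothed != p).astype(int) for p in PHASES])
    INF = n + 1
    cost = np.full((4, n + 1), INF)
    choice = np.zeros((4, n + 1), dtype=int)
    run = np.zeros(n + 1, dtype=int)
    np.cumsum(mismatch[0], out=run[1:])
    cost[0] = run
    for p in range(1, 4):
        for t in range(p + 1, n + 1):
            # either extend phase p's block or switch from phase p-1 at t-1
            extend = cost[p, t - 1] + mismatch[p, t - 1]
            switch = cost[p - 1, t - 1] + mismatch[p, t - 1]
            if switch < extend:
                cost[p, t] = switch
                choice[p, t] = 1
            else:
                cost[p, t] = extend
    out = np.empty(n, dtype=int)
    p = 3
    for t in range(n, 0, -1):
        out[t - 1] = PHASES[p]
        if p > 0 and choice[p, t]:
            p -= 1
    return out


def classify_phases(model: PhaseClassifier, features: np.ndarray,
                    feature_names: Sequence[str] | None = None,
                    repair: bool = True) -> np.ndarray:
    """Predict per-frame phases for one cycle's feature rows."""
    if feature_names is not None and tuple(feature_names) != model.feature_names:
        raise ValueError("feature schema differs from the classifier's "
                         "training schema")
    if features.shape[1] != len(model.feature_names):
        raise ValueError(
            f"expected {len(model.feature_names)} features, "
            f"got {features.shape[1]}")
    pred = model.pipeline.predict(features)
    return repair_contiguity(pred) if repair else pred


def phase_classification_report(predicted: np.ndarray, truth: np.ndarray
                                ) -> dict:
    """Precision/recall/f1 per phase plus the confusion matrix.

    Confusion-matrix rows are the true phases, columns the predicted ones.
    """
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth must have equal length")
    prec, rec, f1, support = precision_recall_fscore_support(
        truth, predicted, labels=list(PHASES), zero_division=0)
    cm = confusion_matrix(truth, predicted, labels=list(PHASES))
    return {
        "precision": dict(zip(PHASES, prec.tolist())),
        "recall": dict(zip(PHASES, rec.tolist())),
        "f1": dict(zip(PHASES, f1.tolist())),
        "support": dict(zip(PHASES, support.tolist())),
        "confusion_matrix": cm,
        "accuracy": float(np.mean(predicted == truth)),
    }
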