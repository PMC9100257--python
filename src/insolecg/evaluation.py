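"""Trajectory metrics, comparative baselines and group analysis.

Prediction quality is scored per axis by the Pearson correlation, the RMSE
in mm, and the relative RMSE (rRMSE), defined by default as the RMSE as a
percentage of the reference trajectory's peak-to-valley excursion on the
same axis (a mean-normalized variant is available). The comparative study
re-runs the CG prediction with four whole-cycle feature-selection baselines
(none / recursive feature elimination / mutual information / elastic net)
against the phase-branched protocol under one shared seed and identical
training budgets. Group analysis compares young vs. old peak-to-valley
(PV) sway ranges with a Welch two-sample test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.linear_model import ElasticNetCV
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVR

from .features import mutual_information

__all__ = [
    "AXES",
    "trajectory_metrics",
    "pv_range",
    "group_difference_test",
    "EvalReport",
    "summarize_trials",
    "select_whole_cycle_features",
]

AXES = ("anterior_posterior", "medial_lateral", "proximal_distal")


def trajectory_metrics(predicted_mm: np.ndarray, reference_mm: np.ndarray,
                       rrmse_mode: str = "range") -> dict[str, dict[str, float]]:
    """Per-axis correlation, RMSE (mm) and rRMSE (%) of one cycle.

    ``rrmse_mode`` "range" divides the RMSE by the reference axis's
    peak-to-valley excursion over the cycle; "mean" divides by the absolute
    mean of the reference. A zero normalizer flags the axis's rRMSE as NaN.
    """
    pred = np.asarray(predicted_mm, dtype=float)
    ref = np.asarray(reference_mm, dtype=float)
    if pred.shape != ref.shape:
        raise ValueError("predicted and reference frame counts differ")
    out = {}
    for a, axis in enumerate(AXES):
        p, r = pred[:, a], ref[:, a]
        rmse = float(np.sqrt(np.mean((p - r) ** 2)))
        if np.std(p) == 0 or np.std(r) == 0:
            corr = np.nan
        else:
            corr = float(np.corrcoef(p, r)[0, 1])
        if rrmse_mode == "range":
            norm = float(r.max() - r.min())
        elif rrmse_mode == "mean":
            norm = float(abs(r.mean()))
        else:
            raise ValueError(f"unknown rRMSE mode {rrmse_mode!r}")
        rrmse = 100.0 * rmse / norm if norm > 0 else np.nan
        out[axis] = {"r": corr, "rmse_mm": rmse, "rrmse_pct": rrmse}
    return out


def pv_range(axis_mm: np.ndarray) -> float:
    """Peak-to-valley range: global max minus global min over the cycle."""
    x = np.asarray(axis_mm, dtype=float)
    if x.size == 0:
        raise ValueError("empty trajectory")
    return float(x.max() - x.min())


def group_difference_test(pv_young: Sequence[float], pv_old: Sequence[float]
                          ) -> dict:
    """Welch two-sample comparison of PV ranges with its direction.

    Returns the p-value and the direction of the mean difference
    ("old_gt_young", "young_gt_old" or "none").
    """
    a = np.asarray(pv_young, dtype=float)
    b = np.asarray(pv_old, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    if np.std(a) == 0 and np.std(b) == 0:
        p = 1.0 if a.mean() == b.mean() else 0.0
    else:
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    diff = float(b.mean() - a.mean())
    if diff > 0:
        direction = "old_gt_young"
    elif diff < 0:
        direction = "young_gt_old"
    else:
        direction = "none"
    return {"p_value": p, "direction": direction, "mean_diff_mm": diff}


@dataclass
class EvalReport:
    """Per-axis summary across trials, pooled and per group.

    Correlations are summarized as mean with (min-max) range; RMSE and
    rRMSE as mean +/- sd, following the usual gait-study presentation.
    """

    per_trial: list[dict] = field(default_factory=list)  # metric dicts
    groups: list[str] = field(default_factory=list)

    def add(self, metrics: dict, group: str) -> None:
        self.per_trial.append(metrics)
        self.groups.append(group)

    def summary(self, group: str | None = None) -> dict:
        rows = [m for m, g in zip(self.per_trial, self.groups)
                if group is None or g == group]
        if not rows:
            raise ValueError(f"no trials for group {group!r}")
        out = {}
        for axis in AXES:
            rs = np.array([m[axis]["r"] for m in rows])
            rmses = np.array([m[axis]["rmse_mm"] for m in rows])
            rrmses = np.array([m[axis]["rrmse_pct"] for m in rows])
            out[axis] = {
                "r_mean": float(np.nanmean(rs)),
                "r_min": float(np.nanmin(rs)),
                "r_max": float(np.nanmax(rs)),
                "rmse_mm_mean": float(np.mean(rmses)),
                "rmse_mm_sd": float(np.std(rmses, ddof=1)) if len(rows) > 1 else 0.0,
                "rrmse_pct_mean": float(np.nanmean(rrmses)),
                "rrmse_pct_sd": float(np.nanstd(rrmses, ddof=1)) if len(rows) > 1 else 0.0,
            }
        return out

    def to_dict(self) -> dict:
        d = {"pooled": self.summary()}
        for g in sorted(set(self.groups)):
            d[g] = self.summary(g)
        return d


def summarize_trials(predictions_mm: Sequence[np.ndarray],
                     references_mm: Sequence[np.ndarray],
                     groups: Sequence[str],
                     rrmse_mode: str = "range") -> EvalReport:
    """Build an :class:`EvalReport` from paired trajectory lists."""
    report = EvalReport()
    for pred, ref, g in zip(predictions_mm, references_mm, groups):
        report.add(trajectory_metrics(pred, ref, rrmse_mode), g)
    return report


def select_whole_cycle_features(
    method: str,
    features: np.ndarray,  # pooled frames x 240
    cg: np.ndarray,  # pooled frames x 3
    k: int,
    seed: int = 0,
    n_bins: int = 10,
    elastic_l1_ratio: float = 0.5,
    max_frames: int = 3000,
) -> np.ndarray:
    """Whole-cycle feature selection for the comparative baselines.

    ``none`` keeps all candidates. ``mi`` ranks by axis-averaged scaled
    mutual information over the whole cycle and keeps the top k. ``rfe``
    recursively eliminates the least important fifth of the remaining
    candidates until k are left, scoring importance as the summed
    absolute coefficients of one linear support-vector regressor per axis.
    ``ela`` keeps features with a nonzero elastic-net coefficient on any
    axis (L1/L2 mixing 0.5, penalty cross-validated), falling back to the
    k largest |coefficient| if none survive.
    """
    n_feat = features.shape[1]
    if method == "none" or k >= n_feat:
        return np.arange(n_feat)
    rng = np.random.default_rng(seed)
    if features.shape[0] > max_frames:
        rows = np.sort(rng.choice(features.shape[0], max_frames,
                                  replace=False))
        features, cg = features[rows], cg[rows]
    if method == "mi":
        mi = np.empty((n_feat, 3))
        for a in range(3):
            for j in range(n_feat):
                mi[j, a] = mutual_information(features[:, j], cg[:, a],
                                              n_bins).value
        lo, hi = mi.min(axis=0), mi.max(axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)
        score = ((mi - lo) / span).mean(axis=1)
        return np.sort(np.lexsort((np.arange(n_feat), -score))[:k])
    X = StandardScaler().fit_transform(features)
    if method == "rfe":
        remaining = np.arange(n_feat)
        while remaining.size > k:
            importance = np.zeros(remaining.size)
            for a in range(3):
                svr = LinearSVR(dual="auto", random_state=0, max_iter=5000)
                svr.fit(X[:, remaining], cg[:, a])
                importance += np.abs(svr.coef_)
            n_drop = min(remaining.size - k,
                         max(1, int(0.2 * remaining.size)))
            drop = np.argsort(importance)[:n_drop]
            remaining = np.delete(remaining, drop)
        return np.sort(remaining)
    if method == "ela":
        support = np.zeros(n_feat, dtype=bool)
        mags = np.zeros(n_feat)
        for a in range(3):
            enet = ElasticNetCV(l1_ratio=elastic_l1_ratio, alphas=30,
                                cv=3, random_state=0, max_iter=5000)
            enet.fit(X, cg[:, a])
            support |= enet.coef_ != 0
            mags += np.abs(enet.coef_)
        if not support.any():
            return np.sort(np.argsort(-mags)[:k])
        return np.flatnonzero(support)
    raise ValueError(f"unknown feature-selection method {method!r}")
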