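"""Filtering, segmentation and normalization of pressure and CG series.

The preprocessing contract mirrors standard gait-lab practice: 4th-order
zero-phase Butterworth lowpass filtering (7 Hz for pressures, 10 Hz for CG
marker channels), extraction of right-heel-strike-to-right-heel-strike
cycles, linear time normalization to 100 frames, pressure normalization by
body-weight force, transformation of the CG into a gait-local frame (origin
at the double-support midpoint, x along the horizontal walking direction,
z vertical, y = z x x), and leg-length normalization of the CG.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .synthetic import (GRAVITY, GaitEventSchedule, SubjectProfile,
                        SyntheticTrial)

__all__ = [
    "PreprocessingConfig",
    "PressureCycle",
    "CGTrajectory",
    "GaitSample",
    "lowpass_filter",
    "extract_cycle",
    "time_normalize",
    "normalize_pressure_by_weight",
    "cg_to_local_frame",
    "normalize_cg_by_leg_length",
    "preprocess_trial",
]


@dataclass(frozen=True)
class PreprocessingConfig:
    sample_rate_hz: float = 100.0
    pressure_cutoff_hz: float = 7.0
    cg_cutoff_hz: float = 10.0
    filter_order: int = 4
    n_frames: int = 100
    #: "force" divides pressures by weight * g (N); "mass" divides by kg.
    weight_mode: str = "force"


@dataclass(frozen=True)
class PressureCycle:
    """One time-normalized gait cycle of weight-normalized pressures."""

    pressures: np.ndarray  # (100, 18), dimensionless (fraction of body weight)
    subject: SubjectProfile
    events: GaitEventSchedule

    def __post_init__(self) -> None:
        if self.pressures.shape[0] != 100:
            raise ValueError("a pressure cycle must have exactly 100 frames")
        if np.any(self.pressures < 0):
            raise ValueError("pressures must be non-negative")


@dataclass(frozen=True)
class CGTrajectory:
    """100-frame CG in the local gait frame.

    ``cg`` is leg-length-normalized (dimensionless), ``cg_mm`` the same
    trajectory in mm; axes are (anterior/posterior, medial/lateral,
    proximal/distal).
    """

    cg: np.ndarray  # (100, 3)
    cg_mm: np.ndarray  # (100, 3)

    def __post_init__(self) -> None:
        if self.cg.shape != (100, 3) or self.cg_mm.shape != (100, 3):
            raise ValueError("a CG trajectory must be 100 frames x 3 axes")


@dataclass
class GaitSample:
    """A preprocessed trial: the unit consumed by downstream stages."""

    cycle: PressureCycle
    cg: CGTrajectory
    labels: np.ndarray | None = None  # per-frame gait-phase labels {1..4}


def lowpass_filter(x: np.ndarray, sample_rate: float, cutoff: float,
                   order: int = 4) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth lowpass along axis 0."""
    if cutoff >= sample_rate / 2.0:
        raise ValueError(f"cutoff {cutoff} Hz >= Nyquist ({sample_rate / 2} Hz)")
    x = np.asarray(x, dtype=float)
    if x.shape[0] <= 3 * order:
        raise ValueError("signal too short for the requested filter order")
    sos = sps.butter(order, cutoff, btype="low", fs=sample_rate, output="sos")
    return sps.sosfiltfilt(sos, x, axis=0)


def extract_cycle(x: np.ndarray, heel_strikes: tuple[int, int]) -> np.ndarray:
    """Half-open segment ``[hs1, hs2)`` of a (frames, channels) signal."""
    hs1, hs2 = heel_strikes
    if not 0 <= hs1 < hs2 <= len(x):
        raise ValueError(f"invalid heel-strike indices {heel_strikes} "
                         f"for a {len(x)}-frame signal")
    return np.asarray(x)[hs1:hs2]


def time_normalize(x: np.ndarray, n_frames: int = 100) -> np.ndarray:
    """Linearly resample a cycle to ``n_frames``, preserving the endpoints."""
    x = np.asarray(x, dtype=float)
    n_in = x.shape[0]
    if n_in < 2:
        raise ValueError("need at least 2 frames to time-normalize")
    if n_in == n_frames:
        return x.copy()
    grid = np.linspace(0.0, n_in - 1.0, n_frames)
    base = np.arange(n_in, dtype=float)
    if x.ndim == 1:
        return np.interp(grid, base, x)
    return np.column_stack([np.interp(grid, base, x[:, c])
                            for c in range(x.shape[1])])


def normalize_pressure_by_weight(pressures: np.ndarray, weight: float,
                                 mode: str = "force") -> np.ndarray:
    """Divide pressures in N by body-weight force (default) or mass."""
    if weight <= 0:
        raise ValueError("weight must be positive")
    if mode == "force":
        return np.asarray(pressures, dtype=float) / (weight * GRAVITY)
    if mode == "mass":
        return np.asarray(pressures, dtype=float) / weight
    raise ValueError(f"unknown weight normalization mode {mode!r}")


def cg_to_local_frame(cg_global: np.ndarray, double_support_midpoint: np.ndarray,
                      walking_direction: np.ndarray,
                      vertical: np.ndarray = np.array([0.0, 0.0, 1.0])) -> np.ndarray:
    """Express a global CG trajectory in the local gait frame.

    x = horizontal walking direction, z = vertical, y = z x x, origin at the
    double-support midpoint. Axes are returned in (x, y, z) order, matching
    (anterior/posterior, medial/lateral, proximal/distal).
    """
    z = np.asarray(vertical, dtype=float)
    z = z / np.linalg.norm(z)
    w = np.asarray(walking_direction, dtype=float)
    x = w - (w @ z) * z  # project onto the horizontal plane
    nx = np.linalg.norm(x)
    if nx < 1e-9:
        raise ValueError("walking direction is parallel to the vertical")
    x = x / nx
    y = np.cross(z, x)
    rot = np.vstack([x, y, z])  # rows are the local axes
    return (np.asarray(cg_global, dtype=float)
            - np.asarray(double_support_midpoint, dtype=float)) @ rot.T


def normalize_cg_by_leg_length(cg_mm: np.ndarray, leg_length: float) -> np.ndarray:
    """Divide a CG trajectory in mm by the subject's leg length in mm."""
    if leg_length <= 0:
        raise ValueError("leg length must be positive")
    return np.asarray(cg_mm, dtype=float) / leg_length


def preprocess_trial(trial: SyntheticTrial,
                     config: PreprocessingConfig = PreprocessingConfig()
                     ) -> GaitSample:
    """Run the full preprocessing path on one raw trial.

    Filters pressures (7 Hz) and CG (10 Hz), time-normalizes the heel-strike
    -to-heel-strike cycle to 100 frames, normalizes pressures by body
    weight, transforms the CG into the local gait frame (walking direction
    estimated from the net horizontal CG displacement; origin from the mean
    CG ground position over the initial double support) and normalizes the
    CG by leg length.
    """
    n_raw = trial.pressures.shape[0]
    pressures = lowpass_filter(trial.pressures, config.sample_rate_hz,
                               config.pressure_cutoff_hz, config.filter_order)
    cg = lowpass_filter(trial.cg_global, config.sample_rate_hz,
                        config.cg_cutoff_hz, config.filter_order)
    pressures = extract_cycle(pressures, (0, n_raw))
    cg = extract_cycle(cg, (0, n_raw))
    pressures = time_normalize(pressures, config.n_frames)
    cg = time_normalize(cg, config.n_frames)
    # zero-phase filtering can overshoot slightly below zero on sharp onsets
    np.clip(pressures, 0.0, None, out=pressures)
    pressures = normalize_pressure_by_weight(pressures, trial.profile.weight,
                                             config.weight_mode)

    walking_direction = cg[-1] - cg[0]
    lto = trial.events.lto_frame
    origin = np.array([*np.mean(cg[: lto + 1, :2], axis=0), 0.0])
    cg_local = cg_to_local_frame(cg, origin, walking_direction)
    cg_norm = normalize_cg_by_leg_length(cg_local, trial.profile.leg_length)

    cycle = PressureCycle(pressures=pressures, subject=trial.profile,
                          events=trial.events)
    traj = CGTrajectory(cg=cg_norm, cg_mm=cg_local)
    return GaitSample(cycle=cycle, cg=traj)
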