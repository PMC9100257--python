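"""Time-domain augmentation of training cycles.

Three operators expand the training set four-fold (one raw + three
augmented copies per cycle):

* jittering - additive white Gaussian noise (mean 0, sd 0.03) on the
  weight-normalized pressure inputs;
* time-warping - resampling along a smooth monotone time map built from a
  cubic spline through four random speed knots ~ N(1, 0.2);
* pooling - a centered 3-frame moving average that reduces resolution
  without changing the series length.

Magnitude-domain augmentation is deliberately absent: rescaling signal
intensity confuses the amplitude cues the CG targets depend on. Under
time-warping the CG targets (and phase labels) are warped with the same
map as the inputs so input-target alignment is preserved; jittering and
pooling leave the targets untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.interpolate import CubicSpline

from .preprocessing import CGTrajectory, GaitSample

__all__ = [
    "AugmentationConfig",
    "jitter",
    "time_warp",
    "pool",
    "build_training_set",
]


@dataclass(frozen=True)
class AugmentationConfig:
    jitter_mu: float = 0.0
    jitter_sigma: float = 0.03
    warp_knots: int = 4
    warp_mu: float = 1.0
    warp_sigma: float = 0.2
    pool_window: int = 3
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.jitter_sigma < 0 or self.warp_sigma <= 0:
            raise ValueError("noise scales must be positive")
        if self.warp_knots < 2:
            raise ValueError("time-warping needs at least 2 knots")
        if self.pool_window < 3 or self.pool_window % 2 == 0:
            raise ValueError("pool window must be odd and >= 3")


def jitter(series: np.ndarray, config: AugmentationConfig, seed: int
           ) -> np.ndarray:
    """Add i.i.d. Gaussian noise; shape preserved, deterministic in seed."""
    rng = np.random.default_rng(seed)
    x = np.asarray(series, dtype=float)
    return x + rng.normal(config.jitter_mu, config.jitter_sigma, size=x.shape)


def warp_map(n_frames: int, config: AugmentationConfig, seed: int
             ) -> np.ndarray:
    """A strictly increasing time map fixing both endpoints.

    A cubic spline through ``warp_knots`` random positive speed magnitudes
    ~ N(warp_mu, warp_sigma) (clamped to >= 0.1) is integrated to a
    monotone map over [0, n_frames - 1], then rescaled to fix the final
    endpoint.
    """
    rng = np.random.default_rng(seed)
    knots_x = np.linspace(0.0, n_frames - 1.0, config.warp_knots)
    knots_v = np.maximum(rng.normal(config.warp_mu, config.warp_sigma,
                                    size=config.warp_knots), 0.1)
    speed = np.maximum(CubicSpline(knots_x, knots_v)(np.arange(n_frames)),
                       1e-3)
    tau = np.concatenate([[0.0], np.cumsum(0.5 * (speed[1:] + speed[:-1]))])
    return tau * (n_frames - 1.0) / tau[-1]


def time_warp(series: np.ndarray, config: AugmentationConfig, seed: int
              ) -> np.ndarray:
    """Resample a (frames, channels) series along a random smooth time map."""
    x = np.asarray(series, dtype=float)
    n = x.shape[0]
    if n < 8:
        raise ValueError("time-warping needs at least 8 frames")
    tau = warp_map(n, config, seed)
    base = np.arange(n, dtype=float)
    if x.ndim == 1:
        return np.interp(tau, base, x)
    return np.column_stack([np.interp(tau, base, x[:, c])
                            for c in range(x.shape[1])])


def pool(series: np.ndarray, window: int = 3) -> np.ndarray:
    """Centered moving average with edge replication; length preserved."""
    if window % 2 == 0:
        raise ValueError("pool window must be odd")
    x = np.asarray(series, dtype=float)
    one_d = x.ndim == 1
    if one_d:
        x = x[:, None]
    half = window // 2
    padded = np.vstack([np.repeat(x[:1], half, axis=0), x,
                        np.repeat(x[-1:], half, axis=0)])
    kernel = np.ones(window) / window
    out = np.column_stack([np.convolve(padded[:, c], kernel, mode="valid")
                           for c in range(x.shape[1])])
    return out[:, 0] if one_d else out


def _warp_sample(sample: GaitSample, config: AugmentationConfig, seed: int
                 ) -> GaitSample:
    n = sample.cycle.pressures.shape[0]
    tau = warp_map(n, config, seed)
    base = np.arange(n, dtype=float)

    def warp_cols(arr: np.ndarray) -> np.ndarray:
        return np.column_stack([np.interp(tau, base, arr[:, c])
                                for c in range(arr.shape[1])])

    pressures = np.clip(warp_cols(sample.cycle.pressures), 0.0, None)
    cg = warp_cols(sample.cg.cg)
    cg_mm = warp_cols(sample.cg.cg_mm)
    labels = None
    if sample.labels is not None:
        labels = sample.labels[np.clip(np.rint(tau).astype(int), 0, n - 1)]
    return GaitSample(
        cycle=replace(sample.cycle, pressures=pressures),
        cg=CGTrajectory(cg=cg, cg_mm=cg_mm),
        labels=labels,
    )


def build_training_set(samples: Sequence[GaitSample],
                       config: AugmentationConfig = AugmentationConfig(),
                       seed: int = 0) -> list[GaitSample]:
    """Four-fold augmentation: raw + jittered + warped + pooled copies.

    Jittering and pooling modify the pressure inputs only; time-warping
    warps pressures, CG targets and phase labels with one shared map.
    Per-sample operator seeds derive from ``seed``, so the output is
    deterministic. With augmentation disabled the input list is returned
    unchanged (as a copy).
    """
    if len(samples) == 0:
        raise ValueError("cannot augment an empty training set")
    if not config.enabled:
        return list(samples)
    ss = np.random.SeedSequence(seed)
    out: list[GaitSample] = []
    for sample, sub in zip(samples, ss.spawn(len(samples))):
        s_jit, s_warp = (int(s.generate_state(1)[0] % (2**31 - 1))
                         for s in sub.spawn(2))
        out.append(sample)
        jp = np.clip(jitter(sample.cycle.pressures, config, s_jit), 0.0, None)
        out.append(GaitSample(cycle=replace(sample.cycle, pressures=jp),
                              cg=sample.cg, labels=sample.labels))
        out.append(_warp_sample(sample, config, s_warp))
        pp = np.clip(pool(sample.cycle.pressures, config.pool_window),
                     0.0, None)
        out.append(GaitSample(cycle=replace(sample.cycle, pressures=pp),
                              cg=sample.cg, labels=sample.labels))
    return out
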