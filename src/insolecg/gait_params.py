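"""Per-frame insole parameters derived from the 18 raw pressure channels.

Each foot contributes 15 channels: the 9 sensor pressures, the rear- mid-
and forefoot zone sums, the total sum, and the two center-of-pressure (COP)
coordinates, for 30 parameters in total (left foot first). The COP is the
pressure-weighted mean of the sensor positions; during swing, where the
total load vanishes and the COP is undefined, the last valid value is held
to avoid discontinuities that would poison windowed features.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .preprocessing import PressureCycle

__all__ = [
    "SensorLayout",
    "ParameterSeries",
    "default_layout",
    "compute_cop",
    "compute_parameters",
    "PARAMETER_SUFFIXES",
]

#: Per-foot parameter channels, in output order.
PARAMETER_SUFFIXES = [f"s{k}" for k in range(1, 10)] + [
    "rear", "mid", "front", "total", "cop_x", "cop_y",
]

ZONES = ("rear", "mid", "front")


@dataclass(frozen=True)
class SensorLayout:
    """Sensor positions (mm, x anterior / y medial) and zone labels.

    One instance describes one foot; positions are in a foot-local frame
    with the heel near the origin.
    """

    positions: np.ndarray  # (9, 2)
    zones: tuple[str, ...]  # len 9, each in ZONES

    def __post_init__(self) -> None:
        if self.positions.shape != (9, 2) or len(self.zones) != 9:
            raise ValueError("a sensor layout needs 9 positioned sensors")
        if set(self.zones) != set(ZONES):
            raise ValueError(f"zones must partition the sensors into {ZONES}")

    def zone_indices(self, zone: str) -> np.ndarray:
        return np.array([i for i, z in enumerate(self.zones) if z == zone])


def default_layout(foot: str = "right") -> SensorLayout:
    """Nominal adult-foot sensor placement.

    Two heel (rear) sensors, two midfoot sensors and five forefoot sensors
    (four metatarsal heads plus the hallux), mirrored in y for the left
    foot. Coordinates are nominal mm from the heel center.
    """
    positions = np.array([
        [30.0, 10.0],    # s1 medial heel
        [30.0, -15.0],   # s2 lateral heel
        [95.0, 20.0],    # s3 medial midfoot
        [95.0, -25.0],   # s4 lateral midfoot
        [165.0, 30.0],   # s5 metatarsal I
        [175.0, 10.0],   # s6 metatarsal II
        [175.0, -10.0],  # s7 metatarsal III
        [165.0, -30.0],  # s8 metatarsal IV-V
        [215.0, 25.0],   # s9 hallux
    ])
    zones = ("rear", "rear", "mid", "mid", "front", "front", "front",
             "front", "front")
    if foot == "left":
        positions = positions * np.array([1.0, -1.0])
    elif foot != "right":
        raise ValueError(f"unknown foot {foot!r}")
    return SensorLayout(positions=positions, zones=zones)


def write_layout_csv(path: str | Path, left: SensorLayout,
                     right: SensorLayout) -> None:
    lines = ["foot,sensor_id,x_mm,y_mm,zone"]
    for foot, layout in (("left", left), ("right", right)):
        for k in range(9):
            x, y = (float(v) for v in layout.positions[k])
            lines.append(f"{foot},s{k + 1},{x!r},{y!r},{layout.zones[k]}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_layout_csv(path: str | Path) -> tuple[SensorLayout, SensorLayout]:
    rows = Path(path).read_text().strip().splitlines()[1:]
    data: dict[str, list] = {"left": [], "right": []}
    for row in rows:
        foot, sid, x, y, zone = row.split(",")
        data[foot].append((int(sid[1:]), float(x), float(y), zone))
    layouts = {}
    for foot, entries in data.items():
        entries.sort()
        pos = np.array([[x, y] for _, x, y, _ in entries])
        zones = tuple(z for _, _, _, z in entries)
        layouts[foot] = SensorLayout(positions=pos, zones=zones)
    return layouts["left"], layouts["right"]


@dataclass(frozen=True)
class ParameterSeries:
    """The 30 derived per-frame parameters of one cycle."""

    values: np.ndarray  # (100, 30)
    names: tuple[str, ...]  # len 30; left-foot 15 then right-foot 15

    def __post_init__(self) -> None:
        if self.values.shape[1] != 30 or len(self.names) != 30:
            raise ValueError("a parameter series has exactly 30 channels")


def compute_cop(foot_pressures: np.ndarray, layout: SensorLayout,
                floor: float = 1e-3) -> np.ndarray:
    """Pressure-weighted COP per frame, held at the last valid value.

    ``floor`` is the minimum total (weight-normalized) pressure for the COP
    to be considered defined; below it the previous valid COP is carried
    forward (frames before the first valid one take the first valid value).
    """
    p = np.asarray(foot_pressures, dtype=float)
    if p.ndim != 2 or p.shape[1] != 9:
        raise ValueError("foot pressures must be (frames, 9)")
    total = p.sum(axis=1)
    valid = total > floor
    if not valid.any():
        raise ValueError("COP undefined: no frame carries load on this foot")
    cop = np.full((len(p), 2), np.nan)
    cop[valid] = (p[valid] @ layout.positions) / total[valid, None]
    # hold-last (and back-fill before the first valid frame)
    idx = np.where(valid, np.arange(len(p)), -1)
    idx = np.maximum.accumulate(idx)
    first_valid = int(np.argmax(valid))
    idx[idx < 0] = first_valid
    return cop[idx]


def compute_parameters(cycle: PressureCycle,
                       left: SensorLayout | None = None,
                       right: SensorLayout | None = None,
                       cop_floor: float = 1e-3) -> ParameterSeries:
    """Derive the 30 input parameters from an 18-channel pressure cycle."""
    left = left if left is not None else default_layout("left")
    right = right if right is not None else default_layout("right")
    values = []
    names = []
    for foot, layout, sl in (("L", left, slice(0, 9)),
                             ("R", right, slice(9, 18))):
        p = cycle.pressures[:, sl]
        cop = compute_cop(p, layout, floor=cop_floor)
        cols = [p]
        for zone in ZONES:
            cols.append(p[:, layout.zone_indices(zone)].sum(axis=1, keepdims=True))
        cols.append(p.sum(axis=1, keepdims=True))
        cols.append(cop)
        values.append(np.hstack(cols))
        names.extend(f"{foot}_{suffix}" for suffix in PARAMETER_SUFFIXES)
    return ParameterSeries(values=np.hstack(values), names=tuple(names))
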