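"""Voltage-to-force calibration of piezo-resistive pressure sensors.

The sensor response is nonlinear and is modelled by a three-parameter
exponential law ``force = a * exp(b * voltage) + c`` fitted per sensor by
nonlinear least squares (initialized from a log-linear regression). The
fitted curve's Pearson correlation and RMSE against the calibration points
are stored as fit-quality diagnostics. Calibration is optional in the
synthetic pipeline, whose pressures are generated directly in force units.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import optimize, stats

__all__ = ["CalibrationCurve", "fit_calibration", "apply_calibration",
           "write_calibration_csv", "read_calibration_csv"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CalibrationCurve:
    """An exponential voltage-to-force law for one sensor."""

    sensor_id: str
    a: float
    b: float
    c: float
    r: float  # Pearson correlation of fit vs. calibration forces
    rmse_n: float  # RMSE against calibration forces, N
    v_min: float  # calibrated voltage range
    v_max: float

    def __call__(self, voltage: np.ndarray) -> np.ndarray:
        return self.a * np.exp(self.b * np.asarray(voltage, dtype=float)) + self.c


def _exp_law(v, a, b, c):
    return a * np.exp(b * v) + c


def fit_calibration(voltage: Sequence[float], force: Sequence[float],
                    sensor_id: str = "", fit_offset: bool = False
                    ) -> CalibrationCurve:
    """Least-squares exponential fit of force (N) against voltage (V).

    The offset ``c`` defaults to 0 (the law reduces to ``a exp(bV)``);
    ``fit_offset=True`` frees it to absorb a sensor baseline. Initial
    values come from a log-linear regression of the positive forces.
    """
    v = np.asarray(voltage, dtype=float)
    f = np.asarray(force, dtype=float)
    if v.size != f.size:
        raise ValueError("voltage and force must be paired")
    if v.size < 5:
        raise ValueError("calibration needs at least 5 points")

    pos = f > 0
    if pos.sum() >= 2:
        slope, intercept, *_ = stats.linregress(v[pos], np.log(f[pos]))
        p0 = [float(np.exp(intercept)), float(slope)]
    else:
        neg = f < 0
        if neg.sum() >= 2:  # decreasing law with negative amplitude
            slope, intercept, *_ = stats.linregress(v[neg], np.log(-f[neg]))
            p0 = [-float(np.exp(intercept)), float(slope)]
        else:
            p0 = [1.0, 1.0]
    if fit_offset:
        p0.append(0.0)
        model = _exp_law
    else:
        def model(x, a, b):
            return _exp_law(x, a, b, 0.0)
    try:
        popt, _ = optimize.curve_fit(model, v, f, p0=p0, maxfev=20000)
    except RuntimeError as err:
        raise RuntimeError(
            f"calibration fit for sensor {sensor_id!r} did not converge "
            f"(n={v.size}, voltage range [{v.min():.3g}, {v.max():.3g}] V): "
            f"{err}") from err
    a, b = float(popt[0]), float(popt[1])
    c = float(popt[2]) if fit_offset else 0.0
    pred = _exp_law(v, a, b, c)
    rmse = float(np.sqrt(np.mean((pred - f) ** 2)))
    if np.std(pred) == 0 or np.std(f) == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(pred, f)[0, 1])
    return CalibrationCurve(sensor_id=sensor_id, a=a, b=b, c=c, r=r,
                            rmse_n=rmse, v_min=float(v.min()),
                            v_max=float(v.max()))


def apply_calibration(curve: CalibrationCurve, voltage: np.ndarray,
                      extrapolation_margin: float = 0.1) -> np.ndarray:
    """Convert voltages to forces (N); negative outputs clamp to 0.

    Voltages outside the calibrated range by more than
    ``extrapolation_margin`` (fraction of the range) are still converted,
    with a logged warning.
    """
    v = np.asarray(voltage, dtype=float)
    span = curve.v_max - curve.v_min
    margin = extrapolation_margin * (span if span > 0 else 1.0)
    out_of_range = (v < curve.v_min - margin) | (v > curve.v_max + margin)
    if out_of_range.any():
        logger.warning(
            "sensor %s: %d voltage samples outside the calibrated range "
            "[%.3g, %.3g] V (margin %.3g); extrapolating",
            curve.sensor_id, int(out_of_range.sum()), curve.v_min,
            curve.v_max, margin)
    return np.clip(curve(v), 0.0, None)


def write_calibration_csv(path: str | Path,
                          curves: Sequence[CalibrationCurve]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sensor_id", "a", "b", "c", "r", "rmse_N",
                    "v_min", "v_max"])
        for cu in curves:
            w.writerow([cu.sensor_id, repr(cu.a), repr(cu.b), repr(cu.c),
                        repr(cu.r), repr(cu.rmse_n), repr(cu.v_min),
                        repr(cu.v_max)])


def read_calibration_csv(path: str | Path) -> list[CalibrationCurve]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(CalibrationCurve(
                sensor_id=row["sensor_id"], a=float(row["a"]),
                b=float(row["b"]), c=float(row["c"]), r=float(row["r"]),
                rmse_n=float(row["rmse_N"]), v_min=float(row["v_min"]),
                v_max=float(row["v_max"])))
    return out
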