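"""Ultrasonic distance sensing: calibration, height estimation, range checks.

An ultrasonic rangefinder pointed straight down at the canopy outputs a
voltage proportional to the echo travel time.  A linear calibration maps
the voltage ``v`` (0-10 V) to a distance ``d`` in centimetres; the default
model is ``d = 7.0275 v + 29.658``.  Plant height is obtained by
subtracting the measured distance from a weed-free reference distance
(sensor mounted at 0.80 m).  Echoes outside the configured sensing window
(350-1000 mm) are reported by the device as a full-scale error sentinel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as _sps

__all__ = [
    "FULL_SCALE_VOLTS",
    "CalibrationModel",
    "DEFAULT_CALIBRATION",
    "SensorConfig",
    "HeightReading",
    "SampleSummary",
    "voltage_to_distance",
    "distance_to_voltage",
    "fit_calibration",
    "reference_distance",
    "estimate_height",
    "summarize_sample",
    "read_trace",
    "save_calibration",
    "load_calibration",
]

#: Full scale of the sensor's analog voltage output, volts.
FULL_SCALE_VOLTS = 10.0


@dataclass(frozen=True)
class CalibrationModel:
    """Linear voltage-to-distance calibration ``d = slope * v + intercept``.

    Attributes
    ----------
    slope : float
        Centimetres per volt; must be positive.
    intercept : float
        Distance in cm at 0 V.
    r_squared : float
        Coefficient of determination of the calibration fit.
    """

    slope: float = 7.0275
    intercept: float = 29.658
    r_squared: float = 0.99

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError(f"calibration slope must be > 0, got {self.slope}")


#: Factory-style default calibration of the rangefinder.
DEFAULT_CALIBRATION = CalibrationModel()


@dataclass(frozen=True)
class SensorConfig:
    """Mounting geometry and sensing window of the rangefinder.

    ``reference_distance_cm`` is the sensor-to-soil distance over bare,
    weed-free ground.  The sensing window is expressed in millimetres, as
    configured on the device; echoes outside it yield the full-scale
    ``error_sentinel_volts`` instead of a distance reading.
    """

    reference_distance_cm: float = 80.0
    range_min_mm: float = 350.0
    range_max_mm: float = 1000.0
    error_sentinel_volts: float = FULL_SCALE_VOLTS

    def __post_init__(self) -> None:
        if not 0 < self.range_min_mm < self.range_max_mm:
            raise ValueError("require 0 < range_min_mm < range_max_mm")
        if not (self.range_min_mm <= self.reference_distance_cm * 10.0 <= self.range_max_mm):
            raise ValueError("reference distance must lie inside the sensing window")


@dataclass(frozen=True)
class HeightReading:
    """One calibrated reading: distance, derived plant height, validity."""

    distance_cm: float
    height_cm: float
    valid: bool


@dataclass(frozen=True)
class SampleSummary:
    """Aggregate of a trace segment: mean height over valid readings."""

    mean_height_cm: float
    n_valid: int
    n_invalid: int


def _check_voltages(v: np.ndarray, full_scale: float) -> None:
    if not np.all(np.isfinite(v)):
        raise ValueError("voltages must be finite")
    if np.any(v < 0) or np.any(v > full_scale):
        raise ValueError(f"voltages must lie in [0, {full_scale}] V")


def voltage_to_distance(v, calib: CalibrationModel = DEFAULT_CALIBRATION,
                        full_scale: float = FULL_SCALE_VOLTS):
    """Convert sensor voltage(s) to distance in cm via ``d = slope*v + intercept``.

    Parameters
    ----------
    v : float or array-like
        Voltage(s) in [0, ``full_scale``].  Values outside that interval or
        non-finite values raise ``ValueError``.  Note that a voltage equal to
        the error sentinel is *accepted* here and converts like any other —
        callers that care about validity must mask sentinel readings first
        (see :func:`summarize_sample`).

    Returns
    -------
    float or ndarray of distances in cm.
    """
    arr = np.asarray(v, dtype=float)
    _check_voltages(arr, full_scale)
    d = calib.slope * arr + calib.intercept
    return float(d) if np.isscalar(v) else d


def distance_to_voltage(d, calib: CalibrationModel = DEFAULT_CALIBRATION):
    """Inverse calibration: ``v = (d - intercept) / slope``."""
    arr = np.asarray(d, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("distances must be finite")
    v = (arr - calib.intercept) / calib.slope
    return float(v) if np.isscalar(d) else v


def fit_calibration(volts, distances_cm) -> CalibrationModel:
    """Fit a voltage-to-distance line by ordinary least squares.

    Emulates the bench calibration step where sensor output is compared with
    tape-measure distances over the sensing range.

    Raises ``ValueError`` if fewer than two distinct voltages are supplied
    (the fit would be singular).
    """
    v = np.asarray(volts, dtype=float)
    d = np.asarray(distances_cm, dtype=float)
    if v.shape != d.shape or v.ndim != 1:
        raise ValueError("volts and distances must be 1-D and equal length")
    if np.unique(v).size < 2:
        raise ValueError("need at least two distinct voltages to fit a line")
    res = _sps.linregress(v, d)
    return CalibrationModel(slope=float(res.slope), intercept=float(res.intercept),
                            r_squared=float(res.rvalue) ** 2)


def reference_distance(t_seconds, volts, calib: CalibrationModel = DEFAULT_CALIBRATION,
                       window_s: float = 10.0,
                       cfg: SensorConfig = SensorConfig()) -> float:
    """Mean calibrated distance over the first ``window_s`` seconds of a trace.

    The reference is taken over bare ground before measuring plants, so every
    reading inside the window must be in range: a sentinel voltage or an
    out-of-window distance raises ``ValueError``.
    """
    t = np.asarray(t_seconds, dtype=float)
    v = np.asarray(volts, dtype=float)
    if t.shape != v.shape or t.ndim != 1 or t.size == 0:
        raise ValueError("trace must be 1-D, non-empty, equal-length t and v")
    if t[-1] - t[0] < window_s:
        raise ValueError(f"trace spans {t[-1] - t[0]:.3f} s < window {window_s} s")
    sel = t <= t[0] + window_s
    vw = v[sel]
    if np.any(vw >= cfg.error_sentinel_volts):
        raise ValueError("sentinel reading inside the reference window")
    d = voltage_to_distance(vw, calib)
    if np.any(d * 10.0 < cfg.range_min_mm) or np.any(d * 10.0 > cfg.range_max_mm):
        raise ValueError("reference reading outside the sensing window")
    return float(np.mean(d))


def estimate_height(distance_cm: float, cfg: SensorConfig = SensorConfig()) -> HeightReading:
    """Plant height = reference distance minus measured distance.

    The reading is valid only when the distance (in mm) lies inside the
    configured sensing window; invalid readings carry ``height_cm = nan``.
    """
    d_mm = distance_cm * 10.0
    valid = bool(cfg.range_min_mm <= d_mm <= cfg.range_max_mm)
    height = cfg.reference_distance_cm - distance_cm if valid else float("nan")
    return HeightReading(distance_cm=float(distance_cm), height_cm=height, valid=valid)


def summarize_sample(volts, cfg: SensorConfig = SensorConfig(),
                     calib: CalibrationModel = DEFAULT_CALIBRATION) -> SampleSummary:
    """Mean plant height over a trace segment, counting invalid readings.

    A reading is invalid when the voltage equals the error sentinel or the
    calibrated distance falls outside the sensing window.  Raises
    ``ValueError`` when the segment is empty or no reading is valid.
    """
    v = np.asarray(volts, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise ValueError("trace segment must be 1-D and non-empty")
    sentinel = v >= cfg.error_sentinel_volts
    d = calib.slope * v + calib.intercept
    in_range = (d * 10.0 >= cfg.range_min_mm) & (d * 10.0 <= cfg.range_max_mm)
    valid = ~sentinel & in_range
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("no valid readings in segment")
    heights = cfg.reference_distance_cm - d[valid]
    return SampleSummary(mean_height_cm=float(np.mean(heights)),
                         n_valid=n_valid, n_invalid=int(v.size - n_valid))


# ---------------------------------------------------------------------------
# File IO

def read_trace(path) -> pd.DataFrame:
    """Read a voltage trace CSV with columns ``t_seconds, volts``."""
    df = pd.read_csv(path)
    missing = {"t_seconds", "volts"} - set(df.columns)
    if missing:
        raise ValueError(f"trace CSV missing columns: {sorted(missing)}")
    return df


def save_calibration(calib: CalibrationModel, path) -> None:
    Path(path).write_text(json.dumps(asdict(calib), indent=2) + "\n")


def load_calibration(path) -> CalibrationModel:
    return CalibrationModel(**json.loads(Path(path).read_text()))
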