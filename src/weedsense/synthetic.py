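"""Synthetic plot images, voltage traces and field tables with known truth.

Every downstream stage of the pipeline is exercised against ground truth
produced here: plot photographs with a grey circular frame at a known
centre/radius and plant blobs of exactly known coverage, sensor voltage
traces generated by inverting the calibration line, and field sample
tables drawn from configurable group moments with a known linear model
for the ultrasonic height.

Colour design: the frame is a desaturated blue-grey whose 8-bit HSV triple
sits mid-interval of the frame thresholds (an achromatic grey has an
unstable hue, so a hue around 159 makes segmentation deterministic); soil
is a brown texture whose excess-green index never exceeds the plant
threshold; plants are a saturated green far above it.  Brightness noise is
added equally to all channels, which leaves both hue and ExG invariant.

Ring convention: the painted frame annulus consists of pixels whose
*rounded* distance to the centre lies in [radius - frame_width, radius],
i.e. ``radius`` names the outer rounded radius of the frame.  The Hough
accumulator votes on exactly this rounded-distance ring, so on a clean
image the accumulator peaks at (centre, radius) regardless of the frame
width.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .sensor import DEFAULT_CALIBRATION, CalibrationModel, SensorConfig

__all__ = [
    "SOIL_RGB",
    "FRAME_RGB",
    "PLANT_RGB",
    "ROI_SHRINK",
    "PlotImageTruth",
    "FieldSimConfig",
    "TABLE_MOMENTS",
    "STD_BETAS",
    "default_coefficients",
    "gen_plot_image",
    "gen_plot_pair",
    "PlotPairTruth",
    "gen_voltage_trace",
    "gen_field_table",
    "save_truth",
    "load_truth",
]

SOIL_RGB = (125, 96, 66)
FRAME_RGB = (150, 160, 190)
PLANT_RGB = (60, 170, 60)

#: Margin (px) by which the measurement ROI sits inside the detected circle.
ROI_SHRINK = 10


@dataclass(frozen=True)
class PlotImageTruth:
    """Ground truth of one synthetic plot photograph.

    ``true_coverage`` is the plant-pixel fraction of the ROI disc of radius
    ``radius - ROI_SHRINK`` around ``center`` — the same disc the imaging
    chain measures after shrinking a perfectly detected circle.
    """

    center: tuple[int, int]
    radius: int
    true_coverage: float
    frame_width: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.radius > self.frame_width:
            raise ValueError("radius must exceed frame_width")
        if not 0.0 <= self.true_coverage <= 1.0:
            raise ValueError("true_coverage must lie in [0, 1]")
        if self.radius - ROI_SHRINK < 1:
            raise ValueError("radius leaves no ROI after shrinking")


def _paint_ellipse(mask: np.ndarray, allowed: np.ndarray, cy: float, cx: float,
                   a: float, b: float, theta: float) -> None:
    """OR an axis-rotated filled ellipse into ``mask``, clipped to ``allowed``."""
    h, w = mask.shape
    rmax = int(np.ceil(max(a, b)))
    y0, y1 = max(0, int(cy) - rmax - 1), min(h, int(cy) + rmax + 2)
    x0, x1 = max(0, int(cx) - rmax - 1), min(w, int(cx) + rmax + 2)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    mask[y0:y1, x0:x1] |= inside & allowed[y0:y1, x0:x1]


def _geometry(truth: PlotImageTruth, size: tuple[int, int]):
    h, w = size
    x0, y0 = truth.center
    r = truth.radius
    if not (r <= x0 < w - r and r <= y0 < h - r):
        raise ValueError("frame circle does not fit inside the image bounds")
    yy, xx = np.ogrid[:h, :w]
    dist = np.hypot(yy - y0, xx - x0)
    rdist = np.rint(dist).astype(np.int64)
    frame = (rdist >= r - truth.frame_width) & (rdist <= r)
    roi = dist**2 <= (r - ROI_SHRINK) ** 2
    return frame, roi


def _paint_plants(rng: np.random.Generator, allowed: np.ndarray, target: int,
                  center: tuple[int, int], rho_max: float) -> np.ndarray:
    """Random-ellipse mask inside ``allowed`` with exactly ``target`` pixels.

    Ellipse centres range a little past the allowed rim (blobs are clipped)
    so plant density stays uniform up to the boundary; the count is made
    exact by un-painting surplus pixels or, for very dense targets, topping
    up with single pixels.
    """
    x0, y0 = center
    plants = np.zeros(allowed.shape, dtype=bool)
    cap = int(allowed.sum())
    if target >= cap:
        return allowed.copy()
    if target <= 0:
        return plants
    tries = 0
    while int(plants.sum()) < target and tries < 500:
        rho = np.sqrt(rng.uniform(0.0, 1.0)) * rho_max
        phi = rng.uniform(0.0, 2.0 * np.pi)
        _paint_ellipse(plants, allowed, y0 + rho * np.sin(phi), x0 + rho * np.cos(phi),
                       a=rng.uniform(4.0, 14.0), b=rng.uniform(4.0, 14.0),
                       theta=rng.uniform(0.0, np.pi))
        tries += 1
    excess = int(plants.sum()) - target
    if excess > 0:
        idx = np.flatnonzero(plants)
        drop = rng.choice(idx, size=excess, replace=False)
        plants.flat[drop] = False
    elif excess < 0:
        idx = np.flatnonzero(allowed & ~plants)
        add = rng.choice(idx, size=-excess, replace=False)
        plants.flat[add] = True
    return plants


def _render(truth: PlotImageTruth, size: tuple[int, int], frame: np.ndarray,
            plants: np.ndarray, rng: np.random.Generator, n_specks: int) -> np.ndarray:
    """Compose soil texture, frame ring, debris specks and plants into RGB."""
    h, w = size
    x0, y0 = truth.center
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = SOIL_RGB
    img += rng.integers(-4, 5, size=(h, w, 3)).astype(np.float64)  # per-channel soil grain
    img[frame] = FRAME_RGB
    for _ in range(n_specks):
        sy = int(rng.integers(2, h - 2))
        sx = int(rng.integers(2, w - 2))
        sd = np.hypot(sy - y0, sx - x0)
        if abs(sd - (truth.radius - truth.frame_width / 2)) < truth.frame_width / 2 + 15:
            continue  # keep debris clear of the ring
        srad = int(rng.integers(1, 3))
        img[max(0, sy - srad):sy + srad + 1, max(0, sx - srad):sx + srad + 1] = FRAME_RGB
    img[plants] = PLANT_RGB
    # brightness noise shared across channels: hue and ExG are unaffected
    img += rng.integers(-10, 11, size=(h, w, 1)).astype(np.float64)
    return np.clip(img, 0, 255).astype(np.uint8)


def gen_plot_image(truth: PlotImageTruth, size: tuple[int, int] = (400, 400),
                   n_specks: int = 12) -> tuple[np.ndarray, PlotImageTruth]:
    """Render a synthetic plot photograph with exactly known plant coverage.

    Parameters
    ----------
    truth : PlotImageTruth
        Frame geometry, target coverage and seed.
    size : (height, width)
        Image dimensions in pixels; the frame must fit fully inside.
    n_specks : int
        Number of small frame-coloured debris specks scattered over the
        soil, small enough for the size-10 majority filter to remove.

    Returns the uint8 RGB image together with the truth record.  The painted
    plant-pixel count inside the ROI disc equals ``round(true_coverage *
    roi_area)`` exactly, so the empirical coverage is within 0.5 / roi_area
    of the target.
    """
    frame, roi = _geometry(truth, size)
    rng = np.random.default_rng(truth.seed)
    target = int(round(truth.true_coverage * int(roi.sum())))
    plants = _paint_plants(rng, roi, target, truth.center,
                           (truth.radius - ROI_SHRINK) + 12)
    return _render(truth, size, frame, plants, rng, n_specks), truth


@dataclass(frozen=True)
class PlotPairTruth:
    """Ground truth of a before/after-weeding image pair.

    The after image shows exactly the crop pixels of the before image with
    every weed pixel reverted to soil, so the coverage difference inside
    the ROI equals ``weed_fraction`` exactly.
    """

    before: PlotImageTruth
    after: PlotImageTruth
    weed_fraction: float


def gen_plot_pair(center: tuple[int, int], radius: int, crop_coverage: float,
                  weed_coverage: float, seed: int, size: tuple[int, int] = (400, 400),
                  frame_width: int = 12, n_specks: int = 12):
    """Render a before/after-weeding image pair sharing crop pixels.

    The before image carries crop + weed blobs at total coverage
    ``crop_coverage + weed_coverage`` (capped at 1); the after image carries
    the identical crop blobs only.  Returns ``(before_rgb, after_rgb,
    PlotPairTruth)`` where ``weed_fraction`` is the exact painted coverage
    difference.
    """
    total = min(crop_coverage + weed_coverage, 1.0)
    t_before = PlotImageTruth(center=center, radius=radius, true_coverage=total,
                              frame_width=frame_width, seed=seed)
    frame, roi = _geometry(t_before, size)
    roi_area = int(roi.sum())
    rng = np.random.default_rng(seed)
    crop_target = int(round(crop_coverage * roi_area))
    before_target = int(round(total * roi_area))
    rho_max = (radius - ROI_SHRINK) + 12
    crop = _paint_plants(rng, roi, crop_target, center, rho_max)
    weeds = _paint_plants(rng, roi & ~crop, before_target - crop_target, center, rho_max)
    t_after = PlotImageTruth(center=center, radius=radius,
                             true_coverage=crop_target / roi_area,
                             frame_width=frame_width, seed=seed)
    img_before = _render(t_before, size, frame, crop | weeds, rng, n_specks)
    img_after = _render(t_after, size, frame, crop, rng, n_specks)
    truth = PlotPairTruth(before=t_before, after=t_after,
                          weed_fraction=(before_target - crop_target) / roi_area)
    return img_before, img_after, truth


def gen_voltage_trace(true_distance_cm, noise_sd: float = 0.0, seed: int | None = None,
                      calib: CalibrationModel = DEFAULT_CALIBRATION,
                      cfg: SensorConfig = SensorConfig(),
                      sample_rate_hz: float = 10.0) -> pd.DataFrame:
    """Voltage trace for a series of true distances, by inverting the calibration.

    ``v = (d - intercept) / slope`` plus Gaussian noise.  Distances outside
    the sensing window — including the top sliver where the inverse
    calibration would exceed the full-scale output — emit the error
    sentinel.  Noisy in-window voltages are clipped just below the sentinel
    so noise can never masquerade as an error flag.

    Returns a DataFrame with columns ``t_seconds`` and ``volts``.
    """
    d = np.asarray(true_distance_cm, dtype=float)
    if d.ndim != 1 or d.size == 0:
        raise ValueError("true_distance_cm must be a non-empty 1-D series")
    if not np.all(np.isfinite(d)):
        raise ValueError("distances must be finite")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    v = (d - calib.intercept) / calib.slope
    out = ((d * 10.0 < cfg.range_min_mm) | (d * 10.0 > cfg.range_max_mm)
           | (v < 0.0) | (v >= cfg.error_sentinel_volts))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, noise_sd, size=v.shape)
        v = np.clip(v, 0.0, cfg.error_sentinel_volts - 1e-2)
    v = np.where(out, cfg.error_sentinel_volts, v)
    t = np.arange(d.size, dtype=float) / sample_rate_hz
    return pd.DataFrame({"t_seconds": t, "volts": v})


# ---------------------------------------------------------------------------
# Field sample tables

#: Per-variable (mean, sd) of the field variables; heights in cm, densities
#: in plants per sample, biomass in g dry weight, coverage as a fraction.
TABLE_MOMENTS: dict[str, tuple[float, float]] = {
    "weed_coverage": (0.167, 0.103),
    "grass_height": (3.6, 0.6),
    "bl_height": (2.0, 1.1),
    "crop_height": (6.6, 0.5),
    "grass_density": (4.8, 2.9),
    "bl_density": (3.5, 2.9),
    "crop_density": (9.7, 1.7),
    "grass_biomass": (0.7, 0.4),
    "bl_biomass": (0.3, 0.3),
    "crop_biomass": (1.6, 0.5),
}

#: Standardized coefficients of the default ultrasonic-height model (response
#: sd 1.0 cm); variables absent here do not enter the model.
STD_BETAS: dict[str, float] = {
    "weed_coverage": 0.029,
    "grass_height": 0.301,
    "bl_height": 0.227,
    "grass_density": 0.392,
    "crop_density": 0.225,
    "grass_biomass": 0.174,
    "bl_biomass": 0.177,
}

GROUPS = ("non-infested", "grass", "broad-leaved", "mixture")

#: Default sample composition of a simulated field campaign (80 points,
#: grass-dominated infestation, broad-leaved-only spots rare).
GROUP_SIZES = {"non-infested": 11, "grass": 39, "broad-leaved": 10, "mixture": 20}

_GRASS_VARS = ("grass_height", "grass_density", "grass_biomass")
_BL_VARS = ("bl_height", "bl_density", "bl_biomass")

#: Which variables are structurally zero in each infestation group.
_ZEROED = {
    "non-infested": ("weed_coverage", *_GRASS_VARS, *_BL_VARS),
    "grass": _BL_VARS,
    "broad-leaved": _GRASS_VARS,
    "mixture": (),
}


def default_coefficients(moments: dict[str, tuple[float, float]] | None = None,
                         response_sd: float = 1.0) -> dict[str, float]:
    """Raw model coefficients implied by the standardized defaults.

    raw = standardized * sd(response) / sd(predictor).
    """
    moments = moments or TABLE_MOMENTS
    return {k: b * response_sd / moments[k][1] for k, b in STD_BETAS.items()}


def _default_intercept(coeffs: dict[str, float],
                       moments: dict[str, tuple[float, float]],
                       target_mean: float = 3.7) -> float:
    """Intercept placing the across-group mean ultrasonic height near target."""
    presence = {v: np.mean([v not in _ZEROED[g] for g in GROUPS]) for v in moments}
    return target_mean - sum(b * moments[k][0] * presence[k] for k, b in coeffs.items())


@dataclass(frozen=True)
class FieldSimConfig:
    """Generating model for field sample tables.

    Covariates are drawn per group from zero-truncated normal distributions
    at the configured moments (variables structurally absent from a group
    are exactly 0); the ultrasonic height is a linear model over the
    covariates plus Gaussian noise.  The default noise sd of sqrt(1/3)
    leaves the model explaining about two thirds of a unit response
    variance.

    ``n_per_group`` is either one integer (balanced groups) or a
    group-name -> count mapping; the default is the unbalanced 80-point
    composition of a grass-dominated campaign.
    """

    n_per_group: int | dict[str, int] | None = None
    groups: tuple[str, ...] = GROUPS
    moments: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(TABLE_MOMENTS))
    coefficients: dict[str, float] = field(default_factory=default_coefficients)
    intercept: float | None = None
    noise_sd: float = float(np.sqrt(1.0 / 3.0))
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.group_sizes().values()) < 2:
            raise ValueError("need at least 2 samples per group")
        if any(sd < 0 for _, sd in self.moments.values()):
            raise ValueError("standard deviations must be >= 0")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be > 0")
        unknown = set(self.groups) - set(_ZEROED)
        if unknown:
            raise ValueError(f"unknown groups: {sorted(unknown)}")

    def group_sizes(self) -> dict[str, int]:
        if self.n_per_group is None:
            return {g: GROUP_SIZES[g] for g in self.groups}
        if isinstance(self.n_per_group, dict):
            return {g: int(self.n_per_group[g]) for g in self.groups}
        return {g: int(self.n_per_group) for g in self.groups}

    def resolved_intercept(self) -> float:
        if self.intercept is not None:
            return self.intercept
        return _default_intercept(self.coefficients, self.moments)


def _draw_truncated(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    if sd == 0:
        return np.full(n, mean)
    a = (0.0 - mean) / sd
    return truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)


def gen_field_table(cfg: FieldSimConfig = FieldSimConfig()) -> pd.DataFrame:
    """Draw a reproducible field sample table with known model structure.

    Returns one row per sampling point with the covariates, the generated
    ultrasonic height, and the infestation / weed-presence labels.
    """
    rng = np.random.default_rng(cfg.seed)
    intercept = cfg.resolved_intercept()
    sizes = cfg.group_sizes()
    rows = []
    sid = 0
    for group in cfg.groups:
        n_g = sizes[group]
        zeroed = set(_ZEROED[group])
        cols = {}
        for var, (m, s) in cfg.moments.items():
            if var in zeroed:
                cols[var] = np.zeros(n_g)
            else:
                cols[var] = _draw_truncated(rng, m, s, n_g)
        height = np.full(n_g, intercept)
        for var, b in cfg.coefficients.items():
            height = height + b * cols.get(var, 0.0)
        height = height + rng.normal(0.0, cfg.noise_sd, size=n_g)
        for i in range(n_g):
            rows.append({
                "sample_id": f"S{sid:04d}",
                "infestation": group,
                "weed_presence": "non-infested" if group == "non-infested" else "infested",
                "ultrasonic_height": height[i],
                **{var: cols[var][i] for var in cfg.moments},
            })
            sid += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Truth sidecars

def save_truth(truth: PlotImageTruth, path) -> None:
    Path(path).write_text(json.dumps(asdict(truth), indent=2) + "\n")


def load_truth(path) -> PlotImageTruth:
    d = json.loads(Path(path).read_text())
    d["center"] = tuple(d["center"])
    return PlotImageTruth(**d)
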