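"""Circular-frame ROI detection and excess-green plant coverage.

Each plot photograph contains a grey circular frame marking the sensor
footprint.  The processing chain is:

1. convert RGB to HSV on an 8-bit [0, 255] scale,
2. threshold each HSV channel and AND the three binary images to segment
   the frame by colour,
3. clean the mask with a binary majority (median) filter,
4. locate the frame with a circular Hough transform whose accumulator grid
   has the same size as the image,
5. shrink the detected circle to exclude the frame itself and mask the RGB
   image through the alpha channel,
6. compute the excess green index ExG = 2G - R - B, threshold it, and
   report plant coverage C = pf / (pf + pb) over ROI pixels only.

Conventions: 0-based coordinates with x = column and y = row; circle
membership is decided on pixel centres; binary masks are boolean arrays
with ``True`` = object (the inverse of the black-ink-on-white display
convention sometimes used for such masks).
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
from PIL import Image
from scipy import ndimage as ndi
from scipy.signal import fftconvolve
from skimage.color import rgb2hsv

__all__ = [
    "HsvThresholds",
    "ROICircle",
    "CoverageResult",
    "PlotMeasurement",
    "rgb_to_hsv8",
    "segment_frame",
    "median_majority",
    "ring_offsets",
    "hough_accumulator",
    "hough_circle",
    "shrink_roi",
    "roi_mask",
    "apply_roi",
    "exg_image",
    "exg_threshold",
    "segment_plants",
    "coverage",
    "detect_roi",
    "measure_plot",
    "read_image",
    "write_image",
]


@dataclass(frozen=True)
class HsvThresholds:
    """Inclusive per-channel intervals on the 8-bit HSV scale.

    Defaults segment the desaturated grey-blue frame: H in [116, 255],
    S in [0, 128], V in [31, 255].
    """

    h: tuple[int, int] = (116, 255)
    s: tuple[int, int] = (0, 128)
    v: tuple[int, int] = (31, 255)

    def __post_init__(self) -> None:
        for name, (lo, hi) in (("h", self.h), ("s", self.s), ("v", self.v)):
            if not (0 <= lo <= hi <= 255):
                raise ValueError(f"threshold {name}=({lo},{hi}) not a valid 8-bit interval")


@dataclass(frozen=True)
class ROICircle:
    """A detected measurement circle: centre (x0, y0), radius, vote support."""

    x0: int
    y0: int
    r: int
    score: int = 1

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError("circle radius must be positive")
        if self.score < 1:
            raise ValueError("accumulator score must be >= 1")


@dataclass(frozen=True)
class CoverageResult:
    """Plant/background pixel counts inside an ROI and their ratio."""

    pf: int
    pb: int

    @property
    def coverage(self) -> float:
        return self.pf / (self.pf + self.pb)


@dataclass(frozen=True)
class PlotMeasurement:
    """Full result of the imaging chain on one photograph."""

    circle: ROICircle
    roi: ROICircle
    result: CoverageResult


# ---------------------------------------------------------------------------
# Colour transforms and thresholding

def rgb_to_hsv8(rgb: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB image to HSV with every channel on [0, 255].

    Hue is rescaled from degrees so that 360 deg maps to 255 (e.g. pure blue,
    240 deg, becomes 170); achromatic pixels get H = 0.  Channels are rounded
    to the nearest integer.
    """
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("expected an HxWx3 RGB image")
    hsv = rgb2hsv(rgb.astype(np.float64) / 255.0)
    return np.rint(hsv * 255.0).astype(np.uint8)


def segment_frame(hsv8: np.ndarray, thr: HsvThresholds = HsvThresholds()) -> np.ndarray:
    """Binary frame mask: object iff all three HSV values fall in-interval.

    Equivalent to thresholding each channel separately and combining the
    three binary images with a pixelwise AND.
    """
    hsv8 = np.asarray(hsv8)
    if hsv8.ndim != 3 or hsv8.shape[2] != 3:
        raise ValueError("expected an HxWx3 HSV image")
    masks = []
    for c, (lo, hi) in enumerate((thr.h, thr.s, thr.v)):
        ch = hsv8[..., c]
        masks.append((ch >= lo) & (ch <= hi))
    return masks[0] & masks[1] & masks[2]


def median_majority(mask: np.ndarray, size: int = 10) -> np.ndarray:
    """Binary median: majority vote over a size x size window.

    A pixel stays object iff strictly more than half of the window pixels
    are object; exact ties resolve to background, and windows extending past
    the border see background padding.  For even sizes the window covers
    offsets [-size//2, size - 1 - size//2] in each axis.
    """
    if size < 1:
        raise ValueError("window size must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    counts = ndi.correlate(mask.astype(np.int32), np.ones((size, size), dtype=np.int32),
                           mode="constant", cval=0)
    return counts * 2 > size * size


# ---------------------------------------------------------------------------
# Circular Hough transform

def ring_offsets(r: int) -> np.ndarray:
    """(dy, dx) offsets whose Euclidean length rounds to exactly r.

    This discrete ring is both the set of centre candidates voted for by an
    object pixel and, by symmetry, the set of object pixels supporting a
    centre — so vote accumulation (scatter) and support counting (gather)
    agree exactly.
    """
    if r < 1:
        raise ValueError("radius must be >= 1")
    span = np.arange(-r, r + 1)
    yy, xx = np.meshgrid(span, span, indexing="ij")
    ring = np.rint(np.hypot(yy, xx)).astype(np.int64) == r
    return np.argwhere(ring) - r


def hough_accumulator(mask: np.ndarray, r: int) -> np.ndarray:
    """Vote accumulator for circles of radius r, on a grid the size of the image.

    Every object pixel increments the accumulator along a circle of radius r
    around its own position; a cell's final value is therefore the number of
    object pixels lying at (rounded) distance r from it.
    """
    mask = np.asarray(mask, dtype=bool)
    offs = ring_offsets(r)
    n_pix = int(mask.sum())
    if n_pix * len(offs) <= 2_000_000:
        acc = np.zeros(mask.shape, dtype=np.int64)
        pix = np.argwhere(mask)
        if n_pix:
            cand = pix[:, None, :] + offs[None, :, :]
            cand = cand.reshape(-1, 2)
            ok = ((cand[:, 0] >= 0) & (cand[:, 0] < mask.shape[0])
                  & (cand[:, 1] >= 0) & (cand[:, 1] < mask.shape[1]))
            cand = cand[ok]
            np.add.at(acc, (cand[:, 0], cand[:, 1]), 1)
        return acc
    # Large masks: the scatter is a convolution with the (symmetric) ring
    # kernel; FFT error is far below 0.5 for integer counts, so rounding
    # recovers the exact vote counts.
    kernel = np.zeros((2 * r + 1, 2 * r + 1), dtype=np.float64)
    kernel[offs[:, 0] + r, offs[:, 1] + r] = 1.0
    acc = fftconvolve(mask.astype(np.float64), kernel, mode="same")
    return np.rint(acc).astype(np.int64)


def _radius_list(radii) -> list[int]:
    if isinstance(radii, tuple) and len(radii) == 2 and all(np.isscalar(x) for x in radii):
        lo, hi = int(radii[0]), int(radii[1])
        if lo > hi:
            raise ValueError("radius range is empty")
        return list(range(lo, hi + 1))
    rs = sorted(int(r) for r in radii)
    if not rs:
        raise ValueError("radius range is empty")
    return rs


def hough_circle(mask: np.ndarray, radii) -> ROICircle:
    """Best-supported circle over a radius range.

    ``radii`` is an inclusive ``(lo, hi)`` pair or an iterable of candidate
    radii.  Returns the (x0, y0, r) with the maximal accumulator value; ties
    are broken towards the smallest radius, then row-major pixel order.
    Raises ``ValueError`` on an empty mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot run the Hough transform on an empty mask")
    best = None  # (score, r, y, x)
    for r in _radius_list(radii):
        acc = hough_accumulator(mask, r)
        idx = int(np.argmax(acc))  # first maximum in row-major order
        score = int(acc.flat[idx])
        if best is None or score > best[0]:
            y, x = divmod(idx, mask.shape[1])
            best = (score, r, y, x)
    score, r, y, x = best
    return ROICircle(x0=x, y0=y, r=r, score=score)


def shrink_roi(c: ROICircle, margin: int = 10) -> ROICircle:
    """Shrink the detected circle so the frame itself stays outside the ROI."""
    if c.r <= margin:
        raise ValueError(f"radius {c.r} does not exceed shrink margin {margin}")
    return ROICircle(x0=c.x0, y0=c.y0, r=c.r - margin, score=c.score)


def roi_mask(shape: tuple[int, int], c: ROICircle) -> np.ndarray:
    """Boolean disc mask: pixel centres with (x-x0)^2 + (y-y0)^2 <= r^2."""
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (xx - c.x0) ** 2 + (yy - c.y0) ** 2 <= c.r**2


def apply_roi(rgb: np.ndarray, c: ROICircle) -> np.ndarray:
    """Attach the ROI as an alpha channel: opaque inside the circle, transparent outside."""
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("expected an HxWx3 RGB image")
    alpha = roi_mask(rgb.shape[:2], c).astype(np.uint8) * 255
    return np.dstack([rgb, alpha])


# ---------------------------------------------------------------------------
# Excess-green segmentation and coverage

def exg_image(rgb: np.ndarray) -> np.ndarray:
    """Excess green index 2G - R - B per pixel, clipped to [0, 255].

    Green vegetation appears bright against soil and the grey frame, both of
    which fall at or below zero before clipping.
    """
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("expected an HxWx3 RGB image")
    r = rgb[..., 0].astype(np.int16)
    g = rgb[..., 1].astype(np.int16)
    b = rgb[..., 2].astype(np.int16)
    return np.clip(2 * g - r - b, 0, 255).astype(np.uint8)


def exg_threshold(fraction: float = 0.08) -> int:
    """Grey level for an ExG fraction of full scale: truncate(255 * fraction).

    The default 8 % maps to grey level 20.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie strictly between 0 and 1")
    return int(255 * fraction)


def segment_plants(exg: np.ndarray, fraction: float = 0.08) -> np.ndarray:
    """Plant mask: pixels whose ExG strictly exceeds the threshold grey level."""
    return np.asarray(exg) > exg_threshold(fraction)


def coverage(plant: np.ndarray, roi: np.ndarray) -> CoverageResult:
    """Plant coverage C = pf / (pf + pb), counting ROI pixels only."""
    plant = np.asarray(plant, dtype=bool)
    roi = np.asarray(roi, dtype=bool)
    if plant.shape != roi.shape:
        raise ValueError("plant mask and ROI mask must share dimensions")
    n_roi = int(roi.sum())
    if n_roi == 0:
        raise ValueError("empty ROI: coverage is undefined")
    pf = int((plant & roi).sum())
    return CoverageResult(pf=pf, pb=n_roi - pf)


# ---------------------------------------------------------------------------
# Convenience chains

def detect_roi(rgb: np.ndarray, radii, thr: HsvThresholds = HsvThresholds(),
               median_size: int = 10, shrink: int = 10) -> tuple[ROICircle, ROICircle]:
    """Frame segmentation -> median -> Hough -> shrink; returns (frame circle, ROI)."""
    hsv = rgb_to_hsv8(rgb)
    mask = median_majority(segment_frame(hsv, thr), size=median_size)
    circle = hough_circle(mask, radii)
    return circle, shrink_roi(circle, shrink)


def measure_plot(rgb: np.ndarray, radii, thr: HsvThresholds = HsvThresholds(),
                 median_size: int = 10, shrink: int = 10,
                 exg_fraction: float = 0.08) -> PlotMeasurement:
    """Run the full imaging chain on one photograph and return coverage."""
    circle, roi = detect_roi(rgb, radii, thr=thr, median_size=median_size, shrink=shrink)
    plants = segment_plants(exg_image(rgb), exg_fraction)
    res = coverage(plants, roi_mask(rgb.shape[:2], roi))
    return PlotMeasurement(circle=circle, roi=roi, result=res)


# ---------------------------------------------------------------------------
# Image IO

def read_image(path) -> np.ndarray:
    """Load an image file as an HxWx3 uint8 RGB array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def write_image(path, arr: np.ndarray) -> None:
    """Write an RGB, RGBA or single-channel uint8 array as an image file."""
    Image.fromarray(np.asarray(arr, dtype=np.uint8)).save(path)
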