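"""Image-based freshness index for powder photographs.

A fresh powder occupies a characteristic box in RGB space.  Thresholding a
photograph with per-channel intensity ranges gives a binary "fresh" mask;
the freshness index is the percentage ratio between the in-range (white)
pixel count of an image and that of the time-zero baseline, so the baseline
itself scores 100 %.  Moisture-driven caking changes the powder's
light-scattering and drives pixels out of the fresh box, pulling the index
down.

Default ranges for instant coffee: R 70–190, G 55–170, B 10–90, membership
inclusive on both bounds and required on all three channels simultaneously.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from PIL import Image
from scipy import stats

from .exceptions import DomainError, FormatError

__all__ = [
    "RGBRanges", "FreshnessResult", "load_image", "fresh_mask",
    "freshness_index", "calibrate_ranges", "pearson_r", "write_mask_png",
]


@dataclass(frozen=True)
class RGBRanges:
    """Inclusive per-channel intensity ranges defining 'fresh' pixels."""

    r_min: int = 70
    r_max: int = 190
    g_min: int = 55
    g_max: int = 170
    b_min: int = 10
    b_max: int = 90

    def __post_init__(self):
        for lo, hi, name in ((self.r_min, self.r_max, "R"),
                             (self.g_min, self.g_max, "G"),
                             (self.b_min, self.b_max, "B")):
            if not (0 <= lo <= hi <= 255):
                raise DomainError(f"{name} range [{lo}, {hi}] invalid")

    @property
    def lows(self):
        return np.array([self.r_min, self.g_min, self.b_min])

    @property
    def highs(self):
        return np.array([self.r_max, self.g_max, self.b_max])


@dataclass(frozen=True)
class FreshnessResult:
    """Pixel counts and the normalised freshness index (%)."""

    n_in_range: int
    n_total: int
    baseline_in_range: int
    index: float

    def __post_init__(self):
        if not (0 <= self.n_in_range <= self.n_total):
            raise DomainError("in-range count must lie in [0, n_total]")


def load_image(path) -> np.ndarray:
    """Load a PNG/TIFF photograph as an 8-bit RGB array (alpha dropped)."""
    with Image.open(path) as im:
        if im.mode in ("L", "I", "I;16", "F", "1", "LA"):
            raise FormatError(f"image is not RGB (mode {im.mode})")
        return np.asarray(im.convert("RGB"), dtype=np.uint8)


def _as_rgb_array(image) -> np.ndarray:
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise FormatError(
            f"expected an HxWx3 RGB image, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        if np.any(arr < 0) or np.any(arr > 255):
            raise FormatError("channel values must lie in [0, 255]")
        arr = arr.astype(np.uint8)
    return arr


def fresh_mask(image, ranges: RGBRanges = RGBRanges()) -> np.ndarray:
    """Binary mask: True (white) where all three channels sit inside their
    inclusive ranges."""
    arr = _as_rgb_array(image)
    return np.all((arr >= ranges.lows) & (arr <= ranges.highs), axis=2)


def freshness_index(image, ranges: RGBRanges,
                    baseline_in_range: int) -> FreshnessResult:
    """Freshness index of an image against a baseline white-pixel count.

    index = 100 · n_in_range / baseline_in_range, not clamped above 100.
    """
    if baseline_in_range <= 0:
        raise DomainError("baseline in-range pixel count must be > 0")
    mask = fresh_mask(image, ranges)
    n_in = int(mask.sum())
    return FreshnessResult(
        n_in_range=n_in, n_total=int(mask.size),
        baseline_in_range=int(baseline_in_range),
        index=100.0 * n_in / baseline_in_range)


def calibrate_ranges(reference, coverage: float = 0.99) -> RGBRanges:
    """Derive fresh ranges from a reference photograph.

    Takes the symmetric per-channel quantile interval
    [(1−coverage)/2, 1−(1−coverage)/2], rounded outward to integers.  The
    reference image's own in-range fraction under the result must be at
    least coverage − 0.03 (sanity check on the joint coverage).
    """
    if not (0.0 < coverage <= 1.0):
        raise DomainError(f"coverage must lie in (0, 1]: {coverage}")
    arr = _as_rgb_array(reference)
    flat = arr.reshape(-1, 3).astype(float)
    lo_q = (1.0 - coverage) / 2.0
    lows = np.floor(np.quantile(flat, lo_q, axis=0)).astype(int)
    highs = np.ceil(np.quantile(flat, 1.0 - lo_q, axis=0)).astype(int)
    lows = np.clip(lows, 0, 255)
    highs = np.clip(highs, 0, 255)
    ranges = RGBRanges(r_min=int(lows[0]), r_max=int(highs[0]),
                       g_min=int(lows[1]), g_max=int(highs[1]),
                       b_min=int(lows[2]), b_max=int(highs[2]))
    frac = fresh_mask(arr, ranges).mean()
    if frac < coverage - 0.03:
        raise DomainError(
            f"calibrated ranges cover only {frac:.3f} of the reference "
            f"(need >= {coverage - 0.03:.3f})")
    return ranges


def pearson_r(x, y) -> float:
    """Product-moment correlation between two equal-length series (n >= 3)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise DomainError("need equal-length 1-D series with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DomainError("correlation undefined for zero-variance series")
    return float(stats.pearsonr(x, y)[0])


def write_mask_png(mask: np.ndarray, path) -> None:
    """Write a binary mask as a 1-bit PNG (white = in range)."""
    Image.fromarray(np.asarray(mask, bool)).convert("1").save(path)


def freshness_table(results: dict[float, FreshnessResult]) -> pd.DataFrame:
    """Tabulate a freshness trajectory: time, index %, pixel counts."""
    rows = [{"time": t, "index_pct": r.index, "n_in_range": r.n_in_range,
             "n_total": r.n_total} for t, r in sorted(results.items())]
    return pd.DataFrame(rows)
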