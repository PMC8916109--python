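"""Weighted seasonal compositing of daily 4-band reflectance stacks.

A season's worth of daily scenes is collapsed into one composite per tile by
a per-pixel, per-band weighted mean.  Two multiplicative weights suppress
contaminated observations:

* a *haze* weight ``W1 = 1 / blue**2`` — clouds and haze brighten the blue
  band, so bright-blue dates are strongly down-weighted;
* a *shadow* weight ``W2 = 1 / NIR**4`` applied when a date's NIR falls
  below the pixel's in-season NIR median, and 1 otherwise.

Note the shadow weight, taken at face value, *increases* the weight of dark
(low-NIR) dates rather than suppressing them; it is kept in that form as the
default (``shadow_weight_mode="as_printed"``) with an alternative
``"dark_downweight"`` mode (``W2 = NIR**4``) that matches the stated intent
of suppressing cloud shadow.  See docs/methods.md.

Reflectance is unitless surface reflectance on [0, 1].  Inputs stored as
scaled integers must be divided by their scale factor before entering this
module — both weights are scale-sensitive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import date as _date
from typing import Sequence

import numpy as np

__all__ = [
    "EPS",
    "PixelSeries",
    "SeasonWindow",
    "SeasonalComposite",
    "QualityGrade",
    "haze_weight",
    "shadow_weight",
    "composite_pixel",
    "composite_tile",
    "quality_score",
    "expected_composite_count",
]

#: clamp for zero reflectance in the weight denominators
EPS = 1e-4

BAND_NAMES = ("blue", "green", "red", "nir")


@dataclass
class PixelSeries:
    """Dated 4-band reflectance observations at one pixel.

    ``reflectance`` has shape (n_dates, 4) ordered (blue, green, red, NIR);
    ``valid`` marks dates usable for compositing (cloud-mask bits, if
    available, are folded in upstream).
    """

    dates: Sequence[_date]
    reflectance: np.ndarray
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.reflectance.ndim != 2 or self.reflectance.shape[1] != 4:
            raise ValueError("reflectance must have shape (n_dates, 4)")
        if len(self.dates) != self.reflectance.shape[0]:
            raise ValueError("dates and reflectance length mismatch")
        if self.valid is None:
            self.valid = np.ones(len(self.dates), dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        if not np.all(np.isfinite(self.reflectance[self.valid])):
            raise ValueError("valid reflectance must be finite")
        if np.any(self.reflectance[self.valid] < 0):
            raise ValueError("reflectance must be non-negative")


@dataclass(frozen=True)
class SeasonWindow:
    """A compositing period, e.g. growing = May–September."""

    label: str
    start: _date
    end: _date

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("season start must precede end")

    def contains(self, d: _date) -> bool:
        return self.start <= d <= self.end


@dataclass
class SeasonalComposite:
    """Per-tile weighted-mean composite for one season.

    ``data`` has shape (4, H, W); ``count`` is the number of contributing
    dates per pixel; pixels with zero valid in-window dates are nodata
    (``count == 0``, data NaN).
    """

    data: np.ndarray
    season: str
    count: np.ndarray

    @property
    def nodata_mask(self) -> np.ndarray:
        return self.count == 0


def haze_weight(blue: np.ndarray | float, eps: float = EPS) -> np.ndarray | float:
    """Haze/cloud suppression weight ``1 / max(blue, eps)**2``."""
    b = np.asarray(blue, dtype=float)
    if np.any(b < 0):
        raise ValueError("blue reflectance must be non-negative")
    w = 1.0 / np.maximum(b, eps) ** 2
    return w if w.ndim else float(w)


def shadow_weight(
    nir_t: float,
    nir_series: Sequence[float],
    mode: str = "as_printed",
    eps: float = EPS,
) -> float:
    """Shadow weight for one date against the pixel's in-season NIR series.

    Dates at or above the series median get weight 1.  Below the median,
    ``as_printed`` returns ``1 / max(NIR, eps)**4`` and ``dark_downweight``
    returns ``NIR**4``.
    """
    series = np.asarray(nir_series, dtype=float)
    if series.size == 0:
        raise ValueError("NIR series must be non-empty")
    med = float(np.median(series))
    if nir_t >= med:
        return 1.0
    if mode == "as_printed":
        return float(1.0 / np.maximum(nir_t, eps) ** 4)
    if mode == "dark_downweight":
        return float(nir_t**4)
    raise ValueError(f"unknown shadow_weight_mode {mode!r}")


def _composite_weights(
    blue: np.ndarray, nir: np.ndarray, mode: str, eps: float
) -> np.ndarray:
    """Combined per-date weights W1*W2 for arrays of in-window observations."""
    w1 = 1.0 / np.maximum(blue, eps) ** 2
    med = np.median(nir)
    below = nir < med
    if mode == "as_printed":
        w2 = np.where(below, 1.0 / np.maximum(nir, eps) ** 4, 1.0)
    elif mode == "dark_downweight":
        w2 = np.where(below, nir**4, 1.0)
    else:
        raise ValueError(f"unknown shadow_weight_mode {mode!r}")
    return w1 * w2


def composite_pixel(
    series: PixelSeries,
    season: SeasonWindow,
    mode: str = "as_printed",
    eps: float = EPS,
) -> np.ndarray:
    """Weighted-mean 4-vector for one pixel over one season.

    Returns an all-NaN vector when no valid date falls inside the window.
    The result is bounded, per band, by the contributing observations.
    """
    in_window = np.array([season.contains(d) for d in series.dates], dtype=bool)
    use = in_window & series.valid
    if not np.any(use):
        return np.full(4, np.nan)
    refl = series.reflectance[use]
    w = _composite_weights(refl[:, 0], refl[:, 3], mode, eps)
    return (refl * w[:, None]).sum(axis=0) / w.sum()


def composite_tile(
    dates: Sequence[_date],
    stack: np.ndarray,
    season: SeasonWindow,
    valid: np.ndarray | None = None,
    mode: str = "as_printed",
    eps: float = EPS,
) -> SeasonalComposite:
    """Vectorized per-pixel compositing over a (n_dates, 4, H, W) stack.

    ``valid`` is an optional (n_dates, H, W) boolean mask.  Equivalent to
    applying :func:`composite_pixel` independently at each pixel.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 4 or stack.shape[1] != 4:
        raise ValueError("stack must have shape (n_dates, 4, H, W)")
    if len(dates) != stack.shape[0]:
        raise ValueError("dates and stack length mismatch")
    if stack.shape[0] == 0:
        raise ValueError("empty stack")
    n, _, h, w_ = stack.shape
    if valid is None:
        valid = np.ones((n, h, w_), dtype=bool)
    else:
        valid = np.asarray(valid, dtype=bool)
        if valid.shape != (n, h, w_):
            raise ValueError("validity mask shape mismatch with stack grid")

    in_window = np.array([season.contains(d) for d in dates], dtype=bool)
    use = valid & in_window[:, None, None]  # (n, H, W)

    blue = stack[:, 0]
    nir = stack[:, 3]
    # per-pixel median of in-window valid NIR
    nir_masked = np.where(use, nir, np.nan)
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-nodata pixels
        med = np.nanmedian(nir_masked, axis=0)  # (H, W)

    w1 = 1.0 / np.maximum(blue, eps) ** 2
    below = nir < med[None, :, :]
    if mode == "as_printed":
        w2 = np.where(below, 1.0 / np.maximum(nir, eps) ** 4, 1.0)
    elif mode == "dark_downweight":
        w2 = np.where(below, nir**4, 1.0)
    else:
        raise ValueError(f"unknown shadow_weight_mode {mode!r}")
    w = np.where(use, w1 * w2, 0.0)  # (n, H, W)

    wsum = w.sum(axis=0)  # (H, W)
    num = (stack * w[:, None, :, :]).sum(axis=0)  # (4, H, W)
    count = use.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        data = np.where(count[None] > 0, num / wsum[None], np.nan)
    return SeasonalComposite(data=data, season=season.label, count=count)


@dataclass(frozen=True)
class QualityGrade:
    """Manual composite quality grades, each category 0 (worst) to 3 (best).

    Categories: residual cloud, cloud shadow, scene-seam artifacts, and
    resolution degradation.  The rescaled score is the grade sum over the
    maximum attainable 12.
    """

    cloud: int
    shadow: int
    seam: int
    resolution: int

    def __post_init__(self) -> None:
        for g in (self.cloud, self.shadow, self.seam, self.resolution):
            if g not in (0, 1, 2, 3):
                raise ValueError("grades must be integers in {0,1,2,3}")


def quality_score(grades: QualityGrade) -> float:
    """Rescaled composite quality score in [0, 1] (grade sum / 12)."""
    return (grades.cloud + grades.shadow + grades.seam + grades.resolution) / 12.0


def expected_composite_count(n_tiles: int, n_seasons: int = 2) -> int:
    """Catalog size: one composite per (tile, season)."""
    if n_tiles < 0 or n_seasons < 0:
        raise ValueError("counts must be non-negative")
    return n_tiles * n_seasons
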