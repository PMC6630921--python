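"""Canopy temperature (Tc) and stress degree day (SDD) from thermal images.

A thermal raster assigns a temperature (°C) to every pixel.  Plot-level
canopy temperature is obtained by (1) cropping a central region of
interest so neighbouring plots do not contaminate the reading, (2)
discarding non-canopy pixels (soil, weeds, air) with a mask or a
temperature band, (3) trimming the coldest and hottest tails of the
remaining temperature histogram, and (4) averaging what is left.  The
stress degree day is SDD = Tc - Ta, where Ta is the air temperature at
capture time: a canopy warmer than the air indicates reduced
transpirational cooling, i.e. water stress.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

#: Plausibility window for pixel temperatures (°C).  Values outside this
#: range almost always mean a raw-count (non-radiometric) raster was read
#: as if it were degrees Celsius, so they are rejected at load time.
TEMP_MIN_C = -20.0
TEMP_MAX_C = 70.0

__all__ = [
    "TEMP_MIN_C",
    "TEMP_MAX_C",
    "ThermalImage",
    "CanopyMask",
    "TrimConfig",
    "TcSummary",
    "DimensionError",
    "EmptyCanopyError",
    "ShapeMismatchError",
    "read_thermal_image",
    "read_mask",
    "central_roi",
    "trim_by_percentiles",
    "segment_canopy",
    "extract_tc",
]


class DimensionError(ValueError):
    """A requested crop does not fit inside the image."""


class EmptyCanopyError(ValueError):
    """No canopy pixels survive segmentation; thresholds need review."""


class ShapeMismatchError(ValueError):
    """Mask and image shapes disagree."""


@dataclass
class ThermalImage:
    """Rectangular grid of pixel temperatures in °C.

    Parameters
    ----------
    pixels
        2-D array of temperatures (°C).  Must be finite and inside the
        plausibility window ``[TEMP_MIN_C, TEMP_MAX_C]``.
    capture_time
        Optional acquisition timestamp (ISO-8601 string).
    plot_id
        Optional plot label.
    """

    pixels: np.ndarray
    capture_time: Optional[str] = None
    plot_id: Optional[str] = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError(f"pixels must be a non-empty 2-D grid, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError("thermal image contains non-finite pixel values")
        lo, hi = float(px.min()), float(px.max())
        if lo < TEMP_MIN_C or hi > TEMP_MAX_C:
            raise ValueError(
                f"pixel temperatures [{lo:.2f}, {hi:.2f}] °C outside the plausibility "
                f"window [{TEMP_MIN_C}, {TEMP_MAX_C}] °C; is this a radiometric raster?"
            )
        self.pixels = px

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class CanopyMask:
    """Boolean keep-grid paired with a thermal image of the same shape."""

    keep: np.ndarray

    def __post_init__(self) -> None:
        self.keep = np.asarray(self.keep, dtype=bool)
        if self.keep.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {self.keep.shape}")

    @property
    def n_kept(self) -> int:
        return int(self.keep.sum())


@dataclass(frozen=True)
class TrimConfig:
    """Region-of-interest size and percentile trim thresholds.

    Defaults follow the published protocol: a 30 x 30 pixel centre crop,
    with pixels below the 1st or above the 97.5th percentile discarded.
    """

    roi_size: int = 30
    low_percentile: float = 1.0
    high_percentile: float = 97.5

    def __post_init__(self) -> None:
        if self.roi_size < 1:
            raise ValueError(f"roi_size must be >= 1, got {self.roi_size}")
        if not (0.0 <= self.low_percentile < self.high_percentile <= 100.0):
            raise ValueError(
                "require 0 <= low_percentile < high_percentile <= 100, got "
                f"({self.low_percentile}, {self.high_percentile})"
            )


@dataclass
class TcSummary:
    """Canopy-temperature result with a trimming audit trail.

    ``sdd = tc - ta`` always holds; counts record how many pixels the
    ROI contained, how many passed the canopy mask, and how many
    survived the percentile trim.  ``p_low``/``p_high`` are the realized
    trim thresholds in °C.
    """

    tc: float
    ta: float
    sdd: float
    n_roi: int
    n_masked: int
    n_retained: int
    p_low: float
    p_high: float
    config: TrimConfig = field(default_factory=TrimConfig)

    def to_dict(self) -> dict:
        return {
            "tc_c": self.tc,
            "ta_c": self.ta,
            "sdd_c": self.sdd,
            "n_roi": self.n_roi,
            "n_masked": self.n_masked,
            "n_retained": self.n_retained,
            "p_low_c": self.p_low,
            "p_high_c": self.p_high,
            "roi_size": self.config.roi_size,
            "low_percentile": self.config.low_percentile,
            "high_percentile": self.config.high_percentile,
        }


def read_thermal_image(path, plot_id: Optional[str] = None) -> ThermalImage:
    """Read a single-band thermal raster in °C.

    ``.tif``/``.tiff`` files are read with :mod:`tifffile`; anything else
    is treated as a headerless CSV matrix (one row per image row).
    """
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        px = np.asarray(tifffile.imread(path), dtype=float)
        if px.ndim == 3 and px.shape[2] == 1:
            px = px[:, :, 0]
    else:
        px = np.loadtxt(path, delimiter=",", dtype=float, ndmin=2)
    return ThermalImage(px, plot_id=plot_id or path.stem)


def read_mask(path) -> CanopyMask:
    """Read a canopy mask (PNG or 0/1 CSV); non-zero means keep."""
    path = Path(path)
    if path.suffix.lower() == ".png":
        import imageio.v3 as iio

        arr = np.asarray(iio.imread(path))
        if arr.ndim == 3:  # collapse colour channels
            arr = arr[..., :3].max(axis=2)
    else:
        arr = np.loadtxt(path, delimiter=",", ndmin=2)
    return CanopyMask(arr != 0)


def central_roi(image: ThermalImage, roi_size: int) -> ThermalImage:
    """Centered square crop of ``roi_size`` pixels per side.

    When ``(dimension - roi_size)`` is odd the extra row/column is
    dropped on the high-index side.  The returned grid is a view sharing
    values with the source.
    """
    h, w = image.height, image.width
    if roi_size > min(h, w):
        raise DimensionError(
            f"roi_size {roi_size} exceeds image dimensions {h}x{w}"
        )
    r0 = (h - roi_size) // 2
    c0 = (w - roi_size) // 2
    sub = image.pixels[r0 : r0 + roi_size, c0 : c0 + roi_size]
    return ThermalImage(sub, capture_time=image.capture_time, plot_id=image.plot_id)


def trim_by_percentiles(
    values, low_percentile: float = 1.0, high_percentile: float = 97.5
):
    """Drop the coldest/hottest tails of a temperature sample.

    Thresholds are percentiles computed with linear interpolation
    between closest order statistics (numpy's default); the retained
    interval ``[p_low, p_high]`` is closed on both ends, so a constant
    sample is retained in full.

    Degenerate samples: if the interval contains no sample value at all
    (possible only for two distinct values, whose interpolated
    thresholds fall strictly between them), trimming is meaningless and
    the full sample is retained, with the realized thresholds widened
    to the sample min/max.  The result is therefore never empty.

    Returns
    -------
    (retained, p_low, p_high)
        ``retained`` is a 1-D array of the surviving values in input
        order; ``p_low``/``p_high`` the realized thresholds in °C.
    """
    vals = np.asarray(values, dtype=float).ravel()
    if vals.size == 0:
        raise ValueError("cannot trim an empty collection of temperatures")
    if not (0.0 <= low_percentile < high_percentile <= 100.0):
        raise ValueError(
            f"invalid percentile bounds ({low_percentile}, {high_percentile})"
        )
    p_low, p_high = np.percentile(vals, [low_percentile, high_percentile])
    retained = vals[(vals >= p_low) & (vals <= p_high)]
    if retained.size == 0:
        retained, p_low, p_high = vals, vals.min(), vals.max()
    return retained, float(p_low), float(p_high)


def segment_canopy(
    image: ThermalImage,
    mode: str = "band_threshold",
    mask: Optional[CanopyMask] = None,
    t_min: Optional[float] = None,
    t_max: Optional[float] = None,
) -> CanopyMask:
    """Separate canopy from soil/weeds/air.

    Two modes replace interactive segmentation:

    ``external_mask``
        Pass through a mask produced elsewhere (shape-checked).
    ``band_threshold``
        Keep pixels with ``t_min <= T <= t_max``.  Canopy is cooler than
        sunlit soil at midday, so a band just above the canopy mode
        separates the classes.
    """
    if mode == "external_mask":
        if mask is None:
            raise ValueError("external_mask mode requires a mask")
        if mask.keep.shape != image.pixels.shape:
            raise ShapeMismatchError(
                f"mask shape {mask.keep.shape} != image shape {image.pixels.shape}"
            )
        return mask
    if mode == "band_threshold":
        if t_min is None or t_max is None or not (t_min < t_max):
            raise ValueError("band_threshold mode requires t_min < t_max")
        keep = (image.pixels >= t_min) & (image.pixels <= t_max)
        if not keep.any():
            raise EmptyCanopyError(
                f"temperature band [{t_min}, {t_max}] °C keeps no pixels; "
                "review thresholds against the image histogram"
            )
        return CanopyMask(keep)
    raise ValueError(f"unknown segmentation mode {mode!r}")


def extract_tc(
    image: ThermalImage,
    ta: float,
    mask: Optional[CanopyMask] = None,
    config: TrimConfig = TrimConfig(),
) -> TcSummary:
    """ROI crop -> canopy mask -> percentile trim -> mean Tc; SDD = Tc - Ta.

    Parameters
    ----------
    image
        Full thermal raster.
    ta
        Air temperature at capture time (°C), from the nearest weather
        station record.
    mask
        Optional canopy mask for the *full* image (cropped alongside the
        ROI).  ``None`` keeps every ROI pixel.
    config
        ROI size and trim percentiles.

    Negative SDD is legitimate: a freely transpiring canopy is cooler
    than the air.
    """
    if mask is not None and mask.keep.shape != image.pixels.shape:
        raise ShapeMismatchError(
            f"mask shape {mask.keep.shape} != image shape {image.pixels.shape}"
        )
    roi = central_roi(image, config.roi_size)
    n_roi = roi.pixels.size
    if mask is not None:
        h, w = image.height, image.width
        r0 = (h - config.roi_size) // 2
        c0 = (w - config.roi_size) // 2
        keep = mask.keep[r0 : r0 + config.roi_size, c0 : c0 + config.roi_size]
    else:
        keep = np.ones(roi.pixels.shape, dtype=bool)
    canopy_vals = roi.pixels[keep]
    if canopy_vals.size == 0:
        raise EmptyCanopyError("no canopy pixels inside the region of interest")
    retained, p_low, p_high = trim_by_percentiles(
        canopy_vals, config.low_percentile, config.high_percentile
    )
    tc = float(retained.mean())
    return TcSummary(
        tc=tc,
        ta=float(ta),
        sdd=tc - float(ta),
        n_roi=int(n_roi),
        n_masked=int(canopy_vals.size),
        n_retained=int(retained.size),
        p_low=p_low,
        p_high=p_high,
        config=config,
    )
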