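"""Differential rhodopsin imaging and quantification.

The molecular contrast is the change in backscattered intensity between the
dark-adapted retina (rhodopsin absorbs the 520 nm probe, single-pass decadic
OD per pass, crossed twice) and the light-adapted retina (pigment bleached,
transparent).  The normalized per-pixel differential

    relative:     D = (I2 - I1) / max(I2, floor)
    log_density:  D = log10(max(I2, floor) / max(I1, floor))

with I1 the dark- and I2 the light-adapted intensity, is computed either on
IS/OS-forward en face projections (lateral x-y map) or on averaged B-scans
(depth-resolved x-z map).  On the log scale the differential below the outer
segments equals twice the cumulative rhodopsin OD above — the double-pass
shadow — so half the log ratio of the projections is a per-pixel estimate of
the single-pass OD, i.e. a rhodopsin map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu
from scipy import ndimage

from .segment import BoundaryMap
from .simulate import OCTVolume

__all__ = [
    "EnFaceImage",
    "DifferentialImage",
    "DepthProfile",
    "ROIStats",
    "RhodopsinMap",
    "enface_projection",
    "differential_image",
    "average_alines",
    "roi_stats",
    "estimate_rhodopsin_od",
    "detect_bleach_pattern",
    "bleach_energy_per_point",
    "percent_lower",
]

#: default intensity floor as a fraction of the brighter image maximum
FLOOR_FRAC = 1e-6


@dataclass
class EnFaceImage:
    """(y, x) sum of linear intensity from the IS/OS forward."""

    value: np.ndarray
    band_extent: int
    boundary_hash: int = 0
    truncated: bool = False  # band clipped at the deep end of the volume


@dataclass
class DifferentialImage:
    """Normalized dark/light difference in the x-y or x-z plane."""

    value: np.ndarray
    plane: str                      # xy | xz
    i1_label: str = "dark"
    i2_label: str = "light"
    normalization: str = "relative" # relative | log_density


@dataclass
class DepthProfile:
    """Per-depth average of a differential B-scan over the lateral axis."""

    value: np.ndarray
    z_pitch: float


@dataclass
class ROIStats:
    roi_name: str
    mean: float
    sd: float
    n_pixels: int


@dataclass
class RhodopsinMap:
    """Single-pass decadic OD estimate per (y, x)."""

    od_estimate: np.ndarray
    valid_mask: np.ndarray


def enface_projection(
    volume: OCTVolume, boundary: BoundaryMap, band_extent: int | None = None
) -> EnFaceImage:
    """Sum linear intensity from the IS/OS forward along depth.

    value(y, x) = sum_{z = isos}^{isos + band_extent - 1} I(y, x, z); the
    band is truncated at the deep end of the volume (noted on the result).
    ``band_extent=None`` sums to the deepest pixel.
    """
    if boundary.shape != volume.shape[:2]:
        raise ValueError("boundary map does not match volume lateral grid")
    n_y, n_x, n_z = volume.shape
    if band_extent is None:
        band_extent = n_z
    if band_extent <= 0:
        raise ValueError("band_extent must be positive")
    isos = boundary.isos_z
    # cumulative sum along z gives each A-line band sum in O(1)
    csum = np.concatenate(
        [
            np.zeros((n_y, n_x, 1), dtype=np.float64),
            np.cumsum(volume.intensity, axis=2, dtype=np.float64),
        ],
        axis=2,
    )
    z0 = np.clip(isos, 0, n_z)
    z1 = np.clip(isos + band_extent, 0, n_z)
    value = np.take_along_axis(csum, z1[..., None], axis=2)[..., 0] - np.take_along_axis(
        csum, z0[..., None], axis=2
    )[..., 0]
    truncated = bool(np.any(isos + band_extent > n_z))
    return EnFaceImage(
        value=value,
        band_extent=int(band_extent),
        boundary_hash=hash(boundary.isos_z.tobytes()),
        truncated=truncated,
    )


def _as_array(img) -> np.ndarray:
    if isinstance(img, EnFaceImage):
        return np.asarray(img.value, dtype=np.float64)
    return np.asarray(img, dtype=np.float64)


def differential_image(
    i1,
    i2,
    normalization: str = "relative",
    floor: float | None = None,
    plane: str = "xy",
    i1_label: str = "dark",
    i2_label: str = "light",
) -> DifferentialImage:
    """Normalized differential of two same-plane images (I1 dark, I2 light)."""
    a1, a2 = _as_array(i1), _as_array(i2)
    if a1.shape != a2.shape:
        raise ValueError(f"image shapes differ: {a1.shape} vs {a2.shape}")
    if floor is None:
        floor = FLOOR_FRAC * max(float(a2.max()), np.finfo(float).tiny)
    if floor <= 0:
        raise ValueError("floor must be positive")
    if normalization == "relative":
        value = (a2 - a1) / np.maximum(a2, floor)
    elif normalization == "log_density":
        value = np.log10(np.maximum(a2, floor) / np.maximum(a1, floor))
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    return DifferentialImage(value, plane, i1_label, i2_label, normalization)


def average_alines(
    diff_bscan: DifferentialImage, exclude_mask: np.ndarray | None = None
) -> DepthProfile:
    """Average the A-lines of an x-z differential over the lateral axis.

    ``exclude_mask`` marks lateral positions (e.g. the optic disc) left out
    of the mean.
    """
    if diff_bscan.plane != "xz":
        raise ValueError("average_alines expects an x-z differential")
    img = np.asarray(diff_bscan.value)  # (x, z)
    keep = np.ones(img.shape[0], dtype=bool)
    if exclude_mask is not None:
        keep = ~np.asarray(exclude_mask, dtype=bool)
    if not keep.any():
        raise ValueError("all lateral positions excluded")
    return DepthProfile(value=img[keep].mean(axis=0), z_pitch=np.nan)


def roi_stats(image: DifferentialImage | np.ndarray, roi: np.ndarray, name: str = "roi") -> ROIStats:
    """Mean, population SD and pixel count of a differential within a mask."""
    img = image.value if isinstance(image, DifferentialImage) else np.asarray(image)
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != img.shape:
        raise ValueError("ROI mask shape does not match image")
    vals = img[roi]
    if vals.size == 0:
        raise ValueError(f"ROI {name!r} is empty")
    return ROIStats(name, float(vals.mean()), float(vals.std()), int(vals.size))


def percent_lower(inside: float, outside: float) -> float:
    """How much lower (percent) ``inside`` is than ``outside``."""
    return 100.0 * (outside - inside) / outside


def estimate_rhodopsin_od(
    enface_dark: EnFaceImage, enface_light: EnFaceImage, floor: float | None = None
) -> RhodopsinMap:
    """Per-pixel single-pass rhodopsin OD from dark/light projections.

    od = 0.5 * log10(light / dark): the probe crosses the outer segments
    twice, so the decadic log ratio of the projected intensities is twice the
    single-pass OD.  Both projections must use the same boundary and band;
    negative estimates (noise) are clipped to 0 and flagged in the mask.
    """
    if (
        enface_dark.band_extent != enface_light.band_extent
        or enface_dark.boundary_hash != enface_light.boundary_hash
    ):
        raise ValueError("projections use different boundaries or band extents")
    d = np.asarray(enface_dark.value, dtype=np.float64)
    l = np.asarray(enface_light.value, dtype=np.float64)
    if floor is None:
        floor = FLOOR_FRAC * max(float(l.max()), np.finfo(float).tiny)
    od = 0.5 * np.log10(np.maximum(l, floor) / np.maximum(d, floor))
    valid = (l > floor) & (d > floor) & (od >= 0)
    return RhodopsinMap(od_estimate=np.clip(od, 0.0, None), valid_mask=valid)


def detect_bleach_pattern(
    diff: DifferentialImage,
    threshold_method: str = "otsu",
    smooth_sigma: float = 2.0,
    min_separation: float = 0.5,
) -> np.ndarray:
    """Segment the pre-bleached (low-differential) region of an x-y image.

    An Otsu two-class threshold on the lightly smoothed differential returns
    the low-signal class as the bleached mask.  If the histogram is
    effectively unimodal (class means separated by less than
    ``min_separation`` pooled SDs) an empty mask is returned with a warning.
    """
    if threshold_method != "otsu":
        raise ValueError(f"unknown threshold method {threshold_method!r}")
    if diff.plane != "xy":
        raise ValueError("bleach-pattern detection expects an x-y differential")
    img = np.asarray(diff.value, dtype=float)
    if smooth_sigma > 0:
        img = ndimage.gaussian_filter(img, smooth_sigma)
    if np.ptp(img) <= 1e-12:
        warnings.warn("differential is uniform; no bleach pattern found", stacklevel=2)
        return np.zeros(img.shape, dtype=bool)
    t = threshold_otsu(img)
    low = img < t
    if low.all() or not low.any():
        warnings.warn("degenerate threshold; no bleach pattern found", stacklevel=2)
        return np.zeros(img.shape, dtype=bool)
    mu0, mu1 = img[low].mean(), img[~low].mean()
    sd = np.sqrt(0.5 * (img[low].var() + img[~low].var()))
    if (mu1 - mu0) < min_separation * max(sd, 1e-12):
        warnings.warn(
            "differential histogram is unimodal; returning an empty bleach mask",
            stacklevel=2,
        )
        return np.zeros(img.shape, dtype=bool)
    return low


def bleach_energy_per_point(power: float, point_rate: float, passes: int = 1) -> float:
    """Optical energy delivered per illuminated point, J.

    energy = passes * power / point_rate: each raster pass dwells 1/rate
    seconds per point at the given power.
    """
    if power <= 0 or point_rate <= 0 or passes <= 0:
        raise ValueError("power, point_rate and passes must all be positive")
    return passes * power / point_rate
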