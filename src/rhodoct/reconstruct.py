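"""Spectral-domain OCT reconstruction and resolution metrology.

Recorded interference spectra are sampled uniformly in wavelength; the
reconstruction subtracts the reference (DC) spectrum, resamples to a uniform
wavenumber grid with a cubic spline, optionally applies a Hann window,
Fourier transforms, and compensates the spectrometer sensitivity falloff by
element-wise division (floored to avoid noise blow-up at deep pixels).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .simulate import SourceSpectrum, natural_z_pitch_um

__all__ = [
    "CalibrationProfile",
    "reconstruct_aline",
    "reconstruct_many",
    "axial_resolution",
    "air_to_tissue",
    "profile_fwhm",
]

#: minimum relative sensitivity used in falloff compensation
FALLOFF_FLOOR = 0.05


@dataclass(frozen=True)
class CalibrationProfile:
    """Spectrometer calibration: pixel wavelengths, falloff, DC reference."""

    wavelength_grid: np.ndarray   # nm per spectrometer pixel, strictly monotone
    falloff_profile: np.ndarray   # sensitivity per depth pixel, in (0, 1]
    dc_spectrum: np.ndarray       # reference (reflector-free) spectrum

    def __post_init__(self):
        lam = np.asarray(self.wavelength_grid, dtype=float)
        d = np.diff(lam)
        if lam.ndim != 1 or lam.size < 4 or not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("wavelength_grid must be strictly monotone")
        if np.any(np.asarray(self.falloff_profile) <= 0):
            raise ValueError("falloff_profile must be positive")

    @property
    def n_pixels(self) -> int:
        return len(self.wavelength_grid)

    @property
    def n_z(self) -> int:
        return len(self.falloff_profile)

    @property
    def z_pitch_um(self) -> float:
        """Depth pixel pitch implied by the wavenumber span, um."""
        k = 2.0 * np.pi / (np.asarray(self.wavelength_grid, float) * 1e-3)
        span = float(np.abs(k.max() - k.min()))
        n = self.n_pixels
        return np.pi / (span / (n - 1) * n)

    @classmethod
    def from_source(cls, src: SourceSpectrum, dc: float = 1.0) -> "CalibrationProfile":
        """Calibration matching :func:`rhodoct.simulate.spectra_from_reflectors`."""
        lam = src.wavelength_grid()
        return cls(
            wavelength_grid=lam,
            falloff_profile=src.falloff_profile(src.n_pixels // 2),
            dc_spectrum=float(dc) * src.envelope(lam),
        )


def reconstruct_aline(
    spectrum: np.ndarray,
    calib: CalibrationProfile,
    window: str | None = "hann",
    compensate_falloff: bool = True,
    return_complex: bool = False,
) -> np.ndarray:
    """Reconstruct one depth profile from a recorded interference spectrum.

    Steps: DC subtraction, cubic resampling wavelength -> uniform wavenumber,
    window, inverse Fourier transform, magnitude squared, falloff division.
    Output length is ``calib.n_z`` (single-sided depth axis of pitch
    ``calib.z_pitch_um``).  With ``return_complex`` the complex single-sided
    A-line before magnitude/falloff is returned (reconstruction is linear in
    this domain).
    """
    spec = np.asarray(spectrum, dtype=float)
    if spec.shape != (calib.n_pixels,):
        raise ValueError(
            f"spectrum length {spec.shape} does not match calibration "
            f"({calib.n_pixels} pixels)"
        )
    lam = np.asarray(calib.wavelength_grid, dtype=float)
    fringe = spec - np.asarray(calib.dc_spectrum, dtype=float)

    k = 2.0 * np.pi / (lam * 1e-3)  # rad/um
    order = np.argsort(k)
    k_sorted = k[order]
    k_uniform = np.linspace(k_sorted[0], k_sorted[-1], calib.n_pixels)
    fringe_k = CubicSpline(k_sorted, fringe[order])(k_uniform)

    if window == "hann":
        fringe_k = fringe_k * np.hanning(calib.n_pixels)
    elif window not in (None, "none"):
        raise ValueError(f"unknown window {window!r}")

    aline_c = np.fft.fft(fringe_k)[: calib.n_z]
    if return_complex:
        return aline_c
    profile = np.abs(aline_c) ** 2
    if compensate_falloff:
        fall = np.clip(np.asarray(calib.falloff_profile, float), FALLOFF_FLOOR, None)
        profile = profile / fall**2  # falloff scales fringe amplitude
    return profile


def reconstruct_many(spectra: np.ndarray, calib: CalibrationProfile, **kw) -> np.ndarray:
    """Reconstruct an (..., n_pixels) stack of spectra to (..., n_z)."""
    spectra = np.asarray(spectra)
    lead = spectra.shape[:-1]
    flat = spectra.reshape(-1, spectra.shape[-1])
    out = np.stack([reconstruct_aline(s, calib, **kw) for s in flat])
    return out.reshape(*lead, -1)


def profile_fwhm(profile: np.ndarray, pitch: float = 1.0) -> float:
    """FWHM of the dominant peak by linear interpolation at half maximum."""
    p = np.asarray(profile, dtype=float)
    i = int(np.argmax(p))
    half = p[i] / 2.0
    floor = np.median(p)
    if p[i] <= 10.0 * max(floor, np.finfo(float).tiny):
        raise ValueError("no dominant peak above the noise floor")

    def _cross(idx_range):
        prev = i
        for j in idx_range:
            if p[j] <= half:
                # linear interpolation between j and prev
                frac = (p[prev] - half) / (p[prev] - p[j])
                return prev + frac * (j - prev)
            prev = j
        raise ValueError("half-maximum crossing not found; peak truncated")

    left = _cross(range(i - 1, -1, -1))
    right = _cross(range(i + 1, len(p)))
    return float(abs(right - left)) * pitch


def air_to_tissue(fwhm_air: float, refractive_index: float = 1.4) -> float:
    """Convert an in-air axial resolution to tissue (divide by n)."""
    if refractive_index <= 0:
        raise ValueError("refractive index must be positive")
    return fwhm_air / refractive_index


def axial_resolution(
    profile: np.ndarray,
    z_pitch: float,
    refractive_index: float = 1.0,
    domain: str = "intensity",
) -> float:
    """Axial resolution (FWHM, um) of a point-reflector profile.

    Resolution is quoted by convention on the linear-magnitude PSF; for a
    reconstructed magnitude-squared profile (``domain='intensity'``, the
    default) the square root is taken before measuring the FWHM.  ``z_pitch``
    converts pixels to um; dividing by the refractive index maps an in-air
    measurement to tissue.
    """
    p = np.asarray(profile, dtype=float)
    if domain == "intensity":
        p = np.sqrt(np.clip(p, 0.0, None))
    elif domain != "magnitude":
        raise ValueError(f"unknown profile domain {domain!r}")
    return air_to_tissue(profile_fwhm(p, z_pitch), refractive_index)
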