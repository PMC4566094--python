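"""Forward model: phantom -> speckled OCT volumes and raw interference spectra.

The noise-free expectation obeys double-pass Beer-Lambert attenuation,
I(z) = R(z) * 10^(-2 * OD_above(z)), where OD_above accumulates fractionally
through each absorbing layer (the probe crosses the absorber once on the way
in and once on the way out).  The expectation is blurred axially with a
Gaussian PSF (13.7 um FWHM in air / refractive index 1.4 in tissue) in the
incoherent approximation and then modulated by fully developed speckle:
per-voxel intensity is |a|^2 with a a circular complex Gaussian amplitude of
mean-square equal to the expectation (exponential intensity, contrast 1).

Volumes acquired in one session share the scatterer realization — the tissue
did not move between the dark- and light-adapted scans — so the differential
isolates absorption.  Decorrelation between repeat scans enters through
per-A-line axial motion jitter and an additive detection background
(exponential, mean ``noise_floor``), both drawn from acquisition-keyed
streams so a fixed (seed, acquisition) pair is bit-for-bit reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .phantom import PhantomError, RetinaPhantom

__all__ = [
    "ScanParams",
    "SourceSpectrum",
    "OCTVolume",
    "PSF_FWHM_AIR_UM",
    "TISSUE_INDEX",
    "expected_aline",
    "expected_volume",
    "simulate_volume",
    "synthesize_spectra",
    "spectra_from_reflectors",
    "phantom_reflectors",
]

#: measured axial point-spread FWHM of the probe in air, um
PSF_FWHM_AIR_UM = 13.7
#: assumed refractive index of retinal tissue
TISSUE_INDEX = 1.4

_FWHM2SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class ScanParams:
    """Raster-scan geometry and acquisition noise parameters."""

    n_x: int = 512          # A-lines per B-scan (fast axis)
    n_y: int = 128          # B-scans (slow axis)
    n_z: int = 1024         # depth pixels
    z_pitch: float = 2.0    # um per depth pixel in tissue
    line_rate: float = 64_000.0  # A-lines per second
    jitter_sd: float = 0.3  # per-A-line axial shift SD, pixels
    noise_floor: float = 0.02  # additive background mean, reflectivity units
    seed: int = 0

    def __post_init__(self):
        if min(self.n_x, self.n_y, self.n_z) < 1:
            raise ValueError("scan dimensions must be >= 1")
        if self.z_pitch <= 0:
            raise ValueError("z_pitch must be positive")


@dataclass(frozen=True)
class SourceSpectrum:
    """Probe source: 520 nm centre, 9.3 nm FWHM Gaussian, 2048-pixel camera."""

    center: float = 520.0
    fwhm: float = 9.3
    n_pixels: int = 2048
    falloff_half_frac: float = 0.5  # depth fraction at which sensitivity = 0.5

    def __post_init__(self):
        if self.fwhm <= 0:
            raise ValueError("source fwhm must be positive")

    def wavelength_grid(self) -> np.ndarray:
        """Uniform-in-wavelength spectrometer pixel grid, centre +- 3 FWHM, nm."""
        half = 3.0 * self.fwhm
        return np.linspace(self.center - half, self.center + half, self.n_pixels)

    def envelope(self, wavelength_nm) -> np.ndarray:
        lam = np.asarray(wavelength_nm, dtype=float)
        return np.exp(-4.0 * np.log(2.0) * ((lam - self.center) / self.fwhm) ** 2)

    def falloff_profile(self, n_depth: int) -> np.ndarray:
        """Sensitivity vs depth pixel: Gaussian decay to 0.5 at
        ``falloff_half_frac`` of the imaging depth."""
        z = np.arange(n_depth) / max(n_depth - 1, 1)
        return np.exp(-np.log(2.0) * (z / self.falloff_half_frac) ** 2)


@dataclass
class OCTVolume:
    """3-D linear-intensity image indexed (y, x, z) with pixel-pitch metadata."""

    intensity: np.ndarray
    z_pitch: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity)
        if self.intensity.ndim != 3:
            raise ValueError("intensity must be a (y, x, z) array")
        if self.intensity.size and float(self.intensity.min()) < 0:
            raise ValueError("intensity must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensity.shape


def psf_sigma_px(z_pitch: float) -> float:
    """Axial PSF Gaussian sigma in depth pixels (tissue)."""
    return PSF_FWHM_AIR_UM / TISSUE_INDEX * _FWHM2SIGMA / z_pitch


def _expected_bscan(
    phantom: RetinaPhantom,
    params: ScanParams,
    iy: int,
    wavelength: float,
    blur: bool = True,
) -> np.ndarray:
    """Noise-free (n_x, n_z) expectation for B-scan row ``iy``."""
    if phantom.map_shape != (params.n_y, params.n_x):
        raise PhantomError(
            f"phantom map_shape {phantom.map_shape} must match scan lateral grid "
            f"({params.n_y}, {params.n_x})"
        )
    od_map = phantom.rhodopsin_od_map(wavelength)  # also checks state applied
    disc_row = phantom.disc_mask()[iy]
    off = phantom.top_offset_um + phantom.curvature_offset_um()[iy]  # (n_x,)
    zc = (np.arange(params.n_z) + 0.5) * params.z_pitch  # (n_z,)

    R = np.zeros((params.n_x, params.n_z), dtype=np.float32)
    OD = np.zeros_like(R)
    z0 = 0.0
    for layer in phantom.layers:
        top = off[:, None] + z0
        bot = top + layer.thickness_um
        inside = (zc[None, :] >= top) & (zc[None, :] < bot)
        refl = np.full(params.n_x, layer.reflectivity, dtype=np.float32)
        if layer.name == "OS":
            refl[disc_row] = 0.0
        R += inside * refl[:, None]
        if layer.absorber != "none":
            frac = np.clip((zc[None, :] - top) / layer.thickness_um, 0.0, 1.0)
            if layer.absorber == "rhodopsin":
                OD += od_map[iy][:, None].astype(np.float32) * frac.astype(np.float32)
            elif layer.absorber == "melanin" and phantom.pigmented:
                OD += np.float32(phantom.melanin_od) * frac.astype(np.float32)
        z0 += layer.thickness_um

    I = R * np.power(10.0, -2.0 * OD, dtype=np.float32)
    if blur:
        I = gaussian_filter1d(I, sigma=psf_sigma_px(params.z_pitch), axis=1, mode="nearest")
    return I


def expected_volume(
    phantom: RetinaPhantom,
    params: ScanParams,
    wavelength: float | None = None,
    src: SourceSpectrum | None = None,
    blur: bool = True,
) -> OCTVolume:
    """Noise-free expectation volume at the probe wavelength.

    ``blur=False`` skips the axial PSF, exposing the raw Beer-Lambert
    profile (useful for closed-form checks).
    """
    lam = wavelength if wavelength is not None else (src.center if src else 520.0)
    out = np.empty((params.n_y, params.n_x, params.n_z), dtype=np.float32)
    for iy in range(params.n_y):
        out[iy] = _expected_bscan(phantom, params, iy, lam, blur=blur)
    return OCTVolume(
        out,
        params.z_pitch,
        meta={
            "phantom_hash": phantom.hash,
            "state": phantom.state_label,
            "seed": None,
            "kind": "expected",
            "wavelength_nm": lam,
        },
    )


def expected_aline(
    phantom: RetinaPhantom,
    spectrum_src: SourceSpectrum,
    x_deg: float,
    y_deg: float,
    params: ScanParams | None = None,
    blur: bool = True,
) -> np.ndarray:
    """Noise-free depth profile (length n_z) at one lateral position."""
    params = params or ScanParams()
    ix, iy = phantom.deg_to_index(x_deg, y_deg)
    return _expected_bscan(phantom, params, int(iy), spectrum_src.center, blur=blur)[int(ix)]


def _shift_rows(bscan: np.ndarray, shifts: np.ndarray) -> np.ndarray:
    """Shift each row of (n_x, n_z) axially by a (possibly subpixel) amount,
    linear interpolation, zero fill outside."""
    n_x, n_z = bscan.shape
    zi = np.arange(n_z)[None, :] - shifts[:, None]
    z0 = np.floor(zi).astype(np.int64)
    f = (zi - z0).astype(bscan.dtype)
    v0 = (z0 >= 0) & (z0 < n_z)
    v1 = (z0 + 1 >= 0) & (z0 + 1 < n_z)
    z0c = np.clip(z0, 0, n_z - 1)
    z1c = np.clip(z0 + 1, 0, n_z - 1)
    out = (1.0 - f) * np.take_along_axis(bscan, z0c, axis=1) * v0
    out += f * np.take_along_axis(bscan, z1c, axis=1) * v1
    return out


def simulate_volume(
    phantom: RetinaPhantom,
    params: ScanParams,
    src: SourceSpectrum | None = None,
    acquisition: int = 0,
) -> OCTVolume:
    """Simulate one speckled volume acquisition.

    ``acquisition`` indexes repeat scans of one session: the speckle
    (scatterer) realization is identical for every acquisition under the same
    seed, while jitter and the additive detection background are keyed by
    (seed, acquisition).  Two calls with identical arguments are bit-for-bit
    identical.
    """
    src = src or SourceSpectrum()
    rng_scatter = np.random.default_rng(np.random.SeedSequence([params.seed, 101]))
    rng_acq = np.random.default_rng(
        np.random.SeedSequence([params.seed, 202, int(acquisition)])
    )
    out = np.empty((params.n_y, params.n_x, params.n_z), dtype=np.float32)
    for iy in range(params.n_y):
        E = _expected_bscan(phantom, params, iy, src.center)
        g = rng_scatter.standard_normal((2, params.n_x, params.n_z), dtype=np.float32)
        speckle = 0.5 * (g[0] ** 2 + g[1] ** 2)  # exponential, mean 1
        bscan = E * speckle
        if params.jitter_sd > 0:
            shifts = rng_acq.normal(0.0, params.jitter_sd, size=params.n_x)
            bscan = _shift_rows(bscan, shifts)
        elif params.noise_floor > 0:
            # keep the acquisition stream layout independent of jitter_sd
            rng_acq.normal(0.0, 1.0, size=params.n_x)
        if params.noise_floor > 0:
            bscan = bscan + rng_acq.exponential(
                params.noise_floor, size=bscan.shape
            ).astype(np.float32)
        out[iy] = bscan
    return OCTVolume(
        out,
        params.z_pitch,
        meta={
            "phantom_hash": phantom.hash,
            "state": phantom.state_label,
            "seed": params.seed,
            "acquisition": int(acquisition),
            "kind": "speckle",
            "wavelength_nm": src.center,
        },
    )


# ---------------------------------------------------------------------------
# coherent spectral path (raw interference spectra)
# ---------------------------------------------------------------------------

def natural_z_pitch_um(src: SourceSpectrum) -> float:
    """Depth pixel pitch of the reconstruction implied by the k-grid, um."""
    lam = src.wavelength_grid() * 1e-3  # um
    k = 2.0 * np.pi / lam
    k_span = float(k.max() - k.min())
    n = src.n_pixels
    return np.pi / (k_span / (n - 1) * n)


def max_depth_um(src: SourceSpectrum) -> float:
    """Unambiguous single-sided imaging depth, um."""
    return natural_z_pitch_um(src) * (src.n_pixels // 2)


def spectra_from_reflectors(
    reflectors: Sequence[tuple[float, float]],
    src: SourceSpectrum,
    dc: float = 1.0,
    apply_falloff: bool = True,
) -> np.ndarray:
    """Interference spectrum of discrete reflectors [(z_um, R), ...].

    spectrum(lambda) = envelope * [dc + sum_j 2 sqrt(R_j) cos(2 k z_j)],
    sampled uniformly in wavelength as a real spectrometer records, with each
    fringe scaled by the spectrometer sensitivity at the reflector depth.
    """
    lam_nm = src.wavelength_grid()
    k = 2.0 * np.pi / (lam_nm * 1e-3)  # rad/um
    spec = np.full(src.n_pixels, float(dc))
    zp = natural_z_pitch_um(src)
    z_max = max_depth_um(src)
    fall = src.falloff_profile(src.n_pixels // 2)
    for z_um, refl in reflectors:
        if z_um > z_max:
            warnings.warn(
                f"reflector at {z_um:.1f} um beyond the {z_max:.1f} um imaging "
                "range; it will alias to a wrapped depth",
                stacklevel=2,
            )
        amp = 2.0 * np.sqrt(max(refl, 0.0))
        if apply_falloff:
            amp *= np.interp(z_um / zp, np.arange(fall.size), fall)
        spec = spec + amp * np.cos(2.0 * k * z_um)
    return src.envelope(lam_nm) * spec


def phantom_reflectors(
    phantom: RetinaPhantom, x_deg: float, y_deg: float, wavelength: float
) -> list[tuple[float, float]]:
    """Discrete boundary reflectors (depth um, effective intensity) of one
    A-line: each layer top reflects its layer reflectivity attenuated by the
    double-pass OD accumulated above it."""
    ix, iy = (int(v) for v in phantom.deg_to_index(x_deg, y_deg))
    od_map = phantom.rhodopsin_od_map(wavelength)
    disc = bool(phantom.disc_mask()[iy, ix])
    off = phantom.top_offset_um + float(phantom.curvature_offset_um()[iy, ix])
    out = []
    z0, od_above = 0.0, 0.0
    for layer in phantom.layers:
        refl = layer.reflectivity
        if layer.name == "OS" and disc:
            refl = 0.0
        if refl > 0:
            out.append((off + z0, refl * 10.0 ** (-2.0 * od_above)))
        if layer.absorber == "rhodopsin":
            od_above += 0.0 if disc else float(od_map[iy, ix])
        elif layer.absorber == "melanin" and phantom.pigmented:
            od_above += phantom.melanin_od
        z0 += layer.thickness_um
    return out


def synthesize_spectra(
    phantom: RetinaPhantom,
    params: ScanParams,
    src: SourceSpectrum,
) -> np.ndarray:
    """Per-A-line raw interference spectra, shape (n_y, n_x, n_pixels).

    Round-trips through :func:`rhodoct.reconstruct.reconstruct_aline` to
    recover the boundary-peak positions of :func:`expected_aline`.
    """
    xs = (np.arange(params.n_x) + 0.5) * phantom.field_extent_deg[0] / params.n_x
    ys = (np.arange(params.n_y) + 0.5) * phantom.field_extent_deg[1] / params.n_y
    out = np.empty((params.n_y, params.n_x, src.n_pixels), dtype=np.float32)
    for iy, y in enumerate(ys):
        for ix, x in enumerate(xs):
            refl = phantom_reflectors(phantom, x, y, src.center)
            out[iy, ix] = spectra_from_reflectors(refl, src)
    return out
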