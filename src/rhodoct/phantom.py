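"""Ground-truth layered retina phantom.

The phantom describes a rat retina as an ordered stack of optical layers
(vitreous side first), each with a thickness, a backscatter reflectivity and
an optional absorber.  Rhodopsin lives in the rod outer segments (OS layer)
and its decadic optical density at the probe wavelength depends on the
adaptation state of the eye: dark-adapted rhodopsin absorbs with a unit-peak
band centred at 500 nm, photobleached rhodopsin at 380 nm, so a 520 nm probe
sees strong absorption only in the dark-adapted state.  Melanin (RPE and
choroid of pigmented eyes) is modelled as wavelength-flat absorbance.

Everything downstream — the OCT forward model, segmentation and the
differential rhodopsin quantification — is generated from, and validated
against, this ground truth.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "LAYER_NAMES",
    "LayerSpec",
    "AbsorptionSpectrum",
    "AdaptationState",
    "RetinaPhantom",
    "build_phantom",
    "apply_adaptation",
    "rhodopsin_absorbance",
    "default_layer_table",
]

LAYER_NAMES = ("RNFL", "OPL", "ONL", "IS", "OS", "RPE", "choroid", "sclera")
ABSORBERS = ("none", "rhodopsin", "melanin")
_MELANIN_OK = ("RPE", "choroid")

#: probe wavelength domain accepted by the absorption model, nm
WAVELENGTH_RANGE = (350.0, 700.0)


class PhantomError(ValueError):
    """Raised for invalid phantom configuration."""


def _unit_gaussian(wavelength, center, fwhm):
    lam = np.asarray(wavelength, dtype=float)
    return np.exp(-4.0 * np.log(2.0) * ((lam - center) / fwhm) ** 2)


@dataclass(frozen=True)
class AbsorptionSpectrum:
    """Unit-peak rhodopsin absorption band, dark vs photobleached.

    The dark-adapted pigment peaks at 500 nm; after photobleaching the peak
    shifts to 380 nm, rendering the pigment nearly transparent at the 520 nm
    probe.  Both bands are Gaussian with a common FWHM (default 100 nm,
    approximating the width of the rhodopsin alpha band).
    """

    lambda_peak_dark: float = 500.0
    lambda_peak_bleached: float = 380.0
    band_fwhm: float = 100.0

    def __post_init__(self):
        if not self.lambda_peak_dark > self.lambda_peak_bleached:
            raise PhantomError("dark-state peak must lie red of the bleached peak")
        if self.band_fwhm <= 0:
            raise PhantomError("band_fwhm must be positive")

    def shape_dark(self, wavelength):
        """Unit-peak spectral shape of unbleached rhodopsin."""
        return _unit_gaussian(wavelength, self.lambda_peak_dark, self.band_fwhm)

    def shape_bleached(self, wavelength):
        """Unit-peak spectral shape of the photobleached product."""
        return _unit_gaussian(wavelength, self.lambda_peak_bleached, self.band_fwhm)


@dataclass(frozen=True)
class LayerSpec:
    """One optical layer of the retina stack."""

    name: str
    thickness_um: float
    reflectivity: float
    absorber: str = "none"

    def __post_init__(self):
        if self.name not in LAYER_NAMES:
            raise PhantomError(f"unknown layer name {self.name!r}")
        if not self.thickness_um > 0:
            raise PhantomError(f"layer {self.name!r}: thickness must be > 0")
        if self.reflectivity < 0:
            raise PhantomError(f"layer {self.name!r}: reflectivity must be >= 0")
        if self.absorber not in ABSORBERS:
            raise PhantomError(f"layer {self.name!r}: unknown absorber {self.absorber!r}")
        if self.absorber == "rhodopsin" and self.name != "OS":
            raise PhantomError(f"layer {self.name!r}: rhodopsin belongs in the OS layer")
        if self.absorber == "melanin" and self.name not in _MELANIN_OK:
            raise PhantomError(f"layer {self.name!r}: melanin allowed only in RPE/choroid")


@dataclass(frozen=True)
class AdaptationState:
    """Adaptation state of the eye before acquisition.

    ``dark``: fully dark-adapted (4 h), no pigment bleached.
    ``light``: bleached by bright room light (~800 lx, 15 s); treated as a
    full bleach of the field.
    ``pattern``: dark-adapted except for a pre-bleached vertical strip given
    as a lateral interval in degrees.
    """

    label: str
    pattern_strip: tuple[float, float] | None = None
    adapt_light_lux: float = 800.0
    adapt_seconds: float = 15.0

    def __post_init__(self):
        if self.label not in ("dark", "light", "pattern"):
            raise PhantomError(f"unknown adaptation label {self.label!r}")
        if (self.label == "pattern") != (self.pattern_strip is not None):
            raise PhantomError("pattern_strip is required iff label == 'pattern'")


def default_layer_table(pigmented: bool = False) -> tuple[LayerSpec, ...]:
    """Default rat retina layer stack (thicknesses in um, vitreous side first).

    Reflectivities put the hyper-reflective band at the IS/OS junction (bright
    OS on top of a dim IS) and give the sclera zero backscatter: in vivo data
    show no sclera contribution even though it sits in the imaging range.
    """
    mel = "melanin" if pigmented else "none"
    return (
        LayerSpec("RNFL", 15.0, 0.85),
        LayerSpec("OPL", 20.0, 0.50),
        LayerSpec("ONL", 75.0, 0.10),
        LayerSpec("IS", 20.0, 0.20),
        LayerSpec("OS", 30.0, 1.00, "rhodopsin"),
        LayerSpec("RPE", 15.0, 0.90, mel),
        LayerSpec("choroid", 50.0, 0.50, mel),
        LayerSpec("sclera", 100.0, 0.00),
    )


@dataclass(frozen=True)
class RetinaPhantom:
    """Validated ground-truth retina.

    Lateral coordinates are in degrees of visual angle (converted to um with
    ``um_per_degree``); lateral maps are sampled on a ``map_shape = (n_y,
    n_x)`` grid of pixel centres spanning ``field_extent_deg``.  Depth z is
    measured in um from the nominal retina top, increasing from vitreous
    toward sclera; per-A-line curvature shifts the whole stack axially.
    """

    layers: tuple[LayerSpec, ...]
    field_extent_deg: tuple[float, float] = (39.0, 39.0)
    map_shape: tuple[int, int] = (128, 512)
    curvature_um: float = 30.0
    pigmented: bool = False
    rhodopsin_od_peak: float = 0.25
    melanin_od: float = 1.0
    top_offset_um: float = 150.0
    um_per_degree: float = 55.0
    disc_center_deg: tuple[float, float] | None = None
    disc_radius_deg: float = 0.0
    spectrum: AbsorptionSpectrum = field(default_factory=AbsorptionSpectrum)
    bleach_fraction_map: np.ndarray | None = None
    state_label: str | None = None

    def __post_init__(self):
        if len(self.layers) == 0:
            raise PhantomError("phantom needs at least one layer")
        n_rho = sum(1 for l in self.layers if l.absorber == "rhodopsin")
        if n_rho != 1:
            raise PhantomError("exactly one OS layer must carry rhodopsin")
        if self.rhodopsin_od_peak < 0:
            raise PhantomError("rhodopsin_od_peak must be >= 0")
        if self.melanin_od < 0:
            raise PhantomError("melanin_od must be >= 0")
        if self.bleach_fraction_map is not None:
            b = np.asarray(self.bleach_fraction_map)
            if b.shape != tuple(self.map_shape):
                raise PhantomError("bleach_fraction_map shape must match map_shape")
            if b.min() < 0 or b.max() > 1:
                raise PhantomError("bleach fractions must lie in [0, 1]")

    # ---- lateral grids -------------------------------------------------

    @property
    def n_y(self) -> int:
        return self.map_shape[0]

    @property
    def n_x(self) -> int:
        return self.map_shape[1]

    def x_centers_deg(self) -> np.ndarray:
        fx = self.field_extent_deg[0]
        return (np.arange(self.n_x) + 0.5) * fx / self.n_x

    def y_centers_deg(self) -> np.ndarray:
        fy = self.field_extent_deg[1]
        return (np.arange(self.n_y) + 0.5) * fy / self.n_y

    def disc_mask(self) -> np.ndarray:
        """(n_y, n_x) boolean mask of the optic disc (no photoreceptors)."""
        if self.disc_center_deg is None or self.disc_radius_deg <= 0:
            return np.zeros(self.map_shape, dtype=bool)
        cx, cy = self.disc_center_deg
        xx = self.x_centers_deg()[None, :] - cx
        yy = self.y_centers_deg()[:, None] - cy
        return xx**2 + yy**2 <= self.disc_radius_deg**2

    def curvature_offset_um(self) -> np.ndarray:
        """Axial bowl offset of the whole stack, 0 at field centre and
        ``curvature_um`` at the field corners."""
        xn = 2.0 * self.x_centers_deg() / self.field_extent_deg[0] - 1.0
        yn = 2.0 * self.y_centers_deg() / self.field_extent_deg[1] - 1.0
        return self.curvature_um * 0.5 * (xn[None, :] ** 2 + yn[:, None] ** 2)

    # ---- depth geometry ------------------------------------------------

    def layer_interval_um(self, name: str) -> tuple[float, float]:
        """(top, bottom) of a layer in um relative to the retina top."""
        z = 0.0
        for l in self.layers:
            if l.name == name:
                return z, z + l.thickness_um
            z += l.thickness_um
        raise KeyError(name)

    @property
    def total_thickness_um(self) -> float:
        return float(sum(l.thickness_um for l in self.layers))

    def isos_depth_um(self) -> np.ndarray:
        """Ground-truth IS/OS junction depth (OS top), um, per (y, x)."""
        top, _ = self.layer_interval_um("OS")
        return self.top_offset_um + self.curvature_offset_um() + top

    # ---- adaptation / absorption --------------------------------------

    def require_state(self) -> np.ndarray:
        if self.state_label is None or self.bleach_fraction_map is None:
            raise PhantomError(
                "no adaptation state applied; call apply_adaptation() first"
            )
        return self.bleach_fraction_map

    def rhodopsin_od_map(self, wavelength: float) -> np.ndarray:
        """Single-pass decadic OD of the full OS layer per (y, x)."""
        b = self.require_state()
        lam = float(np.clip(wavelength, *WAVELENGTH_RANGE))
        sp = self.spectrum
        od = self.rhodopsin_od_peak * (
            (1.0 - b) * sp.shape_dark(lam) + b * sp.shape_bleached(lam)
        )
        od = np.where(self.disc_mask(), 0.0, od)
        return od

    def deg_to_index(self, x_deg, y_deg) -> tuple[np.ndarray, np.ndarray]:
        fx, fy = self.field_extent_deg
        ix = np.clip(np.floor(np.asarray(x_deg) / fx * self.n_x).astype(int), 0, self.n_x - 1)
        iy = np.clip(np.floor(np.asarray(y_deg) / fy * self.n_y).astype(int), 0, self.n_y - 1)
        return ix, iy

    # ---- provenance ----------------------------------------------------

    def config_dict(self) -> dict:
        d = {
            "layers": [
                {
                    "name": l.name,
                    "thickness_um": l.thickness_um,
                    "reflectivity": l.reflectivity,
                    "absorber": l.absorber,
                }
                for l in self.layers
            ],
            "field_extent_deg": list(self.field_extent_deg),
            "map_shape": list(self.map_shape),
            "curvature_um": self.curvature_um,
            "pigmented": self.pigmented,
            "rhodopsin_od_peak": self.rhodopsin_od_peak,
            "melanin_od": self.melanin_od,
            "top_offset_um": self.top_offset_um,
            "um_per_degree": self.um_per_degree,
            "disc_center_deg": list(self.disc_center_deg) if self.disc_center_deg else None,
            "disc_radius_deg": self.disc_radius_deg,
            "spectrum": {
                "lambda_peak_dark": self.spectrum.lambda_peak_dark,
                "lambda_peak_bleached": self.spectrum.lambda_peak_bleached,
                "band_fwhm": self.spectrum.band_fwhm,
            },
            "state_label": self.state_label,
        }
        if self.bleach_fraction_map is not None:
            d["bleach_map_sha1"] = hashlib.sha1(
                np.ascontiguousarray(self.bleach_fraction_map)
            ).hexdigest()
        return d

    @property
    def hash(self) -> str:
        text = yaml.safe_dump(self.config_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:12]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.config_dict(), sort_keys=False))


def build_phantom(config: dict | str | Path | None = None, **overrides) -> RetinaPhantom:
    """Build a validated :class:`RetinaPhantom` from a config mapping or file.

    ``config`` may be a dict or a path to a YAML file with the same structure
    as :meth:`RetinaPhantom.config_dict`; keyword overrides win.  Defaults
    reproduce the imaging geometry of the rat experiments (39 x 39 degree
    field, 512 x 128 lateral grid).
    """
    cfg: dict = {}
    if config is not None:
        if isinstance(config, (str, Path)):
            cfg = yaml.safe_load(Path(config).read_text()) or {}
        else:
            cfg = dict(config)
    cfg.update(overrides)
    cfg.pop("bleach_map_sha1", None)
    cfg.pop("state_label", None)

    pigmented = bool(cfg.pop("pigmented", False))
    layers_cfg = cfg.pop("layers", None)
    if layers_cfg is None:
        layers = default_layer_table(pigmented)
    else:
        if len(layers_cfg) == 0:
            raise PhantomError("layer table is empty")
        layers = tuple(
            l if isinstance(l, LayerSpec) else LayerSpec(**l) for l in layers_cfg
        )
    spec_cfg = cfg.pop("spectrum", None)
    spectrum = (
        spec_cfg
        if isinstance(spec_cfg, AbsorptionSpectrum)
        else AbsorptionSpectrum(**spec_cfg)
        if spec_cfg
        else AbsorptionSpectrum()
    )
    for key in ("field_extent_deg", "map_shape", "disc_center_deg"):
        if cfg.get(key) is not None:
            cfg[key] = tuple(cfg[key])
    return RetinaPhantom(layers=layers, pigmented=pigmented, spectrum=spectrum, **cfg)


def apply_adaptation(phantom: RetinaPhantom, state: AdaptationState) -> RetinaPhantom:
    """Return a copy of the phantom with the bleach-fraction map of ``state``.

    ``dark`` zeroes the map, ``light`` saturates it (the 15 s / ~800 lx
    exposure is treated as a full bleach), ``pattern`` bleaches a full-height
    vertical strip given as an x interval in degrees.
    """
    shape = phantom.map_shape
    if state.label == "dark":
        bmap = np.zeros(shape)
    elif state.label == "light":
        bmap = np.ones(shape)
    else:
        x0, x1 = state.pattern_strip  # type: ignore[misc]
        fx = phantom.field_extent_deg[0]
        if not (0.0 <= x0 < x1 <= fx):
            raise PhantomError(
                f"pattern_strip [{x0}, {x1}] deg outside the {fx} deg field"
            )
        xc = phantom.x_centers_deg()
        col = (xc >= x0) & (xc < x1)
        bmap = np.broadcast_to(col.astype(float), shape).copy()
    return replace(phantom, bleach_fraction_map=bmap, state_label=state.label)


def rhodopsin_absorbance(
    spectrum: AbsorptionSpectrum,
    phantom: RetinaPhantom,
    wavelength: float,
    x_deg,
    y_deg,
):
    """Single-pass decadic OD of the OS layer at a lateral position.

    OD = od_peak * [(1-b) S_dark(lambda) + b S_bleached(lambda)] with b the
    local bleach fraction; zero inside the optic disc.  The wavelength is
    clamped to the modelled 350-700 nm domain.
    """
    b_map = phantom.require_state()
    lam = float(np.clip(wavelength, *WAVELENGTH_RANGE))
    ix, iy = phantom.deg_to_index(x_deg, y_deg)
    b = np.asarray(b_map)[iy, ix]
    od = phantom.rhodopsin_od_peak * (
        (1.0 - b) * spectrum.shape_dark(lam) + b * spectrum.shape_bleached(lam)
    )
    disc = phantom.disc_mask()[iy, ix]
    return np.where(disc, 0.0, od) if np.ndim(od) else (0.0 if disc else float(od))
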