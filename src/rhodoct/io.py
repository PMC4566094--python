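"""Volume, table and image I/O with structured-text metadata sidecars.

Volumes are multi-page 32-bit float TIFFs (one page per B-scan, page rows =
A-lines, columns = depth) accompanied by a ``<file>.yaml`` sidecar carrying
pixel pitch and provenance; round-trips are lossless.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile
import yaml

from .simulate import OCTVolume

__all__ = ["read_volume", "write_volume", "render_png", "REQUIRED_SIDECAR_KEYS"]

REQUIRED_SIDECAR_KEYS = ("z_pitch_um", "n_y", "n_x", "n_z", "state", "seed", "phantom_hash")


def _sidecar_path(path: str | Path) -> Path:
    return Path(str(path) + ".yaml")


def write_volume(path: str | Path, volume: OCTVolume) -> None:
    """Write a volume as a multi-page float32 TIFF plus YAML sidecar."""
    path = Path(path)
    data = np.asarray(volume.intensity, dtype=np.float32)
    tifffile.imwrite(path, data, photometric="minisblack")
    meta = {
        "z_pitch_um": float(volume.z_pitch),
        "n_y": int(data.shape[0]),
        "n_x": int(data.shape[1]),
        "n_z": int(data.shape[2]),
        "state": volume.meta.get("state"),
        "seed": volume.meta.get("seed"),
        "phantom_hash": volume.meta.get("phantom_hash"),
    }
    extra = {k: v for k, v in volume.meta.items() if k not in meta}
    meta.update(extra)
    _sidecar_path(path).write_text(yaml.safe_dump(meta, sort_keys=False))


def read_volume(path: str | Path) -> OCTVolume:
    """Read a volume written by :func:`write_volume`.

    Raises if the sidecar is missing (listing the required keys) or if the
    TIFF page count disagrees with the sidecar.
    """
    path = Path(path)
    side = _sidecar_path(path)
    if not side.exists():
        raise FileNotFoundError(
            f"missing metadata sidecar {side}; required keys: "
            + ", ".join(REQUIRED_SIDECAR_KEYS)
        )
    meta = yaml.safe_load(side.read_text())
    missing = [k for k in REQUIRED_SIDECAR_KEYS if k not in meta]
    if missing:
        raise ValueError(f"sidecar {side} missing required keys: {', '.join(missing)}")
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    if data.shape != (meta["n_y"], meta["n_x"], meta["n_z"]):
        raise ValueError(
            f"TIFF shape {data.shape} does not match sidecar "
            f"({meta['n_y']}, {meta['n_x']}, {meta['n_z']})"
        )
    vol_meta = {k: v for k, v in meta.items() if k not in ("z_pitch_um", "n_y", "n_x", "n_z")}
    return OCTVolume(data, meta["z_pitch_um"], vol_meta)


def render_png(
    path: str | Path,
    image: np.ndarray,
    cmap: str = "gray",
    vmin: float | None = None,
    vmax: float | None = None,
) -> None:
    """Render a 2-D array to PNG (robust 1st/99th percentile scaling)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    img = np.asarray(image, dtype=float)
    if vmin is None:
        vmin = float(np.percentile(img, 1))
    if vmax is None:
        vmax = float(np.percentile(img, 99))
    if vmax <= vmin:
        vmax = vmin + 1e-12
    plt.imsave(path, img, cmap=cmap, vmin=vmin, vmax=vmax)
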