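"""Reading holograms from image files and writing reconstruction products.

Integer images (8/16-bit PNG or TIFF) are mapped to [0, 1] by dividing by
the type maximum — not the per-image maximum, so intensity scale stays
consistent across frames of a multi-distance series.  Float images are
taken as-is.  Complex fields are written as a float32 amplitude TIFF plus
a float32 phase TIFF (radians, wrapped to (-pi, pi]) with a YAML metadata
sidecar.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import tifffile
import yaml
from imageio.v3 import imread

from .fields import ComplexField, Hologram, InvalidParameterError

__all__ = ["read_hologram", "write_field", "read_field", "write_mask_png"]


def _load_grayscale(path: Path) -> np.ndarray:
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = imread(path)
    if arr.ndim == 3 and arr.shape[2] == 1:
        arr = arr[:, :, 0]
    if arr.ndim != 2:
        raise InvalidParameterError(
            f"{path}: multi-channel image; convert to single-channel grayscale first"
        )
    return arr


def read_hologram(path, pitch: float, wavelength: float, z: float) -> Hologram:
    """Load a hologram image and attach acquisition metadata.

    ``pitch``, ``wavelength`` and ``z`` are in metres.
    """
    for name, value in (("pitch", pitch), ("wavelength", wavelength)):
        if value is None or not (value > 0):
            raise InvalidParameterError(f"missing or invalid required metadata: {name}")
    path = Path(path)
    arr = _load_grayscale(path)
    bit_depth = None
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        bit_depth = info.bits
        intensity = arr.astype(np.float64) / info.max
    else:
        intensity = arr.astype(np.float64)
    return Hologram(
        intensity,
        pitch=pitch,
        wavelength=wavelength,
        z=z,
        bit_depth=bit_depth,
        meta={"source": str(path)},
    )


def _config_hash(meta: dict) -> str:
    return hashlib.sha256(
        json.dumps(meta, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_field(field: ComplexField, basename, extra_meta: dict | None = None):
    """Write amplitude/phase float32 TIFFs plus a YAML sidecar.

    Returns the three paths ``(amplitude, phase, sidecar)``.  Coordinates
    are row-major, origin top-left, 0-based.
    """
    base = Path(basename)
    base.parent.mkdir(parents=True, exist_ok=True)
    amp_path = base.with_name(base.name + "_amplitude.tif")
    phase_path = base.with_name(base.name + "_phase.tif")
    meta_path = base.with_name(base.name + "_meta.yaml")
    tifffile.imwrite(amp_path, field.amplitude.astype(np.float32))
    tifffile.imwrite(phase_path, field.phase.astype(np.float32))
    meta = {
        "pitch_m": field.pitch,
        "wavelength_m": field.wavelength,
        "shape": list(field.shape),
        "phase_units": "radians, wrapped to (-pi, pi]",
        "coordinates": "row-major, origin top-left, 0-based",
        **(extra_meta or {}),
    }
    meta["config_hash"] = _config_hash(meta)
    with open(meta_path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    return amp_path, phase_path, meta_path


def read_field(basename) -> ComplexField:
    """Inverse of :func:`write_field`."""
    base = Path(basename)
    amp = tifffile.imread(base.with_name(base.name + "_amplitude.tif"))
    phase = tifffile.imread(base.with_name(base.name + "_phase.tif"))
    with open(base.with_name(base.name + "_meta.yaml")) as fh:
        meta = yaml.safe_load(fh)
    return ComplexField(
        amp.astype(np.float64) * np.exp(1j * phase.astype(np.float64)),
        pitch=meta["pitch_m"],
        wavelength=meta["wavelength_m"],
    )


def write_mask_png(mask: np.ndarray, path) -> None:
    """Write a boolean mask as an 8-bit 0/255 PNG (evolution montages)."""
    from imageio.v3 import imwrite

    imwrite(Path(path), (np.asarray(mask, dtype=bool) * 255).astype(np.uint8))
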