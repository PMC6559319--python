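"""Image and config I/O.

Reflectance images are written as 16-bit multi-page-free TIFF (or PNG) with
a JSON sidecar recording channel order and the integer scaling; masks are
8-bit PNGs with 255 = included. Shipped presets (receptor sets, mapping
matrices, background palettes) live in ``camopipe/presets``.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import ConfigurationError, DataError
from .types import (
    BackgroundStyle,
    IMAGE_CHANNELS,
    ReceptorMapping,
    ReceptorSet,
    ReflectanceImage,
)

__all__ = [
    "write_reflectance_image",
    "read_reflectance_image",
    "write_mask",
    "read_mask",
    "load_receptor_set",
    "load_mapping",
    "load_background_style",
    "write_json",
]

# 16-bit quantization step: 40000 counts per unit reflectance leaves headroom
# for the permitted [0, 1.5] range within uint16.
_COUNTS_PER_UNIT = 40000


def write_reflectance_image(image: ReflectanceImage, path) -> None:
    path = Path(path)
    arr = np.round(image.pixels * _COUNTS_PER_UNIT).astype(np.uint16)
    iio.imwrite(path, np.moveaxis(arr, 0, -1))
    sidecar = {
        "channels": list(image.channels),
        "counts_per_unit": _COUNTS_PER_UNIT,
        "scale_px_per_mm": image.scale_px_per_mm,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_reflectance_image(path) -> ReflectanceImage:
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    raw = iio.imread(path)
    if raw.ndim == 2:
        raw = raw[..., None]
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        channels = tuple(sidecar["channels"])
        scale = raw.astype(float) / sidecar["counts_per_unit"]
        px_per_mm = sidecar.get("scale_px_per_mm")
    else:
        # No sidecar: assume full-range integer image, visible channels only.
        if np.issubdtype(raw.dtype, np.integer):
            scale = raw.astype(float) / np.iinfo(raw.dtype).max
        else:
            scale = raw.astype(float)
        channels = {1: ("lum",), 3: ("r", "g", "b"), 4: IMAGE_CHANNELS}.get(raw.shape[-1])
        if channels is None:
            raise DataError(f"cannot infer channels for {raw.shape[-1]}-plane image {path}")
        px_per_mm = None
    if len(channels) != scale.shape[-1]:
        raise DataError(f"sidecar lists {len(channels)} channels but image has {scale.shape[-1]}")
    return ReflectanceImage(
        channels=channels, pixels=np.moveaxis(scale, -1, 0), scale_px_per_mm=px_per_mm
    )


def write_mask(mask: np.ndarray, path) -> None:
    iio.imwrite(Path(path), (np.asarray(mask, dtype=bool) * np.uint8(255)))


def read_mask(path) -> np.ndarray:
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr >= 128


def _preset_text(filename: str) -> str:
    ref = resources.files("camopipe") / "presets" / filename
    if not ref.is_file():
        raise ConfigurationError(f"no shipped preset {filename!r}")
    return ref.read_text()


def load_receptor_set(name_or_path: str) -> ReceptorSet:
    """Load a receptor set by preset name (e.g. ``pollack_dichromat``) or JSON path."""
    p = Path(name_or_path)
    if p.suffix == ".json" and p.exists():
        return ReceptorSet.from_json(p)
    return ReceptorSet.from_dict(json.loads(_preset_text(f"{name_or_path}.json")))


def load_mapping(name_or_path: str) -> ReceptorMapping:
    """Load a camera-to-cone mapping by preset name (e.g. ``pollack_mapping``) or JSON path."""
    p = Path(name_or_path)
    if p.suffix == ".json" and p.exists():
        return ReceptorMapping.from_json(p)
    return ReceptorMapping.from_dict(json.loads(_preset_text(f"{name_or_path}.json")))


def load_background_style(name: str, styles_path=None) -> BackgroundStyle:
    """Load a background recipe by habitat name from the shipped palettes."""
    if styles_path is not None:
        data = json.loads(Path(styles_path).read_text())
    else:
        data = json.loads(_preset_text("background_styles.json"))
    if name not in data or name == "comment":
        known = sorted(k for k in data if k != "comment")
        raise ConfigurationError(f"unknown background style {name!r}; known styles: {known}")
    entry = data[name]
    palette = tuple(
        (np.array([g["reflectance"][c] for c in IMAGE_CHANNELS]), g["weight"])
        for g in entry["granule_palette"]
    )
    return BackgroundStyle(
        name=name,
        granule_palette=palette,
        granule_size_px=tuple(entry["granule_size_px"]),
        heterogeneity=float(entry["heterogeneity"]),
    )


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True, default=str))
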