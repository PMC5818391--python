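"""NIfTI image/mask I/O with a JSON sidecar for units and provenance."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import InvalidArgumentError
from .geometry import GridSpec, VOIMask
from .simulator import ImageVolume

__all__ = ["save_image", "load_image", "save_mask", "load_mask"]


def _affine(grid: GridSpec) -> np.ndarray:
    affine = np.eye(4)
    affine[:3, :3] = np.diag(grid.spacing)
    affine[:3, 3] = grid.origin
    return affine


def _grid_from(img: nib.Nifti1Image) -> GridSpec:
    affine = img.affine
    spacing = tuple(float(affine[i, i]) for i in range(3))
    if any(s <= 0 for s in spacing) or not np.allclose(affine[:3, :3], np.diag(spacing)):
        raise InvalidArgumentError("only axis-aligned, positive-spacing NIfTI is supported")
    return GridSpec(
        dims=tuple(int(n) for n in img.shape[:3]),
        spacing=spacing,
        origin=tuple(float(v) for v in affine[:3, 3]),
    )


def _sidecar(path: Path) -> Path:
    return path.with_suffix("").with_suffix(".json") if path.suffix == ".gz" else path.with_suffix(".json")


def save_image(image: ImageVolume, path: str | Path) -> Path:
    """Write a float NIfTI plus a .json sidecar (value_unit, provenance)."""
    path = Path(path)
    nib.save(nib.Nifti1Image(image.values.astype(np.float32), _affine(image.grid)), path)
    meta = {"value_unit": image.value_unit, "provenance": _jsonable(image.provenance)}
    _sidecar(path).write_text(json.dumps(meta, indent=2))
    return path


def load_image(path: str | Path) -> ImageVolume:
    path = Path(path)
    img = nib.load(path)
    meta = {}
    sidecar = _sidecar(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return ImageVolume(
        values=np.asarray(img.dataobj, dtype=float),
        grid=_grid_from(img),
        value_unit=meta.get("value_unit", "kBq/mL"),
        provenance=meta.get("provenance", {}),
    )


def save_mask(mask: VOIMask, path: str | Path) -> Path:
    """Write a uint8 NIfTI plus a sidecar with the segmentation provenance."""
    path = Path(path)
    nib.save(nib.Nifti1Image(mask.mask.astype(np.uint8), _affine(mask.grid)), path)
    meta = {
        "method": mask.method,
        "sphere_id": mask.sphere_id,
        "threshold": mask.threshold,
        "absolute_level": mask.absolute_level,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))
    return path


def load_mask(path: str | Path) -> VOIMask:
    path = Path(path)
    img = nib.load(path)
    meta = {}
    sidecar = _sidecar(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return VOIMask(
        mask=np.asarray(img.dataobj) > 0,
        grid=_grid_from(img),
        method=meta.get("method", "unknown"),
        sphere_id=meta.get("sphere_id", ""),
        threshold=meta.get("threshold"),
        absolute_level=meta.get("absolute_level"),
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
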