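"""NIfTI and configuration file surface.

One orientation convention is used internally: RAS axes, 0-based voxel
indices, voxel-centre coordinates.  Volumes are written with a diagonal
affine (spacing on the diagonal, origin in the translation column); on read,
images are reoriented to closest-canonical and must be axis-aligned.
Scalar volumes are stored as float32, masks as uint8 containing only {0, 1}.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .grid import GeometryError, StructureMask, VolumeGrid

__all__ = ["read_volume", "write_volume", "read_mask", "write_mask",
           "load_config_file", "dump_config_file"]

_AFFINE_ATOL = 1e-6


def _affine(grid: VolumeGrid | StructureMask) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = grid.spacing
    aff[:3, 3] = grid.origin
    return aff


def _geometry_from(img: nib.Nifti1Image) -> tuple[np.ndarray, tuple, tuple]:
    img = nib.as_closest_canonical(img)
    aff = img.affine
    rot = aff[:3, :3]
    if not np.allclose(rot - np.diag(np.diag(rot)), 0.0, atol=_AFFINE_ATOL):
        raise GeometryError(
            "oblique NIfTI affines are not supported; resample to an "
            "axis-aligned RAS grid first")
    spacing = tuple(float(d) for d in np.diag(rot))
    if any(s <= 0 for s in spacing):
        raise GeometryError(f"non-positive spacing in affine: {spacing}")
    origin = tuple(float(t) for t in aff[:3, 3])
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise GeometryError(f"expected a 3-D volume, got shape {data.shape}")
    return data, spacing, origin


def write_volume(grid: VolumeGrid, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(grid.data, dtype=np.float32), _affine(grid))
    img.header.set_xyzt_units("mm")
    nib.save(img, path)
    return path


def read_volume(path: str | Path) -> VolumeGrid:
    data, spacing, origin = _geometry_from(nib.load(str(path)))
    return VolumeGrid(np.asarray(data, dtype=np.float64), spacing, origin)


def write_mask(mask: StructureMask, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(mask.mask.astype(np.uint8), _affine(mask))
    img.header.set_xyzt_units("mm")
    nib.save(img, path)
    return path


def read_mask(path: str | Path, name: str | None = None) -> StructureMask:
    data, spacing, origin = _geometry_from(nib.load(str(path)))
    vals = np.unique(data)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError(
            f"mask file {path} is not binary: contains values {vals[:10]}")
    return StructureMask(name or Path(path).name.split(".")[0],
                         data.astype(bool), spacing, origin)


def load_config_file(path: str | Path) -> dict:
    """Load a YAML or JSON configuration mapping."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"configuration file {path} must contain a mapping")
    return data


def dump_config_file(config: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(config, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(config, sort_keys=True))
    return path
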