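"""Core spatial containers: scalar volumes and binary structure masks.

Everything downstream (CBF maps, dose grids, target-volume masks) lives on a
regular, axis-aligned 3-D grid described by a voxel spacing in millimetres and
the physical coordinate of voxel (0, 0, 0).  Axis convention is RAS-like:
axis 0 = left→right (x), axis 1 = posterior→anterior (y),
axis 2 = inferior→superior (z).  Coordinates refer to voxel centres.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

__all__ = ["GeometryError", "VolumeGrid", "StructureMask", "centered_origin"]

_GEOM_ATOL = 1e-6


class GeometryError(ValueError):
    """Raised when grids that must share a geometry do not."""


def centered_origin(shape: tuple[int, int, int],
                    spacing: tuple[float, float, float]) -> tuple[float, float, float]:
    """Origin that puts the physical (0,0,0) at the grid centre.

    With this origin the grid is symmetric about its central planes, which is
    what the mid-sagittal mirroring of the reference region relies on.
    """
    return tuple(-(n - 1) / 2.0 * s for n, s in zip(shape, spacing))


@dataclass
class VolumeGrid:
    """A 3-D scalar field (ASL signal, CBF in ml/100 g/min, or dose in Gy)."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("spacing and origin must have 3 components")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_cc(self) -> float:
        """Volume of one voxel in cm^3 (spacing is in mm; 1 cc = 1000 mm^3)."""
        sx, sy, sz = self.spacing
        return sx * sy * sz / 1000.0

    def same_geometry(self, other: "VolumeGrid | StructureMask") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=_GEOM_ATOL)
            and np.allclose(self.origin, other.origin, atol=_GEOM_ATOL)
        )

    def require_same_geometry(self, *others: "VolumeGrid | StructureMask") -> None:
        for o in others:
            if not self.same_geometry(o):
                raise GeometryError(
                    f"geometry mismatch: {self.shape}/{self.spacing}/{self.origin} vs "
                    f"{o.shape}/{o.spacing}/{o.origin}"
                )

    def like(self, data: np.ndarray) -> "VolumeGrid":
        """A new grid with the same geometry and different values."""
        return VolumeGrid(np.asarray(data), self.spacing, self.origin)

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical voxel-centre coordinates (mm) along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def coordinate_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable (open) coordinate arrays for vectorised geometry."""
        x = self.axis_coords(0)[:, None, None]
        y = self.axis_coords(1)[None, :, None]
        z = self.axis_coords(2)[None, None, :]
        return x, y, z

    def copy(self) -> "VolumeGrid":
        return VolumeGrid(self.data.copy(), self.spacing, self.origin)


@dataclass
class StructureMask:
    """A named binary mask on a grid geometry (GTV, PTV-ASL, brain stem, ...)."""

    name: str
    mask: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    warning: str | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.mask)
        if arr.ndim != 3:
            raise ValueError(f"mask must be 3-D, got ndim={arr.ndim}")
        if arr.dtype != bool:
            vals = np.unique(arr)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError(
                    f"mask '{self.name}' is not binary: values {vals[:10]}"
                )
            arr = arr.astype(bool)
        self.mask = arr
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing}")

    @classmethod
    def from_grid(cls, name: str, mask: np.ndarray, grid: VolumeGrid,
                  warning: str | None = None) -> "StructureMask":
        if np.asarray(mask).shape != grid.shape:
            raise GeometryError("mask shape does not match grid")
        return cls(name, np.asarray(mask), grid.spacing, grid.origin, warning)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape  # type: ignore[return-value]

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def is_empty(self) -> bool:
        return not bool(self.mask.any())

    @property
    def voxel_volume_cc(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz / 1000.0

    @property
    def volume_cc(self) -> float:
        """Structure volume in cc (voxel count x voxel volume)."""
        return self.voxel_count * self.voxel_volume_cc

    def same_geometry(self, other: "VolumeGrid | StructureMask") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=_GEOM_ATOL)
            and np.allclose(self.origin, other.origin, atol=_GEOM_ATOL)
        )

    def require_same_geometry(self, *others: "VolumeGrid | StructureMask") -> None:
        for o in others:
            if not self.same_geometry(o):
                raise GeometryError(
                    f"geometry mismatch between '{self.name}' and {getattr(o, 'name', 'grid')}"
                )

    def with_mask(self, mask: np.ndarray, name: str | None = None,
                  warning: str | None = None) -> "StructureMask":
        return StructureMask(name or self.name, mask, self.spacing, self.origin, warning)

    def as_grid(self) -> VolumeGrid:
        return VolumeGrid(self.mask.astype(np.uint8), self.spacing, self.origin)
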