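"""Voxelized image container shared by all stages.

Coordinate convention (used everywhere in :mod:`petac`): voxel indices are
0-based, arrays are indexed ``[x, y, z]``, space is measured in mm, and the
centre of voxel ``(i, j, k)`` sits at ``origin_mm + (index + 0.5) * spacing_mm``.
Linear attenuation coefficients are stored in cm^-1; the single mm->cm
conversion happens inside the projector when the attenuation exponent is
formed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Recognised image roles.
ROLES = ("activity", "hu", "mu", "mask")


@dataclass
class VoxelImage:
    """A 3D scalar grid with physical spacing and origin.

    Parameters
    ----------
    values : ndarray
        Voxel values, shape ``(nx, ny, nz)``.  2D inputs are promoted to a
        single-slice volume.
    spacing_mm : tuple of float
        Voxel size along x, y, z (mm); strictly positive.
    origin_mm : tuple of float
        World position of the corner of voxel (0, 0, 0) (mm).
    role : str
        One of ``activity`` (counts/s per voxel or MBq/cc), ``hu`` (CT
        numbers), ``mu`` (cm^-1, nonnegative), ``mask`` (0/1).
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    role: str = "activity"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim == 2:
            self.values = self.values[:, :, None]
        if self.values.ndim != 3:
            raise ValueError(f"expected a 2D or 3D array, got ndim={self.values.ndim}")
        if np.isscalar(self.spacing_mm):
            self.spacing_mm = (float(self.spacing_mm),) * 3
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if len(self.spacing_mm) != 3 or len(self.origin_mm) != 3:
            raise ValueError("spacing_mm and origin_mm must have 3 components")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing_mm}")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")
        if self.role == "mu" and np.any(self.values < 0):
            raise ValueError("mu images must be nonnegative")
        if self.role == "mask":
            uniq = np.unique(self.values)
            if not np.all(np.isin(uniq, (0.0, 1.0))):
                raise ValueError("mask images must contain only 0 and 1")

    # -- geometry helpers ---------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_slices(self) -> int:
        return self.values.shape[2]

    def centers_mm(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centres along ``axis``."""
        n = self.values.shape[axis]
        return self.origin_mm[axis] + (np.arange(n) + 0.5) * self.spacing_mm[axis]

    @property
    def center_mm(self) -> tuple[float, float, float]:
        """World coordinate of the grid centre."""
        return tuple(
            self.origin_mm[a] + 0.5 * self.values.shape[a] * self.spacing_mm[a]
            for a in range(3)
        )

    def index_to_world(self, index: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) voxel indices to world mm (voxel centres)."""
        index = np.asarray(index, dtype=float)
        return np.asarray(self.origin_mm) + (index + 0.5) * np.asarray(self.spacing_mm)

    def world_to_index(self, world: np.ndarray) -> np.ndarray:
        world = np.asarray(world, dtype=float)
        return (world - np.asarray(self.origin_mm)) / np.asarray(self.spacing_mm) - 0.5

    # -- construction helpers ----------------------------------------------

    @classmethod
    def zeros_like(cls, other: "VoxelImage", role: str | None = None) -> "VoxelImage":
        return cls(
            np.zeros(other.shape),
            other.spacing_mm,
            other.origin_mm,
            role or other.role,
        )

    def with_values(self, values: np.ndarray, role: str | None = None) -> "VoxelImage":
        return VoxelImage(values, self.spacing_mm, self.origin_mm, role or self.role)

    def copy(self) -> "VoxelImage":
        return replace(self, values=self.values.copy())


def centered_grid(
    shape: tuple[int, int, int],
    spacing_mm: tuple[float, float, float] | float,
    role: str = "activity",
) -> VoxelImage:
    """An all-zero volume whose world centre is the origin (isocenter)."""
    if np.isscalar(spacing_mm):
        spacing_mm = (float(spacing_mm),) * 3
    origin = tuple(-0.5 * n * s for n, s in zip(shape, spacing_mm))
    return VoxelImage(np.zeros(shape), spacing_mm, origin, role)
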