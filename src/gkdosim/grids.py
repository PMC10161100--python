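"""Axis-aligned voxel grids in stereotactic (Leksell) millimetre coordinates.

All 3D data in the package lives on a :class:`VoxelGrid`: a regular,
axis-aligned scalar grid whose voxel values are point samples at voxel
centers.  Coordinates are continuous Leksell mm; the machine focus (unit
center point, UCP) is at (100, 100, 100) mm.  Arrays are indexed
``data[ix, iy, iz]`` so that the x index varies fastest in memory order of
a Fortran-contiguous view; boxes and grid extents are half-open
``[low, high)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

UCP = np.array([100.0, 100.0, 100.0])


@dataclass
class VoxelGrid:
    """Regular scalar grid.

    Parameters
    ----------
    data:
        Array of shape ``(nx, ny, nz)`` (2D grids use ``(nx, ny)``).
    origin:
        Physical position (mm) of the center of voxel ``(0, 0, 0)``.
    spacing:
        Voxel pitch (mm) per axis, strictly positive.
    """

    data: np.ndarray
    origin: tuple[float, ...]
    spacing: tuple[float, ...]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.origin = tuple(float(v) for v in self.origin)
        self.spacing = tuple(float(v) for v in self.spacing)
        if self.data.ndim != len(self.origin) or self.data.ndim != len(self.spacing):
            raise ValueError("origin/spacing dimensionality must match data.ndim")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")

    # -- geometry -----------------------------------------------------------
    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def axis_centers(self, axis: int) -> np.ndarray:
        """Voxel-center coordinates along one axis (mm)."""
        n = self.data.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    @property
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Outer voxel-boundary box (low, high) in mm, half-open."""
        o = np.asarray(self.origin)
        sp = np.asarray(self.spacing)
        n = np.asarray(self.data.shape)
        return o - sp / 2.0, o + sp * (n - 0.5)

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Continuous (fractional) voxel indices for physical points (…, ndim)."""
        pts = np.asarray(points, dtype=float)
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        return np.asarray(idx, dtype=float) * np.asarray(self.spacing) + np.asarray(
            self.origin
        )

    def center_points(self) -> np.ndarray:
        """All voxel-center coordinates, shape ``(*shape, ndim)``."""
        axes = [self.axis_centers(a) for a in range(self.ndim)]
        mesh = np.meshgrid(*axes, indexing="ij")
        return np.stack(mesh, axis=-1)

    # -- sampling -----------------------------------------------------------
    def sample(self, points: np.ndarray, order: int = 1, mode: str = "nearest") -> np.ndarray:
        """Interpolate the grid at physical points (trilinear by default).

        ``mode='nearest'`` clamps to the edge value outside the grid.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        idx = self.world_to_index(pts)
        vals = ndimage.map_coordinates(
            self.data.astype(float), idx.T, order=order, mode=mode
        )
        return vals if np.asarray(points).ndim > 1 else vals[0]

    def contains(self, points: np.ndarray) -> np.ndarray:
        lo, hi = self.bounds
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return np.all((pts >= lo) & (pts < hi), axis=-1)

    def copy_with(self, data: np.ndarray) -> "VoxelGrid":
        return VoxelGrid(data=data, origin=self.origin, spacing=self.spacing)


@dataclass
class LabelGrid(VoxelGrid):
    """Material-label grid: integer codes plus a code → material-name map."""

    labels: dict[int, str] = field(default_factory=dict)

    def mask(self, name: str) -> np.ndarray:
        codes = [c for c, n in self.labels.items() if n == name]
        if not codes:
            raise KeyError(f"no label named {name!r}")
        return np.isin(self.data, codes)


def grid_from_bounds(
    low: np.ndarray, high: np.ndarray, spacing: tuple[float, ...], dtype=float
) -> VoxelGrid:
    """Empty grid whose voxel centers tile [low, high) at the given pitch."""
    low = np.asarray(low, dtype=float)
    high = np.asarray(high, dtype=float)
    sp = np.asarray(spacing, dtype=float)
    n = np.maximum(1, np.ceil((high - low) / sp).astype(int))
    origin = low + sp / 2.0
    return VoxelGrid(np.zeros(tuple(n), dtype=dtype), tuple(origin), tuple(sp))
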