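"""Regular 3D grids and trilinear sampling shared by the phantom and dose code.

All coordinates are millimetres in the phantom frame: right-handed, origin at
the isocenter, cylinder axis along z (the slice-stacking axis), beam-anterior
direction along -y at gantry 0.  Voxel values are stored as ``(nz, ny, nx)``
arrays (slice, row, column), matching the DICOM pixel layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .errors import ConfigurationError, OutOfBoundsError

__all__ = ["Grid3D", "DoseGrid", "trilinear"]


@dataclass(frozen=True)
class Grid3D:
    """A regular axis-aligned grid of voxel centers.

    ``origin`` is the center of voxel (ix=0, iy=0, iz=0); ``shape`` is
    ``(nx, ny, nz)``.
    """

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    shape: tuple[int, int, int]

    def __post_init__(self):
        if any(s <= 0 for s in self.spacing):
            raise ConfigurationError(f"grid spacing must be positive, got {self.spacing}")
        if any(int(n) <= 0 for n in self.shape):
            raise ConfigurationError(f"grid shape must be positive, got {self.shape}")

    @property
    def xs(self) -> np.ndarray:
        return self.origin[0] + self.spacing[0] * np.arange(self.shape[0])

    @property
    def ys(self) -> np.ndarray:
        return self.origin[1] + self.spacing[1] * np.arange(self.shape[1])

    @property
    def zs(self) -> np.ndarray:
        return self.origin[2] + self.spacing[2] * np.arange(self.shape[2])

    @property
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(lower, upper) corners of the voxel-center bounding box."""
        lo = np.asarray(self.origin, dtype=float)
        hi = lo + np.asarray(self.spacing) * (np.asarray(self.shape) - 1)
        return lo, hi

    def contains(self, points: np.ndarray, margin: float = 0.0) -> np.ndarray:
        """True where points lie inside the voxel-center bounding box."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        lo, hi = self.bounds
        return np.all((pts >= lo - margin) & (pts <= hi + margin), axis=1)

    def points(self) -> np.ndarray:
        """All voxel centers, shape ``(nz*ny*nx, 3)``, z-major ordering."""
        zz, yy, xx = np.meshgrid(self.zs, self.ys, self.xs, indexing="ij")
        return np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])

    def empty(self, dtype=np.float64) -> np.ndarray:
        nx, ny, nz = self.shape
        return np.zeros((nz, ny, nx), dtype=dtype)

    @staticmethod
    def centered(extent: tuple[float, float, float], spacing: tuple[float, float, float]) -> "Grid3D":
        """Grid symmetric about the isocenter covering at least ``extent`` mm per axis."""
        shape = tuple(int(np.ceil(e / s)) + 1 for e, s in zip(extent, spacing))
        origin = tuple(-(n - 1) / 2 * s for n, s in zip(shape, spacing))
        return Grid3D(origin, tuple(spacing), shape)


@dataclass
class DoseGrid:
    """Absolute dose (Gy) on a regular grid in the phantom frame."""

    grid: Grid3D
    values: np.ndarray  # (nz, ny, nx), Gy
    frame: str = "phantom"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        nx, ny, nz = self.grid.shape
        if self.values.shape != (nz, ny, nx):
            raise ConfigurationError(
                f"dose array shape {self.values.shape} does not match grid {(nz, ny, nx)}"
            )
        if np.any(self.values < 0):
            raise ConfigurationError("dose values must be non-negative")

    @property
    def max_dose(self) -> float:
        return float(self.values.max())


def trilinear(
    grid: Grid3D,
    values: np.ndarray,
    points: np.ndarray,
    *,
    outside: str = "error",
    cval: float = 0.0,
) -> np.ndarray:
    """Trilinear interpolation of ``values`` (nz,ny,nx) at ``points`` (N,3) [x,y,z].

    ``outside='error'`` raises :class:`OutOfBoundsError` listing offending point
    indices; ``outside='constant'`` fades to ``cval`` beyond the voxel-center box
    (used by the ray tracer, where outside-the-grid is background).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if outside == "error":
        inside = grid.contains(pts, margin=1e-9)
        if not np.all(inside):
            bad = np.flatnonzero(~inside)
            raise OutOfBoundsError(
                f"{bad.size} sampling position(s) outside dose grid; indices {bad[:10].tolist()}"
            )
    ix = (pts[:, 0] - grid.origin[0]) / grid.spacing[0]
    iy = (pts[:, 1] - grid.origin[1]) / grid.spacing[1]
    iz = (pts[:, 2] - grid.origin[2]) / grid.spacing[2]
    return map_coordinates(
        np.asarray(values, dtype=float),
        [iz, iy, ix],
        order=1,
        mode="grid-constant",
        cval=cval,
    )
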