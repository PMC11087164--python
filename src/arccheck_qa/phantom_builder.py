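"""Pseudo-CT construction, ring/platform contouring and RED voxelization.

The virtual phantom is a stack of blank CT slices (pixel value 0) carrying a
structure set of five concentric rings plus optional QA-platform objects; dose
calculation densities come entirely from the structure -> RED override table,
exactly as a TPS bulk-density override would apply them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely

from .errors import ConfigurationError
from .geometry import (
    PlatformObject,
    RingStructure,
    default_rings,
    validate_ring_order,
)
from .grids import Grid3D

__all__ = [
    "PseudoCTSpec",
    "PseudoCT",
    "REDTable",
    "REDVolume",
    "Structure",
    "StructureSet",
    "build_pseudo_ct",
    "build_structures",
    "voxelize_red",
    "uniform_red_volume",
    "default_red_table",
]


@dataclass(frozen=True)
class PseudoCTSpec:
    """Geometry of the blank CT series used as the phantom's DICOM backbone.

    The in-plane corner must equal -(matrix-1)/2 * pixel_spacing so the
    isocenter coincides with the geometric center of the volume; slices are
    centered on z = 0 (for the default 121 slices of 2 mm: -120..+120 mm).
    """

    n_slices: int = 121
    matrix: int = 512
    pixel_spacing: float = 0.97658
    slice_thickness: float = 2.0
    corner_xy: float | None = None  # defaults to -(matrix-1)/2 * pixel_spacing
    fill_value: int = 0

    def __post_init__(self):
        if self.matrix <= 0 or self.n_slices <= 0:
            raise ConfigurationError("matrix and n_slices must be positive")
        if self.pixel_spacing <= 0 or self.slice_thickness <= 0:
            raise ConfigurationError("pixel spacing and slice thickness must be positive")
        centered = -(self.matrix - 1) / 2 * self.pixel_spacing
        if self.corner_xy is None:
            object.__setattr__(self, "corner_xy", centered)
        elif abs(self.corner_xy - centered) > 5e-6:
            raise ConfigurationError(
                f"corner {self.corner_xy} does not center the {self.matrix}-pixel "
                f"matrix on the axis (expected {centered})"
            )

    @property
    def z_first(self) -> float:
        return -(self.n_slices - 1) / 2 * self.slice_thickness

    def grid(self) -> Grid3D:
        return Grid3D(
            origin=(self.corner_xy, self.corner_xy, self.z_first),
            spacing=(self.pixel_spacing, self.pixel_spacing, self.slice_thickness),
            shape=(self.matrix, self.matrix, self.n_slices),
        )


@dataclass
class PseudoCT:
    spec: PseudoCTSpec
    grid: Grid3D
    values: np.ndarray  # (nz, ny, nx) stored CT numbers

    @property
    def slice_positions(self) -> np.ndarray:
        return self.grid.zs


def build_pseudo_ct(spec: PseudoCTSpec | None = None) -> PseudoCT:
    """All-zero CT volume with per-slice positions spanning z = -/+ (n-1)/2 * thickness."""
    spec = spec or PseudoCTSpec()
    grid = spec.grid()
    values = np.full((spec.n_slices, spec.matrix, spec.matrix), spec.fill_value, dtype=np.int16)
    return PseudoCT(spec, grid, values)


@dataclass
class Structure:
    """A named structure: one closed planar contour per slice it spans.

    ``radius`` is set for circular (ring) structures so voxelization can use
    the exact disk instead of the sampled contour polygon.
    """

    name: str
    contours: list[tuple[float, np.ndarray]]  # (z_mm, (M, 2) vertices)
    kind: str = "ring"  # 'ring' | 'platform'
    radius: float | None = None


class StructureSet:
    def __init__(self, structures: list[Structure]):
        self.structures = structures

    def __len__(self) -> int:
        return len(self.structures)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.structures]

    def get(self, name: str) -> Structure:
        for s in self.structures:
            if s.name == name:
                return s
        raise KeyError(name)


def _circle(radius: float, n_vertices: int = 360) -> np.ndarray:
    ang = np.deg2rad(np.arange(n_vertices))
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang)])


def build_structures(
    rings: list[RingStructure] | None = None,
    platform: list[PlatformObject] = (),
    grid: Grid3D | None = None,
    contour_step_deg: float = 1.0,
) -> StructureSet:
    """Delineate ring and platform contours on the slice stack of ``grid``.

    Rings span every phantom slice; each becomes one closed circular contour
    per slice sampled at ``contour_step_deg`` (360 vertices by default).
    Platform polygons attach to slices within their configured z range.
    """
    rings = default_rings() if rings is None else rings
    validate_ring_order(rings)
    grid = grid or PseudoCTSpec().grid()
    half_extent = min(
        abs(grid.origin[0]),
        abs(grid.origin[0] + grid.spacing[0] * (grid.shape[0] - 1)),
        abs(grid.origin[1]),
        abs(grid.origin[1] + grid.spacing[1] * (grid.shape[1] - 1)),
    )
    zs = grid.zs
    structures: list[Structure] = []
    n_vertices = int(round(360.0 / contour_step_deg))
    for ring in rings:
        if ring.outer_radius > half_extent:
            raise ConfigurationError(
                f"ring {ring.name} radius {ring.outer_radius} exceeds grid extent {half_extent:.1f}"
            )
        poly = _circle(ring.outer_radius, n_vertices)
        structures.append(
            Structure(
                ring.name,
                [(float(z), poly) for z in zs],
                kind="ring",
                radius=ring.outer_radius,
            )
        )
    for obj in platform:
        verts = np.asarray(obj.outline, dtype=float)
        if obj.slice_range is None:
            obj_zs = zs
        else:
            lo, hi = obj.slice_range
            obj_zs = zs[(zs >= lo - 1e-9) & (zs <= hi + 1e-9)]
        structures.append(
            Structure(obj.name, [(float(z), verts) for z in obj_zs], kind="platform")
        )
    return StructureSet(structures)


@dataclass(frozen=True)
class REDTable:
    """Ordered (structure name, RED) override table; later entries win.

    The default assignment is Outer 1.130, Complex 1.200, Detectors 1.000,
    Inner 1.130, Insert 1.130, platform objects 1.350; background 0.0.
    """

    entries: tuple[tuple[str, float], ...]
    background: float = 0.0

    def __post_init__(self):
        for name, red in self.entries:
            if red <= 0:
                raise ConfigurationError(f"RED for {name} must be positive, got {red}")

    def value(self, name: str) -> float:
        for n, red in reversed(self.entries):
            if n == name:
                return red
        raise KeyError(name)

    def with_override(self, name: str, red: float) -> "REDTable":
        entries = tuple(
            (n, red if n == name else r) for n, r in self.entries
        )
        if name not in [n for n, _ in self.entries]:
            raise KeyError(name)
        return REDTable(entries, self.background)


def default_red_table(
    rings: list[RingStructure] | None = None,
    platform: list[PlatformObject] = (),
) -> REDTable:
    rings = default_rings() if rings is None else rings
    entries = [(r.name, r.red) for r in rings]
    entries += [(o.name, o.red) for o in platform]
    return REDTable(tuple(entries))


@dataclass
class REDVolume:
    """Relative-electron-density per voxel on a regular grid."""

    grid: Grid3D
    values: np.ndarray  # (nz, ny, nx) float32
    background: float = 0.0

    def __post_init__(self):
        nx, ny, nz = self.grid.shape
        if self.values.shape != (nz, ny, nx):
            raise ConfigurationError(
                f"RED array shape {self.values.shape} does not match grid {(nz, ny, nx)}"
            )


def voxelize_red(
    structures: StructureSet,
    table: REDTable,
    grid: Grid3D | None = None,
) -> REDVolume:
    """Paint structure REDs onto the voxel grid, later table entries overriding.

    Containment is tested at voxel centers against the closed structure
    outline (boundary points belong to the inner, i.e. later-painted,
    structure).  Ring structures use their exact disk (r <= radius, which is
    also sign-symmetric in floating point); platform polygons use the shapely
    containment test.  Structures are assumed prismatic: the outline of their
    first contour applies on every slice they span, so each needs one 2D mask.
    """
    grid = grid or PseudoCTSpec().grid()
    names = set(structures.names)
    for name, _ in table.entries:
        if name not in names:
            raise ConfigurationError(f"RED table references unknown structure {name!r}")
    nx, ny, nz = grid.shape
    values = np.full((nz, ny, nx), table.background, dtype=np.float32)
    gx, gy = np.meshgrid(grid.xs, grid.ys, indexing="xy")  # (ny, nx)
    zs = grid.zs
    for name, red in table.entries:
        struct = structures.get(name)
        if not struct.contours:
            continue
        if struct.radius is not None:
            mask = (gx**2 + gy**2) <= struct.radius**2
        else:
            poly = shapely.Polygon(struct.contours[0][1])
            mask = shapely.intersects_xy(poly, gx.ravel(), gy.ravel()).reshape(ny, nx)
        struct_zs = np.asarray([z for z, _ in struct.contours])
        iz = np.flatnonzero(np.isin(np.round(zs, 6), np.round(struct_zs, 6)))
        for k in iz:
            values[k][mask] = red
    return REDVolume(grid, values, background=table.background)


def uniform_red_volume(
    grid: Grid3D | None = None,
    red: float = 1.130,
    radius: float = 133.0,
) -> REDVolume:
    """Uniform-mode phantom: a single RED throughout the full cylinder.

    Rasterized through the same contour path as the layered build so the two
    modes agree voxel-for-voxel wherever their assigned REDs agree.
    """
    grid = grid or PseudoCTSpec().grid()
    ring = RingStructure("Uniform", radius, red)
    structures = build_structures([ring], grid=grid)
    return voxelize_red(structures, REDTable((("Uniform", red),)), grid)
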