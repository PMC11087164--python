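"""Detector helix, ring structures, MultiPlug grid and gantry-angle series.

The ArcCHECK-MR carries 1386 SunPoint diodes on a cylinder of radius 104 mm,
wound as 21 helical turns of 66 diodes each (22 PCBs of 3 diodes per turn).
Two coordinate systems coexist:

* the 3D phantom frame (mm; origin at isocenter, cylinder axis = z, beam
  anterior direction = -y at gantry 0), in which the angular spacing between
  neighbouring diodes of a turn is exactly 360/66 degrees; and
* the vendor's unfolded *chart*: each diode gets a signed circumferential
  coordinate ``arc`` on the nominal 10 mm spacing convention (+/-5, +/-15, ...,
  +/-325 mm, measured from the anterior pole, positive toward machine left)
  and an ``axial`` coordinate equal to its turn's nominal plane (multiples of
  10 mm, central turn = 0).

The ~3.45 mm mismatch between the nominal 660 mm unfolded circumference and
the true 2*pi*104 mm one is absorbed at the posterior seam (arc +325 <-> -325),
which is where the vendor chart places it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely

from .errors import ConfigurationError

__all__ = [
    "DetectorArraySpec",
    "Detector",
    "DetectorArray",
    "RingStructure",
    "PlatformObject",
    "build_detector_array",
    "chart_coordinates",
    "multiplug_grid",
    "gantry_angle_series",
    "default_rings",
    "default_platform_objects",
    "RING_NAMES",
    "PLATFORM_NAMES",
]

RING_NAMES = ("Outer", "Complex", "Detectors", "Inner", "Insert")
PLATFORM_NAMES = ("LtOuter", "LtMiddle", "LtInner", "RtInner", "RtMiddle", "RtOuter")

#: machine geometry constants (mm)
SAD_MM = 1435.0
SSD_ISOCENTRIC_MM = 1302.0
INSERT_RADIUS_MM = 75.0


@dataclass(frozen=True)
class DetectorArraySpec:
    """Configuration of the helical diode array.

    ``arc_positive_toward_left`` fixes the handedness convention of the chart
    (positive arc toward machine left, i.e. +x); ``z_advance_with_arc`` flips
    the within-turn stacking direction.  Neither is printed by the vendor, so
    both are configuration rather than hard-coded.
    """

    n_total: int = 1386
    per_turn: int = 66
    n_turns: int = 21
    radius: float = 104.0
    nominal_arc_spacing: float = 10.0
    turn_pitch: float = 10.0
    pcb_count: int = 22
    arc_positive_toward_left: bool = True
    z_advance_with_arc: bool = False

    def __post_init__(self):
        if self.n_total != self.per_turn * self.n_turns:
            raise ConfigurationError(
                f"n_total={self.n_total} != per_turn*n_turns={self.per_turn * self.n_turns}"
            )
        if self.per_turn != 3 * self.pcb_count:
            raise ConfigurationError(
                f"per_turn={self.per_turn} != 3*pcb_count={3 * self.pcb_count}"
            )
        if self.radius <= 0:
            raise ConfigurationError("radius must be positive")

    @property
    def max_arc(self) -> float:
        """Largest |arc| chart coordinate (325 mm for the default array)."""
        return (self.per_turn / 2 - 0.5) * self.nominal_arc_spacing


@dataclass(frozen=True)
class Detector:
    index: int
    turn: int
    angle_deg: float  # signed, from the anterior pole, positive toward machine left
    position: tuple[float, float, float]  # mm, phantom frame
    chart: tuple[float, float]  # (arc, axial) mm


class DetectorArray:
    """The built diode array; array-valued accessors plus per-diode records."""

    def __init__(self, spec: DetectorArraySpec, positions, angles_deg, turns, chart):
        self.spec = spec
        self.positions = np.asarray(positions, dtype=float)  # (N, 3)
        self.angles_deg = np.asarray(angles_deg, dtype=float)  # (N,)
        self.turns = np.asarray(turns, dtype=int)  # (N,)
        self.chart = np.asarray(chart, dtype=float)  # (N, 2) = (arc, axial)

    def __len__(self) -> int:
        return self.positions.shape[0]

    @property
    def detectors(self) -> list[Detector]:
        return [
            Detector(
                index=i,
                turn=int(self.turns[i]),
                angle_deg=float(self.angles_deg[i]),
                position=tuple(self.positions[i]),
                chart=tuple(self.chart[i]),
            )
            for i in range(len(self))
        ]

    def chart_index(self, arc: float, axial: float) -> int:
        """Index of the diode at a chart coordinate (exact nominal lattice point)."""
        hit = np.flatnonzero(
            (np.abs(self.chart[:, 0] - arc) < 1e-6) & (np.abs(self.chart[:, 1] - axial) < 1e-6)
        )
        if hit.size != 1:
            raise KeyError(f"no unique detector at chart ({arc}, {axial})")
        return int(hit[0])


def build_detector_array(spec: DetectorArraySpec | None = None) -> DetectorArray:
    """Construct the helical diode array from its specification.

    Per turn, 66 diodes sit at exact 360/66-degree spacing, offset half a
    spacing from the anterior/posterior poles so no diode lies on either pole.
    Within a turn the axial position advances linearly by one turn pitch per
    revolution; 21 turns stack at 10 mm pitch to span 210 mm centered on the
    isocenter plane, the central turn's entrance-side diodes at axial ~0.
    """
    spec = spec or DetectorArraySpec()
    n, per = spec.n_total, spec.per_turn
    dang = 360.0 / per

    j = np.arange(per)  # within-turn index, ordered by descending arc
    arcs = spec.max_arc - spec.nominal_arc_spacing * j  # +325 ... -325
    if not spec.arc_positive_toward_left:
        arcs = -arcs
    m = (np.abs(arcs) - spec.nominal_arc_spacing / 2) / spec.nominal_arc_spacing
    angles = np.sign(arcs) * (m + 0.5) * dang  # signed degrees from anterior pole

    frac = (j + 0.5) / per - 0.5  # -0.5..+0.5 across one revolution
    if spec.z_advance_with_arc:
        frac = -frac
    z_in_turn = frac * spec.turn_pitch

    turn_ids = np.arange(spec.n_turns)
    turn_z = (turn_ids - (spec.n_turns - 1) / 2) * spec.turn_pitch

    all_angles = np.tile(angles, spec.n_turns)
    all_turns = np.repeat(turn_ids, per)
    zs = np.repeat(turn_z, per) + np.tile(z_in_turn, spec.n_turns)

    rad = np.deg2rad(all_angles)
    xs = spec.radius * np.sin(rad)  # positive arc/angle -> machine left (+x)
    ys = -spec.radius * np.cos(rad)  # anterior pole at y = -radius

    positions = np.column_stack([xs, ys, zs])
    chart = np.column_stack([np.tile(arcs, spec.n_turns), np.repeat(turn_z, per)])
    assert positions.shape[0] == n
    return DetectorArray(spec, positions, all_angles, all_turns, chart)


def chart_coordinates(array: DetectorArray) -> np.ndarray:
    """Per-detector (arc, axial) chart coordinates in mm, shape (N, 2).

    Diodes sit at arc = +/-5, +/-15, ..., +/-325 mm from the anterior pole
    (nominal 10 mm circumferential spacing) and at their turn's nominal axial
    plane; the central turn's entrance diodes map to (-5, 0) and (5, 0).
    """
    return array.chart.copy()


def multiplug_grid(spacing: float = 20.0, n: int = 5) -> np.ndarray:
    """Centers of the MultiPlug point-measurement plugs, shape (n*n, 2) mm.

    A symmetric n x n grid (default 5 x 5 at 20 mm spacing, 25 points) in the
    transverse (x, y) plane at z = 0, centered on the phantom axis; all plugs
    must fit inside the 75 mm Insert radius.
    """
    offs = (np.arange(n) - (n - 1) / 2) * spacing
    gx, gy = np.meshgrid(offs, offs, indexing="xy")
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    rmax = float(np.hypot(pts[:, 0], pts[:, 1]).max())
    if rmax >= INSERT_RADIUS_MM:
        raise ConfigurationError(
            f"plug grid extends to {rmax:.1f} mm, beyond the {INSERT_RADIUS_MM} mm insert"
        )
    return pts


def gantry_angle_series(
    step: float = 2.0,
    excluded: tuple[float, float] | None = (8.0, 18.0),
) -> np.ndarray:
    """Ordered gantry angles for an attenuation series.

    Starts at 180 deg, advances by ``step`` with wrap at 360, covering one full
    rotation; angles inside the closed ``excluded`` interval are removed (the
    linac's hardware-protection sector).  Angles are reported in [0, 360) with
    gantry 0 = beam from anterior.
    """
    if step <= 0 or abs(round(360.0 / step) - 360.0 / step) > 1e-9:
        raise ConfigurationError(f"step {step} does not divide 360")
    count = int(round(360.0 / step))
    angles = (180.0 + step * np.arange(count)) % 360.0
    if excluded is None:
        return angles
    lo, hi = excluded
    for edge in (lo, hi):
        if abs(edge / step - round(edge / step)) > 1e-9:
            warnings.warn(
                f"excluded interval edge {edge} is not aligned to the {step} deg step",
                stacklevel=2,
            )
    if lo <= hi:
        keep = ~((angles >= lo - 1e-9) & (angles <= hi + 1e-9))
    else:  # interval wrapping through 360
        keep = ~((angles >= lo - 1e-9) | (angles <= hi + 1e-9))
    return angles[keep]


@dataclass(frozen=True)
class RingStructure:
    """One concentric shell of the phantom: name, outer radius (mm) and RED."""

    name: str
    outer_radius: float
    red: float

    def __post_init__(self):
        if self.outer_radius <= 0:
            raise ConfigurationError(f"ring {self.name}: radius must be positive")
        if self.red <= 0:
            raise ConfigurationError(f"ring {self.name}: RED must be positive")


def default_rings() -> list[RingStructure]:
    """The five-ring decomposition with its published radii and REDs.

    Outer/Inner/Insert are the PMMA shells (RED 1.130), Complex is the PCB +
    low-density band (RED 1.200 after tuning), Detectors the diode band
    treated as water-equivalent (RED 1.000).
    """
    return [
        RingStructure("Outer", 133.0, 1.130),
        RingStructure("Complex", 110.0, 1.200),
        RingStructure("Detectors", 103.4, 1.000),
        RingStructure("Inner", 100.0, 1.130),
        RingStructure("Insert", 75.0, 1.130),
    ]


@dataclass(frozen=True)
class PlatformObject:
    """One contoured QA-platform object: closed polygon in the (x, y) plane.

    ``slice_range`` restricts the object to a z interval (mm); ``None`` spans
    every phantom slice.
    """

    name: str
    outline: tuple[tuple[float, float], ...]  # closed, non-self-intersecting
    red: float = 1.350
    slice_range: tuple[float, float] | None = None

    def __post_init__(self):
        poly = self.polygon()
        if not poly.is_valid or poly.area <= 0:
            raise ConfigurationError(f"platform object {self.name}: invalid polygon")
        if self.red <= 0:
            raise ConfigurationError(f"platform object {self.name}: RED must be positive")

    def polygon(self) -> shapely.Polygon:
        return shapely.Polygon(self.outline)


def _rect(cx: float, cy: float, w: float, h: float) -> tuple[tuple[float, float], ...]:
    return (
        (cx - w / 2, cy - h / 2),
        (cx + w / 2, cy - h / 2),
        (cx + w / 2, cy + h / 2),
        (cx - w / 2, cy + h / 2),
    )


def default_platform_objects(red: float = 1.350) -> list[PlatformObject]:
    """A synthetic six-object QA-platform fixture (three rectangles per side).

    The manufacturer's platform outlines are not public; this fixture is a
    synthetic stand-in with mirror-symmetric names, placed below the phantom
    (posterior, +y) and laterally offset so that beams at gantry angles around
    115-140 deg and 220-245 deg traverse them, reproducing the attenuation
    sectors seen with the real platform.  Replace via configuration for real
    hardware geometry.
    """
    cy, w, h = 175.0, 40.0, 50.0
    centers = {"Inner": 180.0, "Middle": 240.0, "Outer": 300.0}
    objs = []
    for side, sign in (("Lt", +1), ("Rt", -1)):
        for part, cx in centers.items():
            objs.append(PlatformObject(f"{side}{part}", _rect(sign * cx, cy, w, h), red=red))
    order = {n: i for i, n in enumerate(PLATFORM_NAMES)}
    objs.sort(key=lambda o: order[o.name])
    return objs


def validate_ring_order(rings: list[RingStructure]) -> None:
    """Radii must be strictly decreasing in the order Outer > ... > Insert."""
    radii = [r.outer_radius for r in rings]
    if not all(radii[i] > radii[i + 1] for i in range(len(radii) - 1)):
        raise ConfigurationError(f"ring radii not strictly decreasing: {radii}")
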