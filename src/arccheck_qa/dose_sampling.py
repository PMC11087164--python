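"""Sampling dose grids at diode/plug positions and unfolding to the 2D chart.

The vendor software "unfolds" the cylindrical diode array into a 2D chart of
(arc, axial) coordinates; dose comparison, calibration-dose extraction and the
exit/entrance ratio all operate on that chart.  Sampling is trilinear (dose
grids are ~2 mm while diode geometry is sub-millimetre), with an optional
sphere average over a fixed deterministic point set for plug measurements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .errors import ArcCheckError, OutOfBoundsError
from .geometry import DetectorArray
from .grids import DoseGrid, trilinear

__all__ = [
    "DetectorDoses",
    "UnfoldedDoseMap",
    "sample_point",
    "sample_detectors",
    "unfold",
    "refold",
    "normalize",
    "calibration_dose",
    "ENTRANCE_CHART",
    "EXIT_CHART",
    "PLUG_SAMPLING_RADIUS_MM",
]

#: chart coordinates of the entrance-side sampling diodes (gantry 0)
ENTRANCE_CHART = ((-5.0, 0.0), (5.0, 0.0))
#: chart coordinates of the four exit-side sampling diodes around the seam
EXIT_CHART = ((325.0, 10.0), (325.0, 0.0), (-325.0, 0.0), (-325.0, -10.0))
#: radius of the sphere average used for plug point doses (0.25 cm)
PLUG_SAMPLING_RADIUS_MM = 2.5

#: calibration beam the vendor workflow expects (field cm, gantry deg, MU)
CALIBRATION_BEAM = {"field": (10.0, 10.0), "gantry_angle": 0.0, "mu": 200.0}


@dataclass
class DetectorDoses:
    """Per-diode doses (Gy) plus beam metadata and a source tag."""

    values: np.ndarray
    meta: dict = field(default_factory=dict)
    source_tag: str = "calculated"  # 'calculated' | 'measured-like'

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ArcCheckError("detector doses must be non-negative")


@dataclass
class UnfoldedDoseMap:
    """One dose point per physical diode at its (arc, axial) chart position."""

    arc: np.ndarray
    axial: np.ndarray
    dose: np.ndarray

    def to_grid(self) -> tuple[tuple[np.ndarray, np.ndarray], np.ndarray]:
        """Regular-grid resampling: ((axial_axis, arc_axis), values[axial, arc])."""
        ax = np.unique(self.axial)
        ar = np.unique(self.arc)
        values = np.full((ax.size, ar.size), np.nan)
        i = np.searchsorted(ax, self.axial)
        j = np.searchsorted(ar, self.arc)
        values[i, j] = self.dose
        if np.isnan(values).any():
            raise ArcCheckError("unfolded map is not a complete (axial, arc) lattice")
        return (ax, ar), values

    def lookup(self, arc: float, axial: float) -> float:
        hit = np.flatnonzero(
            (np.abs(self.arc - arc) < 1e-6) & (np.abs(self.axial - axial) < 1e-6)
        )
        if hit.size != 1:
            raise KeyError(f"no unique chart point ({arc}, {axial})")
        return float(self.dose[hit[0]])


@lru_cache(maxsize=8)
def _ball_offsets(radius: float, n: int = 256) -> np.ndarray:
    """Deterministic quasi-uniform ball of ``n`` points, exactly centered.

    Half the points follow a Fibonacci-sphere spiral with cube-root radial
    shells; the other half are their negatives, so the set is antipodally
    symmetric and averages any linear field to its central value exactly.
    """
    half = n // 2
    k = np.arange(half)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    zs = 1.0 - 2.0 * (k + 0.5) / half
    rho = np.sqrt(np.clip(1.0 - zs**2, 0.0, 1.0))
    phi = golden * k
    dirs = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), zs])
    radii = radius * ((k + 0.5) / half) ** (1.0 / 3.0)
    pts = dirs * radii[:, None]
    return np.vstack([pts, -pts])


def sample_point(dose: DoseGrid, position, radius: float = 0.0) -> float:
    """Dose at a point (radius 0, trilinear) or sphere mean (radius > 0).

    The sphere mean averages trilinear samples over a fixed deterministic
    256-point quasi-uniform ball; the plug workflow uses
    :data:`PLUG_SAMPLING_RADIUS_MM`.
    """
    pos = np.asarray(position, dtype=float)
    if radius < 0:
        raise ArcCheckError("sampling radius must be non-negative")
    if radius == 0:
        return float(trilinear(dose.grid, dose.values, pos[None, :])[0])
    pts = pos[None, :] + _ball_offsets(float(radius))
    if not np.all(dose.grid.contains(pts)):
        raise OutOfBoundsError(
            f"sampling sphere (r={radius} mm) at {pos.tolist()} extends outside the dose grid"
        )
    return float(trilinear(dose.grid, dose.values, pts).mean())


def sample_detectors(dose: DoseGrid, array: DetectorArray, meta: dict | None = None) -> DetectorDoses:
    """Trilinear point sample at every diode position (errors list bad indices)."""
    values = trilinear(dose.grid, dose.values, array.positions)
    return DetectorDoses(values, meta=dict(meta or {}), source_tag="calculated")


def unfold(doses: DetectorDoses, array: DetectorArray) -> UnfoldedDoseMap:
    """Map per-diode doses to chart coordinates, ordered by (axial, arc)."""
    if len(doses.values) != len(array):
        raise ArcCheckError(
            f"{len(doses.values)} doses for {len(array)} detectors"
        )
    order = np.lexsort((array.chart[:, 0], array.chart[:, 1]))
    return UnfoldedDoseMap(
        arc=array.chart[order, 0].copy(),
        axial=array.chart[order, 1].copy(),
        dose=doses.values[order].copy(),
    )


def refold(dose_map: UnfoldedDoseMap, array: DetectorArray) -> np.ndarray:
    """Inverse of :func:`unfold`: per-detector doses in array order."""
    out = np.empty(len(array))
    for i in range(len(array)):
        out[i] = dose_map.lookup(array.chart[i, 0], array.chart[i, 1])
    return out


def _entrance_mean(doses: DetectorDoses, array: DetectorArray) -> float:
    idx = [array.chart_index(*c) for c in ENTRANCE_CHART]
    return float(doses.values[idx].mean())


def normalize(
    doses: DetectorDoses,
    mode: str,
    *,
    array: DetectorArray | None = None,
    grid: DoseGrid | None = None,
    reference: float | None = None,
) -> DetectorDoses:
    """Divide all doses by a mode-selected reference, recorded in metadata.

    ``entrance_mean``: mean of the two entrance-side chart diodes (needs
    ``array``).  ``center_point``: dose sampled on the phantom axis at the
    isocenter (needs ``grid``; or pass ``reference`` directly).
    ``reference_beam``: an externally supplied scalar (``reference``).
    """
    if mode == "entrance_mean":
        if array is None:
            raise ArcCheckError("entrance_mean normalization needs the detector array")
        ref = _entrance_mean(doses, array)
    elif mode == "center_point":
        if reference is not None:
            ref = float(reference)
        elif grid is not None:
            ref = sample_point(grid, (0.0, 0.0, 0.0))
        else:
            raise ArcCheckError("center_point normalization needs a dose grid or reference")
    elif mode == "reference_beam":
        if reference is None:
            raise ArcCheckError("reference_beam normalization needs a reference value")
        ref = float(reference)
    else:
        raise ArcCheckError(f"unknown normalization mode {mode!r}")
    if ref <= 0:
        raise ArcCheckError(f"normalization reference must be positive, got {ref}")
    meta = dict(doses.meta)
    meta["normalization"] = {"mode": mode, "reference": ref}
    return DetectorDoses(doses.values / ref, meta=meta, source_tag=doses.source_tag)


def calibration_dose(calculated: DetectorDoses, array: DetectorArray) -> float:
    """Calibration dose: mean of the two entrance-side central-turn diode doses.

    The vendor workflow calculates a 10 x 10 cm^2, gantry 0, 200 MU beam and
    enters this mean as the "Calibration Dose"; a mismatched beam only warns,
    since the arithmetic is the same.
    """
    meta = calculated.meta
    for key, expected in CALIBRATION_BEAM.items():
        got = meta.get(key)
        if got is not None and not np.allclose(got, expected):
            warnings.warn(
                f"calibration dose from a non-calibration beam ({key}={got}, "
                f"expected {expected})",
                stacklevel=2,
            )
    return _entrance_mean(calculated, array)
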