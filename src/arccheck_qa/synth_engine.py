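"""Deterministic ray-trace dose engine over RED volumes, plus RED tuning.

This engine is a transparent stand-in for the commercial Monte Carlo TPS: it
combines a divergent point source (inverse-square), exponential attenuation
along the radiological path (water-equivalent depth = integral of RED), a
linear build-up ramp, a rectangular divergent field aperture, and an optional
scalar lateral shift that crudely mimics the magnetic crossline shift.  It is
explicitly NOT a transport calculation; its constants are calibration-level
fixtures chosen so the default 5-layer phantom produces an exit/entrance dose
ratio in the experimentally observed range.

Dose model, for a point p with source s and beam axis u:

    D(p) = MU * output * (SAD / |p - s|)^2 * B(d_eff(p)) * F(p')

with d_eff the water-equivalent depth from the phantom surface, B a linear
ramp to ``buildup_depth`` followed by exp(-mu_water * (d - buildup_depth)),
F the divergent field aperture indicator and p' the point shifted by
``lateral_shift`` along the crossline direction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ArcCheckError, ConfigurationError, UnreachableTargetError
from .geometry import DetectorArray, SAD_MM
from .grids import DoseGrid, Grid3D, trilinear
from .phantom_builder import REDVolume

__all__ = [
    "BeamSpec",
    "EngineConfig",
    "TuneSpec",
    "TuneResult",
    "source_position",
    "radiological_depth",
    "compute_dose",
    "compute_dose_at_points",
    "detector_doses",
    "tune_red",
    "attenuation_series",
    "MAX_FIELD_CM",
    "DEFAULT_MU_WATER",
]

#: maximum field size (FX, FY) at the isocenter plane, cm
MAX_FIELD_CM = (57.4, 22.0)

#: linear attenuation per mm of water-equivalent depth.  Calibration constant:
#: chosen so the default 5-layer phantom yields an EEDR near the measured
#: 0.3207 for the 10 x 10 cm^2 calibration beam; not a claim about the real
#: 7 FFF beam spectrum.
DEFAULT_MU_WATER = 3.620e-3


@dataclass(frozen=True)
class BeamSpec:
    """A single static beam: gantry angle (deg), field (FX, FY) cm at the
    isocenter, monitor units, source-isocenter distance (mm) and output
    (Gy/MU at the isocenter for an unattenuated beam)."""

    gantry_angle: float = 0.0
    field: tuple[float, float] = (10.0, 10.0)
    mu: float = 200.0
    sad: float = SAD_MM
    output: float = 0.01

    def __post_init__(self):
        fx, fy = self.field
        if fx <= 0 or fy <= 0 or fx > MAX_FIELD_CM[0] or fy > MAX_FIELD_CM[1]:
            raise ConfigurationError(
                f"field {self.field} cm outside the deliverable range {MAX_FIELD_CM}"
            )
        if self.mu <= 0 or self.output <= 0:
            raise ConfigurationError("MU and output must be positive")
        if self.sad <= 200.0:
            raise ConfigurationError("SAD must exceed the phantom outer radius")


@dataclass(frozen=True)
class EngineConfig:
    """Engine knobs: attenuation coefficient (per mm water-equivalent),
    build-up ramp depth (mm), lateral crossline-shift mimic (mm, 0 = off),
    the ray-march step (mm; an upper bound, clamped to half the smallest voxel
    dimension of the traced volume) and the surface dose fraction where the
    build-up ramp starts (so a zero-density volume degenerates to pure
    inverse square)."""

    mu_water: float = DEFAULT_MU_WATER
    buildup_depth: float = 15.0
    lateral_shift: float = 0.0
    step: float = 0.5
    surface_fraction: float = 0.3

    def __post_init__(self):
        if self.mu_water < 0:
            raise ConfigurationError("mu_water must be non-negative")
        if self.step <= 0:
            raise ConfigurationError("ray-march step must be positive")
        if self.buildup_depth <= 0:
            raise ConfigurationError("buildup depth must be positive")
        if not 0 < self.surface_fraction <= 1:
            raise ConfigurationError("surface fraction must be in (0, 1]")


@dataclass(frozen=True)
class TuneSpec:
    """RED tuning problem: which layer to vary, RED bounds, the EEDR target
    and the EEDR tolerance at which to stop."""

    layer: str = "Complex"
    bounds: tuple[float, float] = (1.130, 1.250)
    target_eedr: float = 0.3207
    tol: float = 1e-4

    def __post_init__(self):
        lo, hi = self.bounds
        if not lo < hi:
            raise ConfigurationError(f"bounds must satisfy lo < hi, got {self.bounds}")
        if self.tol <= 0:
            raise ConfigurationError("tolerance must be positive")


@dataclass(frozen=True)
class TuneResult:
    red: float
    eedr: float
    n_evaluations: int


def source_position(beam: BeamSpec) -> np.ndarray:
    """Source location in the phantom frame; gantry 0 = source anterior (-y)."""
    g = np.deg2rad(beam.gantry_angle)
    return np.array([beam.sad * np.sin(g), -beam.sad * np.cos(g), 0.0])


def _march_step(config: EngineConfig, volume: REDVolume) -> float:
    return min(config.step, min(volume.grid.spacing) / 2.0)


def _clip_to_box(src: np.ndarray, pts: np.ndarray, lo: np.ndarray, hi: np.ndarray):
    """Per-ray [t0, t1] parameter interval inside the axis-aligned box (slab method)."""
    d = pts - src
    with np.errstate(divide="ignore", invalid="ignore"):
        t_lo = (lo - src) / d
        t_hi = (hi - src) / d
    t_near = np.minimum(t_lo, t_hi)
    t_far = np.maximum(t_lo, t_hi)
    # rays parallel to an axis: inside that slab -> unconstrained, outside -> empty
    par = d == 0
    inside = (src >= lo) & (src <= hi)
    t_near = np.where(par & inside, -np.inf, t_near)
    t_far = np.where(par & inside, np.inf, t_far)
    t_near = np.where(par & ~inside, np.inf, t_near)
    t_far = np.where(par & ~inside, -np.inf, t_far)
    t0 = np.clip(np.max(t_near, axis=-1), 0.0, 1.0)
    t1 = np.clip(np.min(t_far, axis=-1), 0.0, 1.0)
    return t0, np.maximum(t1, t0)


def _radiological_depths(
    volume: REDVolume, source: np.ndarray, points: np.ndarray, step: float
) -> np.ndarray:
    """Water-equivalent depth along source->point by fixed-step midpoint marching.

    Space outside the volume's grid is background (RED 0 by default), so the
    integral is evaluated only on the segment clipped to the grid bounding box
    (exact when the background RED is zero; for nonzero background the outside
    contribution is added analytically).
    """
    if step <= 0:
        raise ArcCheckError("ray-march step must be positive")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    src = np.asarray(source, dtype=float)
    lo, hi = volume.grid.bounds
    half = np.asarray(volume.grid.spacing) / 2.0
    t0, t1 = _clip_to_box(src, pts, lo - half, hi + half)
    seg = pts - src
    seg_len = np.linalg.norm(seg, axis=1)
    clip_len = (t1 - t0) * seg_len

    depths = np.zeros(pts.shape[0])
    todo = np.flatnonzero(clip_len > 1e-12)
    chunk = 4096
    for start in range(0, todo.size, chunk):
        sel = todo[start : start + chunk]
        n_steps = np.maximum(1, np.ceil(clip_len[sel] / step)).astype(int)
        n_max = int(n_steps.max())
        frac = (np.arange(n_max)[None, :] + 0.5) / n_steps[:, None]  # (n, n_max)
        valid = np.arange(n_max)[None, :] < n_steps[:, None]
        t = t0[sel][:, None] + frac * (t1 - t0)[sel][:, None]
        sample_pts = src[None, None, :] + t[:, :, None] * seg[sel][:, None, :]
        red = trilinear(
            volume.grid,
            volume.values,
            sample_pts.reshape(-1, 3),
            outside="constant",
            cval=volume.background,
        ).reshape(len(sel), n_max)
        h = (clip_len[sel] / n_steps)[:, None]
        depths[sel] = np.sum(np.where(valid, red, 0.0) * h, axis=1)
    if volume.background != 0.0:
        depths += volume.background * (seg_len - clip_len)
    return depths


def radiological_depth(
    volume: REDVolume, source_point, target_point, step: float = 0.5
) -> float:
    """Scalar water-equivalent path length (mm) from source to target."""
    return float(
        _radiological_depths(volume, np.asarray(source_point, float),
                             np.asarray(target_point, float)[None, :], step)[0]
    )


def _beam_frame(beam: BeamSpec):
    g = np.deg2rad(beam.gantry_angle)
    axis = np.array([-np.sin(g), np.cos(g), 0.0])  # source -> isocenter
    crossline = np.array([np.cos(g), np.sin(g), 0.0])
    inline = np.array([0.0, 0.0, 1.0])
    return axis, crossline, inline


def compute_dose_at_points(
    volume: REDVolume,
    beam: BeamSpec,
    config: EngineConfig,
    points: np.ndarray,
) -> np.ndarray:
    """Engine dose (Gy) at arbitrary phantom-frame points, vectorized."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    src = source_position(beam)
    axis, crossline, inline = _beam_frame(beam)
    step = _march_step(config, volume)

    rel = pts - src
    r = np.linalg.norm(rel, axis=1)
    inv_sq = (beam.sad / r) ** 2

    # field aperture, evaluated at the (optionally shifted) point projected
    # through the source onto the isocenter plane
    shifted = pts + config.lateral_shift * crossline
    rel_s = shifted - src
    t_axis = rel_s @ axis
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = beam.sad / t_axis
    u = (rel_s @ crossline) * scale
    v = (rel_s @ inline) * scale
    fx_mm, fy_mm = beam.field[0] * 10.0, beam.field[1] * 10.0
    in_field = (
        (t_axis > 0)
        & (np.abs(u) <= fx_mm / 2 + 1e-9)
        & (np.abs(v) <= fy_mm / 2 + 1e-9)
    )

    d_eff = _radiological_depths(volume, src, pts, step)
    db = config.buildup_depth
    f0 = config.surface_fraction
    buildup = np.where(
        d_eff < db,
        f0 + (1.0 - f0) * d_eff / db,
        np.exp(-config.mu_water * (d_eff - db)),
    )
    return beam.mu * beam.output * inv_sq * buildup * in_field


def compute_dose(
    volume: REDVolume,
    beam: BeamSpec,
    config: EngineConfig,
    grid: Grid3D,
) -> DoseGrid:
    """Engine dose on a regular grid (deterministic; no RNG anywhere)."""
    values = compute_dose_at_points(volume, beam, config, grid.points())
    nx, ny, nz = grid.shape
    return DoseGrid(
        grid,
        values.reshape(nz, ny, nx),
        meta={"gantry_angle": beam.gantry_angle, "field": beam.field, "mu": beam.mu},
    )


def detector_doses(
    volume: REDVolume,
    beam: BeamSpec,
    config: EngineConfig,
    array: DetectorArray,
):
    """Engine dose evaluated directly at every diode position."""
    from .dose_sampling import DetectorDoses

    values = compute_dose_at_points(volume, beam, config, array.positions)
    meta = {"gantry_angle": beam.gantry_angle, "field": beam.field, "mu": beam.mu}
    return DetectorDoses(values, meta=meta, source_tag="calculated")


def _eedr_of(volume: REDVolume, beam: BeamSpec, config: EngineConfig, array: DetectorArray) -> float:
    from .qa_metrics import compute_eedr

    return compute_eedr(detector_doses(volume, beam, config, array), array).eedr


def tune_red(
    phantom_factory,
    beam: BeamSpec,
    config: EngineConfig,
    spec: TuneSpec,
    array: DetectorArray,
) -> TuneResult:
    """Bisection on one layer's RED until the engine EEDR matches the target.

    ``phantom_factory(red)`` must rebuild the RED volume with the tuned layer
    set to ``red``.  The EEDR must be monotone in that RED over the bounds
    (verified at the endpoints); a target outside the attainable interval
    raises :class:`UnreachableTargetError` reporting that interval.  Stops
    when |EEDR - target| <= tol or the RED bracket is below 0.001, and
    returns the RED rounded to 0.001 together with the achieved EEDR.
    """
    lo, hi = spec.bounds
    n_eval = 0

    def eedr(red: float) -> float:
        nonlocal n_eval
        n_eval += 1
        return _eedr_of(phantom_factory(red), beam, config, array)

    e_lo, e_hi = eedr(lo), eedr(hi)
    if e_lo == e_hi:
        raise ArcCheckError("EEDR is flat over the RED bounds; nothing to tune")
    decreasing = e_lo > e_hi
    attainable = (min(e_lo, e_hi), max(e_lo, e_hi))
    if not attainable[0] - spec.tol <= spec.target_eedr <= attainable[1] + spec.tol:
        raise UnreachableTargetError(
            f"target EEDR {spec.target_eedr} outside attainable "
            f"[{attainable[0]:.4f}, {attainable[1]:.4f}]",
            attainable=attainable,
        )

    a, b = lo, hi
    e_a = e_lo
    best_red, best_e = (a, e_a) if abs(e_lo - spec.target_eedr) < abs(e_hi - spec.target_eedr) else (b, e_hi)
    while b - a > 1e-3:
        mid = (a + b) / 2.0
        e_mid = eedr(mid)
        if abs(e_mid - spec.target_eedr) < abs(best_e - spec.target_eedr):
            best_red, best_e = mid, e_mid
        if abs(e_mid - spec.target_eedr) <= spec.tol:
            break
        high_side = e_mid > spec.target_eedr
        if high_side == decreasing:
            # EEDR still above target on the low-RED side -> move lower bound up
            a, e_a = mid, e_mid
        else:
            b = mid
    return TuneResult(red=round(best_red, 3), eedr=best_e, n_evaluations=n_eval)


def attenuation_series(
    volume: REDVolume,
    angles: np.ndarray,
    config: EngineConfig,
    beam: BeamSpec | None = None,
    point=(0.0, 0.0, 0.0),
) -> np.ndarray:
    """Central-cavity point dose per gantry angle, normalized to gantry 0.

    The normalizing gantry-0 value is computed explicitly whether or not 0 is
    in the angle list (mirroring the experiment, where the reference output is
    its own measurement).
    """
    beam = beam or BeamSpec()
    pt = np.asarray(point, dtype=float)[None, :]

    def axis_dose(angle: float) -> float:
        b = replace(beam, gantry_angle=float(angle))
        return float(compute_dose_at_points(volume, b, config, pt)[0])

    ref = axis_dose(0.0)
    if ref <= 0:
        raise ArcCheckError("gantry-0 reference dose is zero; point outside the field?")
    return np.array([axis_dose(a) for a in np.asarray(angles, dtype=float)]) / ref
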