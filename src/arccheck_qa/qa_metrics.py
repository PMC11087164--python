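"""Exit/entrance dose ratio, MU rescaling, and DTA / gamma-index analysis.

Comparisons follow the vendor convention: the *reference* is the measured-like
point set at the diode chart positions and the *evaluated* distribution is the
calculated map, searched around each reference point.  The low-dose threshold
is applied to reference doses relative to the global normalization dose in
both local and global modes (configurable, since the vendor does not document
its exact semantics).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .errors import ArcCheckError
from .dose_sampling import ENTRANCE_CHART, EXIT_CHART, DetectorDoses, UnfoldedDoseMap
from .geometry import DetectorArray

__all__ = [
    "GammaCriteria",
    "EEDRResult",
    "GammaResult",
    "compute_eedr",
    "eedr_relative_difference",
    "rescale_mu",
    "gamma_analysis",
    "dta_analysis",
]


@dataclass(frozen=True)
class GammaCriteria:
    """Dose tolerance (%), distance-to-agreement (mm), low-dose threshold (%)
    and normalization mode for a DTA or gamma comparison."""

    dose_tol: float
    dta: float
    threshold: float = 10.0
    mode: str = "local"

    def __post_init__(self):
        if self.dose_tol <= 0 or self.dta <= 0 or self.threshold <= 0:
            raise ArcCheckError("gamma criteria must all be strictly positive")
        if self.mode not in ("local", "global"):
            raise ArcCheckError(f"mode must be 'local' or 'global', got {self.mode!r}")


@dataclass(frozen=True)
class EEDRResult:
    entrance_mean: float
    exit_mean: float

    @property
    def eedr(self) -> float:
        return self.exit_mean / self.entrance_mean


@dataclass
class GammaResult:
    """Per-point statistic (gamma value or DTA pass flag) and the pass rate
    over the points above threshold."""

    gamma: np.ndarray | None
    passed: np.ndarray
    pass_rate: float
    n_evaluated: int
    criteria: GammaCriteria
    kind: str  # 'gamma' | 'dta'


def compute_eedr(doses: DetectorDoses, array: DetectorArray) -> EEDRResult:
    """Exit/entrance dose ratio from the six sampling diodes of a gantry-0 beam.

    Entrance mean over chart points (-5, 0) and (5, 0); exit mean over
    (325, 10), (325, 0), (-325, 0) and (-325, -10); EEDR = exit / entrance.
    """
    try:
        ent_idx = [array.chart_index(*c) for c in ENTRANCE_CHART]
        exit_idx = [array.chart_index(*c) for c in EXIT_CHART]
    except KeyError as exc:
        raise ArcCheckError(f"sampling detector missing from array: {exc}") from exc
    ent = doses.values[ent_idx]
    ext = doses.values[exit_idx]
    if np.any(~np.isfinite(ent)) or np.any(~np.isfinite(ext)):
        raise ArcCheckError("sampling detector dose missing (non-finite)")
    if ent.mean() <= 0:
        raise ArcCheckError("entrance mean dose must be positive")
    return EEDRResult(float(ent.mean()), float(ext.mean()))


def eedr_relative_difference(calculated: float, measured: float) -> float:
    """Relative EEDR difference in percent: 100 * (calc - meas) / meas."""
    if measured == 0:
        raise ArcCheckError("measured EEDR must be nonzero")
    return 100.0 * (calculated - measured) / measured


def rescale_mu(measured_mean: float, calculated_mean: float, mu: float) -> float:
    """Rescale MU by the measured/calculated entrance-dose ratio."""
    if measured_mean <= 0 or calculated_mean <= 0 or mu <= 0:
        raise ArcCheckError("rescale_mu inputs must all be positive")
    return mu * measured_mean / calculated_mean


def _as_regular_map(evaluated):
    """Normalize the evaluated distribution to (axes tuple, values ndarray)."""
    if isinstance(evaluated, UnfoldedDoseMap):
        return evaluated.to_grid()
    axes, values = evaluated
    if isinstance(axes, np.ndarray) and np.asarray(values).ndim == 1:
        axes = (axes,)
    axes = tuple(np.asarray(a, dtype=float) for a in axes)
    values = np.asarray(values, dtype=float)
    if values.ndim != len(axes):
        raise ArcCheckError("evaluated map axes do not match value dimensions")
    return axes, values


def _search_offsets(dta: float, ndim: int, radius_factor: float) -> np.ndarray:
    """Deterministic search lattice: step dta/10 within radius_factor * dta."""
    step = dta / 10.0
    n = int(round(radius_factor * dta / step))
    one = step * np.arange(-n, n + 1)
    if ndim == 1:
        offs = one[:, None]
    else:
        grids = np.meshgrid(*([one] * ndim), indexing="ij")
        offs = np.column_stack([g.ravel() for g in grids])
    dist = np.linalg.norm(offs, axis=1)
    return offs[dist <= radius_factor * dta + 1e-12]


def _prepare(reference_points, reference_doses, evaluated, criteria, norm_dose):
    ref_pts = np.atleast_2d(np.asarray(reference_points, dtype=float))
    if ref_pts.shape[0] == 1 and np.asarray(reference_doses).size > 1:
        ref_pts = ref_pts.T
    ref_dose = np.asarray(reference_doses, dtype=float)
    axes, values = _as_regular_map(evaluated)
    if ref_pts.shape[1] != len(axes):
        raise ArcCheckError(
            f"reference points are {ref_pts.shape[1]}D but evaluated map is {len(axes)}D"
        )
    norm = float(norm_dose) if norm_dose is not None else float(ref_dose.max())
    if norm <= 0:
        raise ArcCheckError("normalization dose must be positive")
    above = ref_dose >= criteria.threshold / 100.0 * norm
    if not np.any(above):
        raise ArcCheckError("no reference points above the low-dose threshold")
    interp = RegularGridInterpolator(
        axes, values, method="linear", bounds_error=False, fill_value=np.nan
    )
    return ref_pts, ref_dose, above, norm, interp


def _dose_tolerances(criteria: GammaCriteria, ref_dose: np.ndarray, norm: float) -> np.ndarray:
    if criteria.mode == "global":
        return np.full(ref_dose.shape, criteria.dose_tol / 100.0 * norm)
    return criteria.dose_tol / 100.0 * ref_dose


#: gamma values are capped here (search radius is 3 x DTA, so larger values
#: cannot be distinguished and are reported as the cap)
GAMMA_CAP = 3.0


def gamma_analysis(
    reference_points,
    reference_doses,
    evaluated,
    criteria: GammaCriteria,
    *,
    norm_dose: float | None = None,
) -> GammaResult:
    """Gamma index of each reference point against an evaluated regular map.

    gamma_i = min over positions p within 3*DTA of the reference point of
    sqrt((|p - p_i| / DTA)^2 + ((E(p) - D_i) / dDtol_i)^2), with the evaluated
    map linearly interpolated on a lattice of step DTA/10.  ``dDtol`` is
    dose_tol% of the normalization dose (global) or of the point's own dose
    (local).  A point passes when gamma <= 1; the pass rate counts only points
    above the low-dose threshold.
    """
    ref_pts, ref_dose, above, norm, interp = _prepare(
        reference_points, reference_doses, evaluated, criteria, norm_dose
    )
    tol = _dose_tolerances(criteria, ref_dose, norm)
    offs = _search_offsets(criteria.dta, ref_pts.shape[1], radius_factor=3.0)
    dist2 = (np.linalg.norm(offs, axis=1) / criteria.dta) ** 2  # (K,)

    gamma = np.full(ref_dose.shape, np.nan)
    idx = np.flatnonzero(above)
    chunk = 512
    for start in range(0, idx.size, chunk):
        sel = idx[start : start + chunk]
        pos = ref_pts[sel][:, None, :] + offs[None, :, :]  # (n, K, D)
        ev = interp(pos.reshape(-1, ref_pts.shape[1])).reshape(len(sel), -1)
        dd = (ev - ref_dose[sel][:, None]) / tol[sel][:, None]
        g2 = dist2[None, :] + dd**2
        g2 = np.where(np.isnan(g2), np.inf, g2)
        gamma[sel] = np.sqrt(g2.min(axis=1))
    gamma = np.minimum(gamma, GAMMA_CAP)
    passed = gamma[above] <= 1.0 + 1e-12
    return GammaResult(
        gamma=gamma,
        passed=passed,
        pass_rate=100.0 * passed.mean(),
        n_evaluated=int(above.sum()),
        criteria=criteria,
        kind="gamma",
    )


def dta_analysis(
    reference_points,
    reference_doses,
    evaluated,
    criteria: GammaCriteria,
    *,
    norm_dose: float | None = None,
) -> GammaResult:
    """Distance-to-agreement pass/fail per reference point.

    A point passes if the dose difference at its own location is within the
    (mode-normalized) tolerance, OR the evaluated distribution attains the
    reference dose somewhere within DTA mm — detected as the interpolated
    values over the search disk bracketing the reference dose.
    """
    ref_pts, ref_dose, above, norm, interp = _prepare(
        reference_points, reference_doses, evaluated, criteria, norm_dose
    )
    tol = _dose_tolerances(criteria, ref_dose, norm)
    offs = _search_offsets(criteria.dta, ref_pts.shape[1], radius_factor=1.0)

    passed_full = np.zeros(ref_dose.shape, dtype=bool)
    idx = np.flatnonzero(above)
    chunk = 512
    for start in range(0, idx.size, chunk):
        sel = idx[start : start + chunk]
        own = interp(ref_pts[sel])
        dose_ok = np.abs(own - ref_dose[sel]) <= tol[sel] + 1e-12
        pos = ref_pts[sel][:, None, :] + offs[None, :, :]
        ev = interp(pos.reshape(-1, ref_pts.shape[1])).reshape(len(sel), -1)
        lo = np.nanmin(ev, axis=1)
        hi = np.nanmax(ev, axis=1)
        crossing = (lo <= ref_dose[sel] + 1e-12) & (hi >= ref_dose[sel] - 1e-12)
        passed_full[sel] = dose_ok | crossing
    passed = passed_full[above]
    return GammaResult(
        gamma=None,
        passed=passed,
        pass_rate=100.0 * passed.mean(),
        n_evaluated=int(above.sum()),
        criteria=criteria,
        kind="dta",
    )
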