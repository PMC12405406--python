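"""Gamma-index comparison of dose distributions.

For each reference point r the gamma index is

    gamma(r) = min over evaluated positions e of
               sqrt( (|e - r| / r_m)^2 + ((D_e - D_r) / D_m)^2 )

with r_m the distance-to-agreement criterion (mm) and D_m the dose
tolerance, expressed as a percentage of the global reference maximum
("global" normalization) or of the local reference dose ("local").
The clinical default is the 3%/3mm criterion; gamma < 1 counts as passing.

The evaluated distribution is linearly interpolated on a lattice of spatial
offsets with pitch ``interp_step_mm`` (default r_m/10) out to
``search_limit_factor * r_m``; the gamma value is the exact minimum over
that candidate lattice. :func:`compute_gamma` searches offsets sorted by
distance with an early exit once the spatial term alone exceeds the current
worst minimum; :func:`gamma_oracle` re-derives the same quantity by plain
exhaustive enumeration per reference point and exists for verification only.

Direction matters: gamma is evaluated from the reference toward the
evaluated distribution and is not symmetric.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator, interpn

from .dose_grid_io import DoseGrid, ScanTable
from .errors import EmptyEvaluationError, InputError, ResourceError

__all__ = [
    "GammaCriteria",
    "GammaMap",
    "GammaSummary",
    "compute_gamma",
    "gamma_oracle",
    "summarize_gamma",
]

_ORACLE_POINT_LIMIT = 10_000


@dataclass(frozen=True)
class GammaCriteria:
    """Parameters of the gamma comparison (defaults: global 3%/3mm)."""

    dose_tolerance_percent: float = 3.0   # D_m
    dta_mm: float = 3.0                   # r_m
    normalization: str = "global"         # "global" | "local"
    dose_threshold_percent: float = 0.0   # low-dose cutoff, % of global ref max
    search_limit_factor: float = 3.0      # search radius in multiples of r_m
    interp_step_mm: float | None = None   # sampling pitch; default r_m / 10

    def __post_init__(self) -> None:
        if self.dose_tolerance_percent <= 0:
            raise InputError("dose_tolerance_percent must be positive")
        if self.dta_mm <= 0:
            raise InputError("dta_mm must be positive")
        if self.normalization not in ("global", "local"):
            raise InputError("normalization must be 'global' or 'local'")
        if not 0 <= self.dose_threshold_percent < 100:
            raise InputError("dose_threshold_percent must be in [0, 100)")
        if self.search_limit_factor < 1:
            raise InputError("search_limit_factor must be >= 1")
        if self.interp_step_mm is not None:
            if not 0 < self.interp_step_mm <= self.dta_mm:
                raise InputError("interp_step_mm must be in (0, dta_mm]")

    @property
    def step_mm(self) -> float:
        return self.interp_step_mm if self.interp_step_mm is not None else self.dta_mm / 10.0


@dataclass
class GammaMap:
    """Per-reference-point gamma values; NaN where the point was masked out."""

    gamma: np.ndarray
    evaluated_mask: np.ndarray
    criteria: GammaCriteria


@dataclass(frozen=True)
class GammaSummary:
    """Agreement fractions over the evaluated points (0..1 scale)."""

    frac_excellent: float  # gamma <= 0.5
    frac_good: float       # 0.5 < gamma < 1.0
    frac_poor: float       # gamma >= 1.0
    pass_rate: float       # gamma < 1.0

    def as_percentages(self) -> dict[str, float]:
        """Percentages rounded to one decimal, as printed in reports."""
        return {
            "excellent_pct": round(100.0 * self.frac_excellent, 1),
            "good_pct": round(100.0 * self.frac_good, 1),
            "poor_pct": round(100.0 * self.frac_poor, 1),
            "pass_rate_pct": round(100.0 * self.pass_rate, 1),
        }


# ---------------------------------------------------------------------------
# adapters
# ---------------------------------------------------------------------------

def _as_grid(obj) -> tuple[list[np.ndarray], np.ndarray]:
    """(axes in mm, dose values) for a DoseGrid or ScanTable."""
    if isinstance(obj, DoseGrid):
        return obj.axes_mm(), obj.values
    if isinstance(obj, ScanTable):
        return [obj.abscissa_mm()], obj.dose
    raise InputError(f"expected DoseGrid or ScanTable, got {type(obj).__name__}")


def _offset_lattice(step: float, radius: float, ndim: int) -> np.ndarray:
    """All lattice offsets (pitch ``step``) with |offset| <= radius."""
    m = int(np.floor(radius / step + 1e-12))
    one = step * np.arange(-m, m + 1)
    if ndim == 1:
        offsets = one[:, None]
    else:
        mesh = np.meshgrid(*([one] * ndim), indexing="ij")
        offsets = np.stack([g.ravel() for g in mesh], axis=-1)
    keep = np.einsum("ij,ij->i", offsets, offsets) <= radius**2 * (1 + 1e-12)
    return offsets[keep]


def _prepare(reference, evaluated, criteria):
    ref_axes, ref_vals = _as_grid(reference)
    ev_axes, ev_vals = _as_grid(evaluated)
    if len(ref_axes) != len(ev_axes):
        raise InputError("reference and evaluated must share dimensionality")
    if ref_vals.size == 0 or ev_vals.size == 0:
        raise InputError("empty dose distribution")
    mesh = np.meshgrid(*ref_axes, indexing="ij")
    points = np.stack([m.ravel() for m in mesh], axis=-1)
    doses = ref_vals.ravel()
    gmax = doses.max()
    if gmax <= 0:
        raise InputError("reference distribution has no positive dose")
    mask = doses >= criteria.dose_threshold_percent / 100.0 * gmax
    if criteria.normalization == "local":
        if np.any(doses[mask] <= 0):
            raise InputError("local normalization undefined at zero-dose reference points")
        dm_abs = criteria.dose_tolerance_percent / 100.0 * doses
    else:
        dm_abs = np.full_like(doses, criteria.dose_tolerance_percent / 100.0 * gmax)
    return ev_axes, ev_vals, points, doses, mask, dm_abs


# ---------------------------------------------------------------------------
# main computation
# ---------------------------------------------------------------------------

def compute_gamma(reference, evaluated, criteria: GammaCriteria = GammaCriteria()) -> GammaMap:
    """Gamma index at every reference point above the dose threshold.

    Offsets are visited nearest-first so the search stops as soon as the
    spatial term alone exceeds the worst current minimum; the result is the
    exact minimum over the full candidate lattice.
    """
    ev_axes, ev_vals, points, doses, mask, dm_abs = _prepare(reference, evaluated, criteria)
    rm = criteria.dta_mm
    offsets = _offset_lattice(criteria.step_mm, criteria.search_limit_factor * rm,
                              points.shape[1])
    dist2 = np.einsum("ij,ij->i", offsets, offsets)
    order = np.argsort(dist2, kind="stable")
    offsets, dist2 = offsets[order], dist2[order]

    interp = RegularGridInterpolator(ev_axes, ev_vals, method="linear",
                                     bounds_error=False, fill_value=np.nan)
    pts = points[mask]
    dr = doses[mask]
    dm = dm_abs[mask]
    best = np.full(pts.shape[0], np.inf)
    chunk = max(1, int(2_000_000 // max(pts.shape[0], 1)))
    i = 0
    while i < offsets.shape[0]:
        if dist2[i] / rm**2 >= best.max():
            break  # no farther offset can improve any point
        j = min(i + chunk, offsets.shape[0])
        cand_pos = pts[None, :, :] + offsets[i:j, None, :]
        de = interp(cand_pos.reshape(-1, pts.shape[1])).reshape(j - i, pts.shape[0])
        with np.errstate(invalid="ignore"):
            g2 = dist2[i:j, None] / rm**2 + ((de - dr[None, :]) / dm[None, :]) ** 2
        g2 = np.where(np.isnan(g2), np.inf, g2)
        best = np.minimum(best, g2.min(axis=0))
        i = j
    gamma = np.full(doses.shape, np.nan)
    gamma[mask] = np.sqrt(best)
    return GammaMap(gamma=gamma, evaluated_mask=mask, criteria=criteria)


def gamma_oracle(reference, evaluated, criteria: GammaCriteria = GammaCriteria()) -> GammaMap:
    """Brute-force gamma for verification: exhaustive, per-point, no shortcuts.

    Enumerates the full candidate lattice for every reference point with no
    sorting, early exit or shared intermediate state. Limited to small
    inputs; intended for tests only.
    """
    ev_axes, ev_vals, points, doses, mask, dm_abs = _prepare(reference, evaluated, criteria)
    if points.shape[0] > _ORACLE_POINT_LIMIT:
        raise ResourceError(f"oracle limited to {_ORACLE_POINT_LIMIT} reference points")
    rm = criteria.dta_mm
    radius = criteria.search_limit_factor * rm
    step = criteria.step_mm
    m = int(np.floor(radius / step + 1e-12))
    ndim = points.shape[1]
    combos = np.array(list(itertools.product(range(-m, m + 1), repeat=ndim)), dtype=float)
    offsets = step * combos
    dist2 = np.einsum("ij,ij->i", offsets, offsets)
    in_radius = dist2 <= radius**2 * (1 + 1e-12)

    gamma = np.full(doses.shape, np.nan)
    flat = gamma.ravel()
    for idx in range(points.shape[0]):
        if not mask.ravel()[idx]:
            continue
        pos = points[idx] + offsets
        de = interpn(ev_axes, ev_vals, pos, method="linear",
                     bounds_error=False, fill_value=np.nan)
        with np.errstate(invalid="ignore"):
            g2 = dist2 / rm**2 + ((de - doses[idx]) / dm_abs[idx]) ** 2
        g2 = np.where(np.isnan(g2) | ~in_radius, np.inf, g2)
        flat[idx] = np.sqrt(g2.min())
    return GammaMap(gamma=gamma, evaluated_mask=mask, criteria=criteria)


def summarize_gamma(gamma_map: GammaMap) -> GammaSummary:
    """Bin the gamma map: excellent (<=0.5), good (0.5,1), poor (>=1)."""
    g = gamma_map.gamma[gamma_map.evaluated_mask]
    g = g[~np.isnan(g)]
    if g.size == 0:
        raise EmptyEvaluationError("all reference points are masked out")
    n = g.size
    excellent = float(np.count_nonzero(g <= 0.5)) / n
    good = float(np.count_nonzero((g > 0.5) & (g < 1.0))) / n
    poor = float(np.count_nonzero(g >= 1.0)) / n
    return GammaSummary(
        frac_excellent=excellent,
        frac_good=good,
        frac_poor=poor,
        pass_rate=excellent + good,
    )
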