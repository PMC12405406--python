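"""Central-axis and profile dosimetry metrics, and relative output factors.

Depth-dose operations
    :func:`find_dmax` locates the depth of maximum dose (build-up peak),
    :func:`normalize_pdd` rescales a curve to percentage depth dose (PDD,
    dose at z_max = 100), and :func:`pdd_summary` extracts the standard
    beam-quality row: d_max, PDD at 5/10/20 cm and the D20/D5 ratio.

Profile operations
    :func:`flatness` (D_max / D_min over the central 80% of the field
    width, x100), :func:`symmetry` (worst mirrored point-pair dose ratio,
    x100), :func:`penumbra_widths` (80%-20% fall-off distance per side)
    and :func:`geometric_penumbra` (source-size projection
    P = s * (SSD + d - SDD) / SDD).

Relative factors
    :func:`scp_factor` (phantom output factor, central-axis dose relative
    to the 10x10 cm^2 reference field), :func:`sc_factor` (head scatter
    factor) and :func:`wedge_factor` (wedged over open central-axis dose)
    are pure ratios with positivity checks.

Conventions: field width is defined by the 50%-of-central-axis-dose
crossings; all crossings use linear interpolation between adjacent samples,
with ties resolved toward the beam axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dose_grid_io import ScanTable, _as_increasing
from .errors import DegenerateModelError, InputError

__all__ = [
    "DepthDoseCurve",
    "PddSummary",
    "LateralProfile",
    "ProfileSummary",
    "GeometrySpec",
    "FactorTable",
    "find_dmax",
    "normalize_pdd",
    "pdd_summary",
    "flatness",
    "symmetry",
    "penumbra_widths",
    "profile_summary",
    "geometric_penumbra",
    "scp_factor",
    "sc_factor",
    "wedge_factor",
    "curve_from_scan",
    "profile_from_scan",
]


@dataclass
class DepthDoseCurve:
    """Central-axis dose versus depth (cm). ``normalized`` marks PDD scaling."""

    depths: np.ndarray
    doses: np.ndarray
    normalized: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.depths = _as_increasing(self.depths, "depths")
        self.doses = np.asarray(self.doses, dtype=float)
        if self.doses.shape != self.depths.shape:
            raise InputError("depths and doses must have the same length")
        if np.any(self.doses < 0):
            raise InputError("doses must be non-negative")
        if self.normalized and abs(self.doses.max() - 100.0) > 1e-9:
            raise InputError("a normalized curve must have maximum 100")

    def to_scan(self) -> ScanTable:
        return ScanTable("pdd", self.depths, self.doses, dict(self.metadata))


@dataclass
class LateralProfile:
    """Off-axis dose D(x) at a stated depth; positions in mm span the axis."""

    positions: np.ndarray
    doses: np.ndarray
    depth: float = 10.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = _as_increasing(self.positions, "positions")
        self.doses = np.asarray(self.doses, dtype=float)
        if self.doses.shape != self.positions.shape:
            raise InputError("positions and doses must have the same length")
        if np.any(self.doses < 0):
            raise InputError("doses must be non-negative")

    def to_scan(self) -> ScanTable:
        meta = dict(self.metadata)
        meta.setdefault("depth_cm", str(self.depth))
        return ScanTable("profile", self.positions, self.doses, meta)


def curve_from_scan(scan: ScanTable) -> DepthDoseCurve:
    if scan.kind != "pdd":
        raise InputError(f"expected a 'pdd' scan, got {scan.kind!r}")
    return DepthDoseCurve(scan.abscissa, scan.dose, metadata=dict(scan.metadata))


def profile_from_scan(scan: ScanTable) -> LateralProfile:
    if scan.kind != "profile":
        raise InputError(f"expected a 'profile' scan, got {scan.kind!r}")
    depth = float(scan.metadata.get("depth_cm", 10.0))
    return LateralProfile(scan.abscissa, scan.dose, depth, dict(scan.metadata))


@dataclass(frozen=True)
class PddSummary:
    """The Table-row quantities of a depth-dose curve."""

    d_max: float          # cm
    pdd5: float           # %
    pdd10: float          # %
    pdd20: float          # %
    d20_d5: float         # dimensionless


@dataclass(frozen=True)
class ProfileSummary:
    flatness_percent: float
    symmetry_percent: float
    penumbra_left_mm: float
    penumbra_right_mm: float
    penumbra_avg_mm: float
    field_width_mm: float


@dataclass(frozen=True)
class GeometrySpec:
    """Source/collimator geometry for the geometric penumbra (all in mm)."""

    s: float    # source size
    ssd: float  # source-to-surface distance
    sdd: float  # source-to-diaphragm distance
    d: float    # depth of the dose plane

    def __post_init__(self) -> None:
        for name in ("s", "ssd", "sdd", "d"):
            if getattr(self, name) <= 0:
                raise InputError(f"GeometrySpec.{name} must be positive")
        if not self.sdd < self.ssd + self.d:
            raise InputError("require sdd < ssd + d for a positive penumbra")


@dataclass
class FactorTable:
    """Rows of relative dosimetric factors per (energy, field size)."""

    frame: pd.DataFrame  # columns: energy_label, field_size, s_cp, s_c, wedge_factor

    def __post_init__(self) -> None:
        required = {"energy_label", "field_size"}
        if not required.issubset(self.frame.columns):
            raise InputError(f"FactorTable requires columns {sorted(required)}")
        for col in ("s_cp", "s_c", "wedge_factor"):
            if col in self.frame.columns and np.any(self.frame[col].dropna() <= 0):
                raise InputError(f"factor column {col!r} must be positive")


# ---------------------------------------------------------------------------
# depth-dose operations
# ---------------------------------------------------------------------------

def find_dmax(curve: DepthDoseCurve) -> float:
    """Depth of maximum dose, in cm.

    The maximum sample wins (ties broken toward the smallest depth); at a
    strict interior maximum the location is refined by a parabola through
    the sample and its neighbours and snapped back to the curve's grid
    spacing, so the result is reported at the scan's own resolution.
    """
    z, y = curve.depths, curve.doses
    if z.size < 3:
        raise InputError("find_dmax needs at least 3 points")
    i = int(np.argmax(y))  # first occurrence = smallest depth on ties
    if 0 < i < z.size - 1 and y[i - 1] < y[i] and y[i + 1] < y[i]:
        denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
        if denom < 0:
            h = 0.5 * (z[i + 1] - z[i - 1])
            offset = 0.5 * (y[i - 1] - y[i + 1]) / denom
            refined = z[i] + offset * h
            return float(round(round(refined / h) * h, 10))
    return float(z[i])


def normalize_pdd(curve: DepthDoseCurve) -> DepthDoseCurve:
    """Rescale to percentage depth dose: dose at the maximum becomes 100.

    Idempotent: an already-normalized curve is returned unchanged.
    """
    if curve.normalized:
        return curve
    peak = float(curve.doses.max())
    if peak <= 0:
        raise DegenerateModelError("cannot normalize a curve with non-positive maximum")
    return DepthDoseCurve(
        curve.depths, curve.doses * (100.0 / peak), normalized=True,
        metadata=dict(curve.metadata),
    )


def pdd_summary(curve: DepthDoseCurve) -> PddSummary:
    """d_max, PDD at 5/10/20 cm (linear interpolation) and D20/D5."""
    if curve.depths[0] > 5.0 or curve.depths[-1] < 20.0:
        raise InputError("pdd_summary requires the curve to span 5-20 cm depth")
    norm = normalize_pdd(curve)
    p5, p10, p20 = np.interp([5.0, 10.0, 20.0], norm.depths, norm.doses)
    if p5 <= 0:
        raise InputError("PDD at 5 cm is zero; D20/D5 undefined")
    return PddSummary(
        d_max=find_dmax(norm),
        pdd5=float(p5),
        pdd10=float(p10),
        pdd20=float(p20),
        d20_d5=float(p20 / p5),
    )


# ---------------------------------------------------------------------------
# profile operations
# ---------------------------------------------------------------------------

def _central_axis_dose(profile: LateralProfile) -> float:
    x = profile.positions
    if x[0] > 0 or x[-1] < 0:
        raise InputError("profile does not span the beam axis (x = 0)")
    d0 = float(np.interp(0.0, x, profile.doses))
    if d0 <= 0:
        raise InputError("central-axis dose is zero")
    return d0


def _crossing_outward(x: np.ndarray, d: np.ndarray, level: float, side: str) -> float:
    """Position where dose first drops below ``level`` scanning outward.

    ``side`` is 'left' (scan toward decreasing x from the axis) or 'right'.
    Linear interpolation between the bracketing samples; because the scan
    starts at the axis, ties resolve toward the axis.
    """
    if side == "right":
        idx = np.flatnonzero(x >= 0)  # ascending = outward
    else:
        idx = np.flatnonzero(x <= 0)[::-1]  # descending = outward
    for a, b in zip(idx[:-1], idx[1:]):
        if d[a] >= level and d[b] < level:
            # linear interpolation between the bracketing samples
            t = (d[a] - level) / (d[a] - d[b])
            return float(x[a] + t * (x[b] - x[a]))
    raise InputError(f"no {level:.6g} crossing found on the {side} side")


def field_edges(profile: LateralProfile) -> tuple[float, float]:
    """Left/right 50%-of-central-axis-dose crossings (the field edges)."""
    d0 = _central_axis_dose(profile)
    x, d = profile.positions, profile.doses
    left = _crossing_outward(x, d, 0.5 * d0, "left")
    right = _crossing_outward(x, d, 0.5 * d0, "right")
    return left, right


def _central_region(profile: LateralProfile) -> tuple[float, float, float]:
    """(lo, hi) bounds of the central 80% of the field width, plus the width."""
    left, right = field_edges(profile)
    width = right - left
    centre = 0.5 * (left + right)
    return centre - 0.4 * width, centre + 0.4 * width, width


def flatness(profile: LateralProfile) -> float:
    """D_max / D_min x 100 over the central 80% of the field width."""
    lo, hi, _ = _central_region(profile)
    sel = (profile.positions >= lo) & (profile.positions <= hi)
    if not np.any(sel):
        raise InputError("no samples inside the central 80% region")
    d = profile.doses[sel]
    if d.min() <= 0:
        raise InputError("zero dose inside the central region")
    return float(d.max() / d.min() * 100.0)


def symmetry(profile: LateralProfile) -> float:
    """Worst mirrored point-pair ratio over the central 80% region, x 100.

    The mirror dose D(-x) is obtained by linear interpolation; the ratio is
    oriented so the result is >= 100.
    """
    lo, hi, _ = _central_region(profile)
    x, d = profile.positions, profile.doses
    sel = (x >= lo) & (x <= hi)
    xs, ds = x[sel], d[sel]
    if xs.size == 0:
        raise InputError("no samples inside the central 80% region")
    if -xs.max() < x[0] or -xs.min() > x[-1]:
        raise InputError("mirror positions are not covered by the profile")
    mirror = np.interp(-xs, x, d)
    if np.any(ds <= 0) or np.any(mirror <= 0):
        raise InputError("zero dose inside the central region")
    ratio = np.maximum(ds / mirror, mirror / ds)
    return float(ratio.max() * 100.0)


def penumbra_widths(profile: LateralProfile) -> tuple[float, float, float]:
    """(left, right, average) 80%-20% fall-off distances, in mm.

    Levels are percentages of the central-axis dose; crossings are found
    scanning outward from the axis with linear interpolation.
    """
    d0 = _central_axis_dose(profile)
    x, d = profile.positions, profile.doses
    widths = {}
    for side in ("left", "right"):
        x80 = _crossing_outward(x, d, 0.8 * d0, side)
        x20 = _crossing_outward(x, d, 0.2 * d0, side)
        widths[side] = abs(x20 - x80)
    return widths["left"], widths["right"], 0.5 * (widths["left"] + widths["right"])


def profile_summary(profile: LateralProfile) -> ProfileSummary:
    left, right, avg = penumbra_widths(profile)
    el, er = field_edges(profile)
    return ProfileSummary(
        flatness_percent=flatness(profile),
        symmetry_percent=symmetry(profile),
        penumbra_left_mm=left,
        penumbra_right_mm=right,
        penumbra_avg_mm=avg,
        field_width_mm=er - el,
    )


def geometric_penumbra(spec: GeometrySpec) -> float:
    """Geometric penumbra P = s * (SSD + d - SDD) / SDD, in mm."""
    return spec.s * (spec.ssd + spec.d - spec.sdd) / spec.sdd


# ---------------------------------------------------------------------------
# relative dosimetric factors
# ---------------------------------------------------------------------------

def _ratio(numerator: float, denominator: float, what: str) -> float:
    if numerator <= 0 or denominator <= 0:
        raise InputError(f"{what}: both doses must be positive")
    return float(numerator) / float(denominator)


def scp_factor(dose_field: float, dose_reference_field: float) -> float:
    """Phantom output factor: central-axis dose relative to the reference field."""
    return _ratio(dose_field, dose_reference_field, "scp_factor")


def sc_factor(reading_with_head_scatter: float, reading_reference: float) -> float:
    """Head scatter factor: in-air output relative to the reference setup."""
    return _ratio(reading_with_head_scatter, reading_reference, "sc_factor")


def wedge_factor(dose_wedged: float, dose_open: float) -> float:
    """Wedge factor: wedged over open central-axis dose at identical setup."""
    return _ratio(dose_wedged, dose_open, "wedge_factor")
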