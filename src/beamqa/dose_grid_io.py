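"""Dose-data containers and file I/O.

Two in-memory containers are the common currency of every analysis:

``DoseGrid``
    Dose values on a regular 1-, 2- or 3-D rectilinear grid with physical
    axis coordinates (off-axis x, y in mm; depth z in cm).

``ScanTable``
    A 1-D scan: central-axis depth dose (``kind="pdd"``, abscissa in cm) or
    a lateral profile at a stated depth (``kind="profile"``, abscissa in mm).

Both round-trip exactly through small, diff-able text formats:

* dose-grid CSV dialect -- ``#axis <name> <unit> <n> <values...>`` header
  lines followed by one dose value per line in row-major order with axis
  order x, y, z;
* two-column scan CSV -- ``abscissa,dose`` rows preceded by ``#key value``
  metadata comments.

DICOM RT Dose objects can additionally be imported (read-only) through
:func:`read_rtdose`.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .errors import FormatError, InputError, UnsupportedDialectError

_FLOAT_FMT = ".17g"  # round-trips IEEE doubles exactly
_GRID_MAGIC = "#beamqa dose-grid v1"
_SCAN_MAGIC = "#beamqa scan v1"
_AXIS_UNITS = {"mm": 1.0, "cm": 10.0}
SCAN_KINDS = ("pdd", "profile")


class Axis(NamedTuple):
    """One grid axis: a name, a length unit ('mm' or 'cm') and coordinates."""

    name: str
    unit: str
    coords: np.ndarray


def _as_increasing(values, what: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise InputError(f"{what} must be a non-empty 1-D sequence")
    if arr.size > 1 and not np.all(np.diff(arr) > 0):
        raise InputError(f"{what} must be strictly increasing")
    return arr


@dataclass
class DoseGrid:
    """Dose values on a regular grid with physical axis coordinates."""

    values: np.ndarray
    axes: tuple[Axis, ...]
    unit_label: str = "relative"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        axes = []
        for ax in self.axes:
            if ax.unit not in _AXIS_UNITS:
                raise InputError(f"axis {ax.name!r}: unsupported unit {ax.unit!r}")
            axes.append(Axis(ax.name, ax.unit, _as_increasing(ax.coords, f"axis {ax.name!r}")))
        self.axes = tuple(axes)
        if not self.axes:
            raise InputError("a DoseGrid needs at least one axis")
        shape = tuple(ax.coords.size for ax in self.axes)
        if self.values.shape != shape:
            raise InputError(
                f"value array shape {self.values.shape} does not match axes {shape}"
            )
        if np.any(self.values < 0):
            raise InputError("doses must be non-negative")

    @property
    def ndim(self) -> int:
        return len(self.axes)

    def axes_mm(self) -> list[np.ndarray]:
        """Axis coordinates converted to millimetres (gamma's length unit)."""
        return [ax.coords * _AXIS_UNITS[ax.unit] for ax in self.axes]

    def copy(self) -> "DoseGrid":
        return DoseGrid(
            self.values.copy(),
            tuple(Axis(a.name, a.unit, a.coords.copy()) for a in self.axes),
            self.unit_label,
            dict(self.provenance),
        )


@dataclass
class ScanTable:
    """A 1-D dose scan (depth dose or lateral profile) plus metadata."""

    kind: str
    abscissa: np.ndarray
    dose: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in SCAN_KINDS:
            raise InputError(f"scan kind must be one of {SCAN_KINDS}, got {self.kind!r}")
        self.abscissa = _as_increasing(self.abscissa, "abscissa")
        self.dose = np.asarray(self.dose, dtype=float)
        if self.dose.shape != self.abscissa.shape:
            raise InputError("abscissa and dose must have the same length")
        if np.any(self.dose < 0):
            raise InputError("doses must be non-negative")

    def abscissa_mm(self) -> np.ndarray:
        """Abscissa in mm (depth-dose scans are stored in cm)."""
        return self.abscissa * (10.0 if self.kind == "pdd" else 1.0)


# ---------------------------------------------------------------------------
# dose-grid CSV dialect
# ---------------------------------------------------------------------------

def write_dose_grid(grid: DoseGrid, destination) -> None:
    """Write ``grid`` in the dose-grid CSV dialect (value-exact round trip)."""
    lines = [_GRID_MAGIC, f"#unit {grid.unit_label}"]
    for key in sorted(grid.provenance):
        lines.append(f"#meta {key} {grid.provenance[key]}")
    for ax in grid.axes:
        coords = " ".join(format(c, _FLOAT_FMT) for c in ax.coords)
        lines.append(f"#axis {ax.name} {ax.unit} {ax.coords.size} {coords}")
    for v in grid.values.ravel(order="C"):
        lines.append(format(v, _FLOAT_FMT))
    _write_text(destination, "\n".join(lines) + "\n")


def read_dose_grid(source) -> DoseGrid:
    """Read a dose-grid CSV file written by :func:`write_dose_grid`."""
    text = _read_text(source)
    axes: list[Axis] = []
    unit_label = "relative"
    provenance: dict = {}
    values: list[float] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if lineno == 1:
            if line != _GRID_MAGIC:
                raise FormatError(f"line 1: expected {_GRID_MAGIC!r}")
            continue
        if line.startswith("#axis"):
            parts = line.split()
            if len(parts) < 4:
                raise FormatError(f"line {lineno}: malformed #axis header")
            name, unit = parts[1], parts[2]
            if unit not in _AXIS_UNITS:
                raise FormatError(f"line {lineno}: unsupported axis unit {unit!r}")
            try:
                n = int(parts[3])
                coords = np.array([float(p) for p in parts[4:]])
            except ValueError as exc:
                raise FormatError(f"line {lineno}: {exc}") from exc
            if coords.size != n:
                raise FormatError(
                    f"line {lineno}: axis {name!r} declares {n} values, found {coords.size}"
                )
            if coords.size > 1 and not np.all(np.diff(coords) > 0):
                raise FormatError(f"line {lineno}: axis {name!r} not strictly increasing")
            axes.append(Axis(name, unit, coords))
        elif line.startswith("#unit"):
            unit_label = line.split(maxsplit=1)[1] if " " in line else "relative"
        elif line.startswith("#meta"):
            parts = line.split(maxsplit=2)
            if len(parts) == 3:
                provenance[parts[1]] = parts[2]
        elif line.startswith("#"):
            raise FormatError(f"line {lineno}: unknown header {line!r}")
        else:
            try:
                v = float(line)
            except ValueError as exc:
                raise FormatError(f"line {lineno}: not a number: {line!r}") from exc
            if v < 0:
                raise FormatError(f"line {lineno}: negative dose {line!r}")
            values.append(v)
    if not axes:
        raise FormatError("no #axis headers found")
    shape = tuple(len(ax.coords) for ax in axes)
    expected = int(np.prod(shape))
    if len(values) != expected:
        raise FormatError(
            f"axis headers declare {expected} values but {len(values)} data rows found"
        )
    return DoseGrid(np.array(values).reshape(shape), tuple(axes), unit_label, provenance)


# ---------------------------------------------------------------------------
# scan CSV
# ---------------------------------------------------------------------------

def write_scan_table(scan: ScanTable, destination) -> None:
    """Write ``scan`` as two-column CSV with ``#key value`` metadata comments."""
    lines = [_SCAN_MAGIC, f"#kind {scan.kind}"]
    for key in sorted(scan.metadata):
        lines.append(f"#{key} {scan.metadata[key]}")
    lines.append("abscissa,dose")
    for a, d in zip(scan.abscissa, scan.dose):
        lines.append(f"{format(a, _FLOAT_FMT)},{format(d, _FLOAT_FMT)}")
    _write_text(destination, "\n".join(lines) + "\n")


def read_scan_table(source) -> ScanTable:
    """Read a scan CSV file written by :func:`write_scan_table`."""
    text = _read_text(source)
    kind = None
    metadata: dict = {}
    abscissa: list[float] = []
    dose: list[float] = []
    seen_header = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if lineno == 1:
            if line != _SCAN_MAGIC:
                raise FormatError(f"line 1: expected {_SCAN_MAGIC!r}")
            continue
        if line.startswith("#kind"):
            parts = line.split()
            if len(parts) != 2 or parts[1] not in SCAN_KINDS:
                raise FormatError(f"line {lineno}: bad #kind header")
            kind = parts[1]
        elif line.startswith("#"):
            parts = line[1:].split(maxsplit=1)
            if len(parts) == 2:
                metadata[parts[0]] = parts[1]
        elif line == "abscissa,dose":
            seen_header = True
        else:
            parts = line.split(",")
            if len(parts) != 2:
                raise FormatError(f"line {lineno}: expected 'abscissa,dose' pair")
            try:
                a, d = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise FormatError(f"line {lineno}: {exc}") from exc
            if abscissa and a <= abscissa[-1]:
                raise FormatError(f"line {lineno}: abscissa not strictly increasing")
            if d < 0:
                raise FormatError(f"line {lineno}: negative dose")
            abscissa.append(a)
            dose.append(d)
    if kind is None:
        raise FormatError("missing #kind header")
    if not seen_header or not abscissa:
        raise FormatError("scan table contains no data rows")
    return ScanTable(kind, np.array(abscissa), np.array(dose), metadata)


# ---------------------------------------------------------------------------
# DICOM RT Dose import
# ---------------------------------------------------------------------------

def read_rtdose(source) -> DoseGrid:
    """Import a DICOM RT Dose object as a :class:`DoseGrid` (unit Gy).

    The stored integer grid is multiplied by the dose-grid scaling factor;
    the depth axis is reconstructed from the frame offset vector (uniform
    offsets only) and converted from patient-space mm to the toolkit's
    cm depth convention.
    """
    import pydicom

    ds = pydicom.dcmread(source, force=True)
    if "DoseGridScaling" not in ds:
        raise FormatError("RT Dose object lacks DoseGridScaling")
    if "PixelData" not in ds:
        raise FormatError("RT Dose object lacks a dose grid (PixelData)")
    scaling = float(ds.DoseGridScaling)
    arr = ds.pixel_array.astype(float) * scaling

    ipp = [float(v) for v in getattr(ds, "ImagePositionPatient", [0.0, 0.0, 0.0])]
    spacing = [float(v) for v in getattr(ds, "PixelSpacing", [1.0, 1.0])]
    rows, cols = int(ds.Rows), int(ds.Columns)
    x = ipp[0] + spacing[1] * np.arange(cols)  # columns run along x
    y = ipp[1] + spacing[0] * np.arange(rows)

    nframes = int(getattr(ds, "NumberOfFrames", 1))
    if nframes > 1:
        if "GridFrameOffsetVector" not in ds:
            raise FormatError("multi-frame RT Dose lacks GridFrameOffsetVector")
        offsets = np.asarray([float(v) for v in ds.GridFrameOffsetVector])
        steps = np.diff(offsets)
        if steps.size and (np.any(steps <= 0) or np.ptp(steps) > 1e-6 * abs(steps[0])):
            raise UnsupportedDialectError("non-uniform frame offsets are not supported")
        z_cm = offsets / 10.0
        values = np.transpose(arr, (2, 1, 0))  # (frame,row,col) -> (x,y,z)
        axes = (Axis("x", "mm", x), Axis("y", "mm", y), Axis("z", "cm", z_cm))
    else:
        if arr.ndim == 3:
            arr = arr[0]
        values = arr.T  # (row,col) -> (x,y) with x = columns
        axes = (Axis("x", "mm", x), Axis("y", "mm", y))
    provenance = {
        "source": "dicom-rtdose",
        "sop_instance_uid": str(getattr(ds, "SOPInstanceUID", "")),
    }
    return DoseGrid(values, axes, unit_label="Gy", provenance=provenance)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _write_text(destination, text: str) -> None:
    if hasattr(destination, "write"):
        destination.write(text)
    else:
        with open(os.fspath(destination), "w", encoding="utf-8") as fh:
            fh.write(text)


def _read_text(source) -> str:
    if hasattr(source, "read"):
        return source.read()
    with open(os.fspath(source), "r", encoding="utf-8") as fh:
        return fh.read()
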