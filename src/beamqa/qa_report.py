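"""Comparative QA reports: beam-summary tables, deviation tables, gamma reports.

This module orchestrates the library into the standard commissioning-style
outputs: per-beam PDD summaries (d_max, PDD at 5/10/20 cm, D20/D5), profile
metrics (flatness, symmetry, penumbra), relative-factor tables, per-pair
gamma summaries, and per-key deviation tables between two data sources.

Rounding policy (matching clinical report precision): dimensionless ratios
to 3 decimals, percentages to 1-2 decimals, penumbra widths to 2 decimals.
Every artifact written by :func:`run_config` embeds its criteria and
generator parameters so reports are self-describing, and a fixed seed makes
two runs byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .beam_metrics import (
    FactorTable,
    curve_from_scan,
    pdd_summary,
    profile_summary,
)
from .dose_grid_io import Axis, DoseGrid, ScanTable, write_scan_table
from .dose_model import BeamModelParams, make_pdd_curve, make_profile, model_factor_table, perturb_grid
from .errors import ConfigError, InputError
from .gamma_engine import GammaCriteria, compute_gamma, summarize_gamma

__all__ = [
    "BeamSummaryTable",
    "ComparisonReport",
    "build_beam_table",
    "compare_tables",
    "gamma_report",
    "run_config",
]

_BEAM_COLUMNS = ["energy", "field_size", "source", "d_max", "pdd5", "pdd10", "pdd20", "d20_d5"]


@dataclass
class BeamSummaryTable:
    """One PDD-summary row per (energy, field size, source)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(_BEAM_COLUMNS) - set(self.frame.columns)
        if missing and len(self.frame):
            raise InputError(f"BeamSummaryTable missing columns {sorted(missing)}")
        if len(self.frame):
            keys = self.frame[["energy", "field_size", "source"]].apply(tuple, axis=1)
            if keys.duplicated().any():
                raise InputError("duplicate (energy, field_size, source) keys")

    def rounded(self) -> pd.DataFrame:
        """Report formatting: percentages to 1 decimal, ratios to 3."""
        out = self.frame.copy()
        if len(out):
            for col in ("pdd5", "pdd10", "pdd20"):
                out[col] = out[col].round(1)
            out["d_max"] = out["d_max"].round(1)
            out["d20_d5"] = out["d20_d5"].round(3)
        return out


@dataclass
class ComparisonReport:
    """Per-key deviations between two sources, plus summary statistics."""

    kind: str
    frame: pd.DataFrame
    summary: dict = field(default_factory=dict)
    rounding: str = "ratios 3 dp, percentages 1 dp, penumbra 2 dp"


def build_beam_table(scans: Sequence[ScanTable],
                     labels: Sequence[dict] | None = None) -> BeamSummaryTable:
    """Run :func:`pdd_summary` over depth-dose scans and tabulate the rows.

    Each scan needs an (energy, field_size, source) key, taken from
    ``labels`` (parallel to ``scans``) or from the scan's own metadata.
    """
    if labels is not None and len(labels) != len(scans):
        raise InputError("labels must parallel scans")
    rows = []
    for i, scan in enumerate(scans):
        meta = dict(scan.metadata)
        if labels is not None:
            meta.update(labels[i])
        key = {k: meta.get(k, "") for k in ("energy", "field_size", "source")}
        summ = pdd_summary(curve_from_scan(scan))
        rows.append({**key, "d_max": summ.d_max, "pdd5": summ.pdd5,
                     "pdd10": summ.pdd10, "pdd20": summ.pdd20, "d20_d5": summ.d20_d5})
    frame = pd.DataFrame(rows, columns=_BEAM_COLUMNS)
    return BeamSummaryTable(frame)


def _long_form(table) -> pd.DataFrame:
    """Melt a summary/factor table to (key, metric) -> value."""
    if isinstance(table, BeamSummaryTable):
        frame, keys = table.frame, ["energy", "field_size"]
        # a multi-source table needs 'source' in the key to stay unique;
        # single-source tables drop it so two sources can be compared
        if len(frame) and frame["source"].nunique() > 1:
            keys = keys + ["source"]
        values = [c for c in frame.columns if c not in keys + ["source"]]
    elif isinstance(table, FactorTable):
        frame, keys = table.frame, ["energy_label", "field_size"]
        values = [c for c in frame.columns if c not in keys]
    elif isinstance(table, pd.DataFrame):
        keys = [c for c in ("energy", "energy_label", "field_size") if c in table.columns]
        if not keys:
            raise InputError("DataFrame comparison needs energy/field_size key columns")
        frame = table
        values = [c for c in frame.columns if c not in keys + ["source"]]
    else:
        raise InputError(f"cannot compare objects of type {type(table).__name__}")
    long = frame.melt(id_vars=keys, value_vars=values, var_name="metric")
    long["key"] = long[keys + ["metric"]].astype(str).apply("|".join, axis=1)
    return long.set_index("key")["value"]


def compare_tables(a, b) -> ComparisonReport:
    """Per-shared-key deviation b - a between two tables of the same kind.

    Accepts two :class:`BeamSummaryTable`, two :class:`FactorTable`, or two
    plain DataFrames keyed by energy/field-size columns.
    """
    if type(a) is not type(b):
        raise InputError("compare_tables requires two tables of the same kind")
    va, vb = _long_form(a), _long_form(b)
    shared = va.index.intersection(vb.index)
    if len(shared) == 0:
        raise InputError("the two tables share no keys")
    frame = pd.DataFrame({
        "key": shared,
        "value_a": va.loc[shared].to_numpy(dtype=float),
        "value_b": vb.loc[shared].to_numpy(dtype=float),
    })
    frame["deviation"] = frame["value_b"] - frame["value_a"]
    frame["abs_deviation"] = frame["deviation"].abs()
    summary = {
        "n_keys": int(len(frame)),
        "max_abs_deviation": float(frame["abs_deviation"].max()),
        "mean_abs_deviation": float(frame["abs_deviation"].mean()),
    }
    return ComparisonReport(kind=type(a).__name__, frame=frame, summary=summary)


def gamma_report(pairs: Sequence[tuple], criteria: GammaCriteria = GammaCriteria()) -> ComparisonReport:
    """Per-pair gamma summary table (columns as in clinical GI reports).

    ``pairs`` holds (reference, evaluated, label) triples; percentages are
    reported at one decimal. The comparison direction is reference ->
    evaluated and is recorded in the report summary.
    """
    rows = []
    for reference, evaluated, label in pairs:
        summ = summarize_gamma(compute_gamma(reference, evaluated, criteria))
        pct = summ.as_percentages()
        rows.append({
            "label": label,
            "GI < 1.0": pct["pass_rate_pct"],
            "GI < 0.5": pct["excellent_pct"],
            "good_pct": pct["good_pct"],
            "poor_pct": pct["poor_pct"],
        })
    frame = pd.DataFrame(rows, columns=["label", "GI < 1.0", "GI < 0.5", "good_pct", "poor_pct"])
    summary = {
        "criteria": {
            "dose_tolerance_percent": criteria.dose_tolerance_percent,
            "dta_mm": criteria.dta_mm,
            "normalization": criteria.normalization,
            "dose_threshold_percent": criteria.dose_threshold_percent,
            "direction": "reference->evaluated",
        },
        "n_pairs": int(len(frame)),
    }
    return ComparisonReport(kind="GammaReport", frame=frame, summary=summary)


# ---------------------------------------------------------------------------
# end-to-end configuration runner
# ---------------------------------------------------------------------------

_KNOWN_KEYS = {"seed", "output_dir", "beams", "analyses", "gamma", "pdd", "profile", "factors"}
_KNOWN_ANALYSES = {"beam_table", "profile_table", "factors", "gamma"}
_BEAM_KEYS = {"energy", "field_size", "noise_sd", "wedge_transmission_gradient",
              "penumbra_sigma", "horn_amplitude", "ssd"}


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config, "r", encoding="utf-8") as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ConfigError("configuration must be a mapping")
    unknown = sorted(set(config) - _KNOWN_KEYS)
    if unknown:
        raise ConfigError(f"unknown configuration keys: {unknown}")
    for i, beam in enumerate(config.get("beams", [])):
        bad = sorted(set(beam) - _BEAM_KEYS)
        if bad:
            raise ConfigError(f"beams[{i}]: unknown keys: {bad}")
    analyses = config.get("analyses", sorted(_KNOWN_ANALYSES))
    bad = sorted(set(analyses) - _KNOWN_ANALYSES)
    if bad:
        raise ConfigError(f"unknown analyses: {bad}")
    return config


def _beam_params(config: dict, seed: int) -> list[BeamModelParams]:
    beams = config.get("beams") or [
        {"energy": "6MV", "field_size": 10.0},
        {"energy": "12MV", "field_size": 10.0},
    ]
    out = []
    for i, beam in enumerate(beams):
        overrides = {k: v for k, v in beam.items() if k != "energy"}
        out.append(BeamModelParams.for_energy(beam.get("energy", "6MV"),
                                              seed=(seed + i) % 2**31, **overrides))
    return out


def run_config(config, output_dir=None) -> dict:
    """Run the analyses declared in ``config`` and write tables to disk.

    Returns a dict naming the written artifacts. Deterministic under a
    fixed seed: the same configuration writes byte-identical files.
    """
    config = _load_config(config)
    seed = int(config.get("seed", 0))
    outdir = Path(output_dir or config.get("output_dir", "beamqa_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    analyses = config.get("analyses", sorted(_KNOWN_ANALYSES))
    params_list = _beam_params(config, seed)

    pdd_cfg = config.get("pdd", {})
    depths = np.round(np.arange(pdd_cfg.get("start", 0.0),
                                pdd_cfg.get("stop", 30.0) + 1e-9,
                                pdd_cfg.get("step", 0.1)), 10)
    prof_cfg = config.get("profile", {})
    prof_depth = prof_cfg.get("depth_cm", 10.0)

    artifacts: dict[str, str] = {}
    written: list[Path] = []

    def _write_frame(name: str, frame: pd.DataFrame) -> None:
        path = outdir / f"{name}.csv"
        frame.to_csv(path, index=False, lineterminator="\n")
        artifacts[name] = str(path)
        written.append(path)

    if "beam_table" in analyses:
        scans = []
        for p in params_list:
            curve = make_pdd_curve(p, depths)
            scan = curve.to_scan()
            scan.metadata.update(energy=p.energy_label, field_size=str(p.field_size),
                                 source="model")
            scans.append(scan)
            write_scan_table(scan, outdir / f"pdd_{p.energy_label}_{p.field_size:g}.csv")
        table = build_beam_table(scans)
        _write_frame("beam_table", table.rounded())

    if "profile_table" in analyses:
        rows = []
        for p in params_list:
            half = 0.8 * p.field_width_mm(prof_depth)
            positions = np.round(np.arange(-half, half + 1e-9, prof_cfg.get("step_mm", 0.5)), 10)
            prof = make_profile(p, prof_depth, positions)
            s = profile_summary(prof)
            rows.append({
                "energy": p.energy_label,
                "field_size": p.field_size,
                "depth_cm": prof_depth,
                "flatness_pct": round(s.flatness_percent, 2),
                "symmetry_pct": round(s.symmetry_percent, 2),
                "penumbra_left_mm": round(s.penumbra_left_mm, 2),
                "penumbra_right_mm": round(s.penumbra_right_mm, 2),
                "penumbra_avg_mm": round(s.penumbra_avg_mm, 2),
            })
        _write_frame("profile_table", pd.DataFrame(rows))

    if "factors" in analyses:
        factor_params = list(params_list)
        energies = {p.energy_label for p in factor_params}
        for e in sorted(energies):
            if not any(p.field_size == 10.0 and p.energy_label == e for p in factor_params):
                factor_params.append(BeamModelParams.for_energy(e, field_size=10.0))
        table = model_factor_table(factor_params)
        rounded = table.frame.copy()
        for col in ("s_cp", "s_c", "wedge_factor"):
            rounded[col] = rounded[col].round(3)
        _write_frame("factors", rounded)

    if "gamma" in analyses:
        gcfg = config.get("gamma", {})
        criteria = GammaCriteria(
            dose_tolerance_percent=gcfg.get("dd_percent", 3.0),
            dta_mm=gcfg.get("dta_mm", 3.0),
            normalization=gcfg.get("normalization", "global"),
            dose_threshold_percent=gcfg.get("threshold_percent", 0.0),
        )
        shift_cm = gcfg.get("shift_mm", 1.0) / 10.0
        noise_sd = gcfg.get("noise_sd", 0.01)
        pairs = []
        for i, p in enumerate(params_list):
            curve = make_pdd_curve(p, depths)
            ref = DoseGrid(curve.doses, (Axis("z", "cm", curve.depths),),
                           provenance={"beam": p.energy_label})
            ev = perturb_grid(ref, shift=shift_cm, noise_sd=noise_sd,
                              seed=(seed + 1000 + i) % 2**31)
            pairs.append((ref, ev, f"{p.energy_label} {p.field_size:g}x{p.field_size:g} PDD"))
        report = gamma_report(pairs, criteria)
        _write_frame("gamma_report", report.frame)
        path = outdir / "gamma_report.json"
        path.write_text(json.dumps({"summary": report.summary,
                                    "rows": report.frame.to_dict(orient="records")},
                                   indent=2, sort_keys=True) + "\n", encoding="utf-8")
        artifacts["gamma_report_json"] = str(path)

    log = {
        "version": _version,
        "seed": seed,
        "config": {k: v for k, v in config.items()},
        "beams": [
            {"energy": p.energy_label, "field_size": p.field_size, "mu": p.mu,
             "k_buildup": p.k_buildup, "noise_sd": p.noise_sd, "seed": p.seed}
            for p in params_list
        ],
    }
    log_path = outdir / "run_log.json"
    log_path.write_text(json.dumps(log, indent=2, sort_keys=True, default=str) + "\n",
                        encoding="utf-8")
    artifacts["run_log"] = str(log_path)
    return artifacts
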