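"""Readers, writers and pipeline entry points.

File conventions: CSV with a header row, period decimal separator, UTF-8;
JSON for structured reports. Configuration files (YAML or JSON) reference
either the built-in published parameter sets by name ("gemcitabine",
"gem_combo_avg", ...) or spell the fields out inline.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .combination import (
    CombinationScenario,
    MultipleDosingSpec,
    compare_auc_effect,
    simulate_combination,
)
from .disposition import (
    DispositionTrajectory,
    DoseRegimen,
    PKParameters,
    SimulationGrid,
    auc_infinity,
    integrate_disposition,
)
from .effect import BottomModulation, HillCurve, drop_onset_time, effect_trajectory
from .estimation import FitResult, fit_bottom_quadratic, fit_hill, fit_two_compartment
from .synthetic import ConcentrationSample, DoseResponseSample, reference_fixtures

__all__ = [
    "read_concentration_csv",
    "write_concentration_csv",
    "read_dose_response_csv",
    "write_dose_response_csv",
    "read_hill_csv",
    "write_hill_csv",
    "write_trajectory_csv",
    "write_fit_report",
    "load_config",
    "cmd_simulate",
    "cmd_effect",
    "cmd_combo",
    "cmd_fit",
]

CONC_COLUMNS = ["time_min", "conc_ug_per_ml"]
DR_COLUMNS = ["conc", "unit", "inhibition_percent", "replicate"]
HILL_COLUMNS = ["label", "bottom", "top", "steepness", "ec50"]


def _require_columns(frame: pd.DataFrame, columns: Sequence[str], path) -> None:
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


def read_concentration_csv(path) -> list[ConcentrationSample]:
    frame = pd.read_csv(path)
    _require_columns(frame, CONC_COLUMNS, path)
    if frame.empty:
        raise ValueError(f"{path}: no data rows")
    return [ConcentrationSample(time=float(r.time_min), conc=float(r.conc_ug_per_ml))
            for r in frame.itertuples()]


def write_concentration_csv(samples: Sequence[ConcentrationSample], path) -> None:
    pd.DataFrame({"time_min": [s.time for s in samples],
                  "conc_ug_per_ml": [s.conc for s in samples]}).to_csv(path, index=False)


def read_dose_response_csv(path) -> list[DoseResponseSample]:
    frame = pd.read_csv(path)
    _require_columns(frame, DR_COLUMNS, path)
    if frame.empty:
        raise ValueError(f"{path}: no data rows")
    return [DoseResponseSample(conc=float(r.conc), inhibition=float(r.inhibition_percent),
                               replicate=int(r.replicate), unit=str(r.unit))
            for r in frame.itertuples()]


def write_dose_response_csv(samples: Sequence[DoseResponseSample], path) -> None:
    pd.DataFrame({"conc": [s.conc for s in samples],
                  "unit": [s.unit for s in samples],
                  "inhibition_percent": [s.inhibition for s in samples],
                  "replicate": [s.replicate for s in samples]}).to_csv(path, index=False)


def read_hill_csv(path) -> dict[str, HillCurve]:
    frame = pd.read_csv(path)
    _require_columns(frame, HILL_COLUMNS, path)
    return {str(r.label): HillCurve(bottom=float(r.bottom), top=float(r.top),
                                    steepness=float(r.steepness), ec50=float(r.ec50))
            for r in frame.itertuples()}


def write_hill_csv(curves: Mapping[str, HillCurve], path) -> None:
    pd.DataFrame([{"label": label, "bottom": c.bottom, "top": c.top,
                   "steepness": c.steepness, "ec50": c.ec50}
                  for label, c in curves.items()]).to_csv(path, index=False)


def write_trajectory_csv(traj: DispositionTrajectory, path) -> None:
    pd.DataFrame({
        "time_min": traj.times,
        "plasma_amount_mg": traj.plasma_amount,
        "tissue_amount_mg": traj.tissue_amount,
        "eliminated_amount_mg": traj.eliminated_amount,
        "plasma_conc_ug_per_ml": traj.plasma_conc,
        "tissue_conc_ug_per_ml": traj.tissue_conc,
        "auc_plasma": traj.auc_plasma,
    }).to_csv(path, index=False)


def write_fit_report(result: FitResult, path) -> None:
    payload = dataclasses.asdict(result)
    Path(path).write_text(json.dumps(payload, indent=2))


def load_config(path) -> dict:
    """Parse a YAML or JSON run configuration."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return data


# -- config resolution -------------------------------------------------------

def _fixtures() -> dict:
    return reference_fixtures()


def _resolve(entry: Any, cls, fixtures: dict):
    if isinstance(entry, cls):
        return entry
    if isinstance(entry, str):
        obj = fixtures.get(entry)
        if not isinstance(obj, cls):
            raise ValueError(f"unknown fixture {entry!r} for {cls.__name__}")
        return obj
    if isinstance(entry, Mapping):
        return cls(**entry)
    raise ValueError(f"cannot interpret {entry!r} as {cls.__name__}")


def _resolve_grid(entry: Any) -> SimulationGrid:
    if isinstance(entry, SimulationGrid):
        return entry
    if isinstance(entry, Mapping):
        return SimulationGrid(**entry)
    raise ValueError("grid must be a mapping with t_end (and optional h, method)")


# -- pipeline commands -------------------------------------------------------

def cmd_simulate(config: Mapping | str, out_dir=None) -> dict:
    """Single-drug disposition run: trajectory CSV plus a summary JSON.

    The summary reports total plasma AUC (rectangle accumulator), the
    analytic Dose/CL reference, Cmax and the worst mass-balance defect.
    """
    cfg = load_config(config) if isinstance(config, (str, Path)) else dict(config)
    fixtures = _fixtures()
    params = _resolve(cfg["drug"], PKParameters, fixtures)
    regimen = _resolve(cfg["regimen"], DoseRegimen, fixtures)
    grid = _resolve_grid(cfg.get("grid", {"t_end": 400.0}))
    traj = integrate_disposition(params, regimen, grid)
    summary = {
        "auc_plasma": traj.auc_total,
        "auc_trapezoid": traj.auc(rule="trapezoid"),
        "auc_infinity": auc_infinity(params, regimen.total_dose),
        "cmax": traj.cmax,
        "t_cmax": traj.t_cmax,
        "mass_balance_error": traj.mass_balance_error(),
        "grid": {"t_end": grid.t_end, "h": grid.h, "method": grid.method},
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_trajectory_csv(traj, out / "disposition.csv")
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary


def cmd_effect(config: Mapping | str, out_dir=None) -> dict:
    """Single-drug effect run: % inhibition over time and its AUC_effect."""
    cfg = load_config(config) if isinstance(config, (str, Path)) else dict(config)
    fixtures = _fixtures()
    params = _resolve(cfg["drug"], PKParameters, fixtures)
    regimen = _resolve(cfg["regimen"], DoseRegimen, fixtures)
    curve = _resolve(cfg["curve"], HillCurve, fixtures)
    grid = _resolve_grid(cfg.get("grid", {"t_end": 400.0}))
    traj = integrate_disposition(params, regimen, grid)
    eff = effect_trajectory(traj, curve)
    summary = {"auc_effect": eff.total_auc,
               "has_negative_effect": eff.has_negative_effect}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame({"time_min": eff.times, "effect_percent": eff.effect,
                      "auc_effect": eff.auc_effect}).to_csv(out / "effect.csv",
                                                            index=False)
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary


def cmd_combo(config: Mapping | str, out_dir=None) -> dict:
    """Coupled ACD + itraconazole scenarios compared by AUC_effect.

    Each scenario entry gives a label and an itraconazole regimen; the
    scenario list must include the control named by ``control``. Reports
    AUC_effect, percent change versus control, the plateau level over
    ``plateau_window`` and the drop-onset time at ``drop_threshold``.
    """
    cfg = load_config(config) if isinstance(config, (str, Path)) else dict(config)
    fixtures = _fixtures()
    acd_params = _resolve(cfg["acd"]["params"], PKParameters, fixtures)
    acd_regimen = _resolve(cfg["acd"]["regimen"], DoseRegimen, fixtures)
    itz_params = _resolve(cfg["itz"]["params"], PKParameters, fixtures)
    curve = _resolve(cfg["curve"], HillCurve, fixtures)
    bottom_mod = _resolve(cfg["bottom_mod"], BottomModulation, fixtures)
    grid = _resolve_grid(cfg.get("grid", {"t_end": 400.0}))
    control = cfg.get("control")
    scenarios = cfg["scenarios"]
    labels = [s["label"] for s in scenarios]
    if control is None or control not in labels:
        raise ValueError("configuration must name a 'control' present in scenarios")

    plateau_window = tuple(cfg.get("plateau_window", (30.0, 120.0)))
    drop_threshold = float(cfg.get("drop_threshold", 0.008))

    runs = {}
    details = {}
    for entry in scenarios:
        scenario = CombinationScenario(
            acd_params=acd_params, acd_regimen=acd_regimen,
            itz_params=itz_params,
            itz_regimen=_resolve(entry["itz_regimen"], DoseRegimen, fixtures),
            curve=curve, bottom_mod=bottom_mod, grid=grid, label=entry["label"])
        result = simulate_combination(scenario)
        runs[entry["label"]] = result.effect
        onset = drop_onset_time(result.acd, drop_threshold)
        details[entry["label"]] = {
            "plateau": result.effect.plateau(plateau_window),
            "drop_onset_min": onset,
        }
    comparison = compare_auc_effect(runs, control_label=control,
                                    window=cfg.get("window"))
    report = {"control": control, "scenarios": []}
    for label, auc, pct in zip(comparison.labels, comparison.auc_effect,
                               comparison.percent_change):
        report["scenarios"].append({"label": label, "auc_effect": auc,
                                    "percent_change_vs_control": pct,
                                    **details[label]})
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        comparison.to_frame().to_csv(out / "auc_effect.csv", index=False)
        (out / "comparison.json").write_text(json.dumps(report, indent=2))
    return report


def cmd_fit(data_path, mode: str, regimen: DoseRegimen | str | Mapping | None = None,
            out=None, seed: int = 0) -> FitResult | BottomModulation:
    """Fit a model to a data file: 'pk2c', 'hill' or 'bottom'."""
    if mode == "pk2c":
        if regimen is None:
            raise ValueError("pk2c fitting requires the dose regimen")
        samples = read_concentration_csv(data_path)
        reg = _resolve(regimen, DoseRegimen, _fixtures())
        result = fit_two_compartment(samples, reg, seed=seed)
    elif mode == "hill":
        dr = read_dose_response_csv(data_path)
        _, result = fit_hill(dr, seed=seed)
    elif mode == "bottom":
        frame = pd.read_csv(data_path)
        _require_columns(frame, ["x_ug_per_ml", "bottom_percent"], data_path)
        mod = fit_bottom_quadratic(list(zip(frame["x_ug_per_ml"],
                                            frame["bottom_percent"])))
        if out is not None:
            Path(out).write_text(json.dumps(dataclasses.asdict(mod), indent=2))
        return mod
    else:
        raise ValueError(f"unknown fit mode {mode!r}")
    if out is not None:
        write_fit_report(result, out)
    return result
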