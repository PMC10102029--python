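"""Experiment-level orchestration: config loading, the fixed stage order
(titrant → ionization → blank → slope segmentation → surface area → ILR →
mechanistic fit), and report writing.

The pipeline is a pure function of its input files and configuration:
rerunning it produces byte-identical reports.  Every correction and derived
quantity is logged with one line per stage so the processing is auditable.
"""

from __future__ import annotations

import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import ValidationError
from .geometry import DropletPopulation, total_surface_area
from .ilr import IlrResult, MixPrediction, compute_ilr, predict_mixed_ilr
from .mechanistic import MechanisticFit, compare_rate_constants, fit_release_curve
from .registry import (Formulation, LipidRegistry, fa_molar_fractions,
                       formulation_from_dict, load_formulation, load_registry,
                       theoretical_fa_release)
from .synthetic import formulation_density
from .titration import (process_record, read_titration_csv, segment_curve,
                        write_release_csv)
from .units import M_PER_NM

log = logging.getLogger("ilrkit")


@dataclass(frozen=True)
class AnalysisOptions:
    window_points: int = 11
    smoothing_points: int = 0
    lag_method: str = "tangent"
    deviation_denominator: str = "predicted"


@dataclass(frozen=True)
class ExperimentConfig:
    """Resolved configuration for one pH-stat experiment analysis."""

    name: str
    sample_csv: Path
    titrant_molarity: float
    ph9_titrant_volume_ml: float
    formulation: Formulation
    diameter_nm: float
    pdi: float | None = None
    blank_csv: Path | None = None
    blank_titrant_molarity: float | None = None
    blank_ph9_titrant_volume_ml: float = 0.0
    analysis: AnalysisOptions = field(default_factory=AnalysisOptions)
    output_dir: Path | None = None

    def __post_init__(self) -> None:
        if not self.sample_csv.exists():
            raise ValidationError(f"sample CSV not found: {self.sample_csv}")
        if self.blank_csv is not None and not self.blank_csv.exists():
            raise ValidationError(f"blank CSV not found: {self.blank_csv}")
        if self.diameter_nm <= 0:
            raise ValidationError("diameter must be > 0")


def read_dls_csv(path: str | Path) -> tuple[float, float]:
    """Mean (diameter_nm, pdi) over replicate rows of a DLS export CSV."""
    df = pd.read_csv(path)
    for col in ("diameter_nm", "pdi"):
        if col not in df.columns:
            raise ValidationError(f"{path}: expected a {col!r} column")
    return float(df["diameter_nm"].mean()), float(df["pdi"].mean())


def load_experiment_config(path: str | Path) -> ExperimentConfig:
    """Load an experiment TOML; relative paths resolve against the file."""
    path = Path(path)
    base = path.parent
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    exp = raw.get("experiment", raw)

    registry_path = exp.get("registry")
    registry = load_registry(base / registry_path if registry_path else None)
    form_spec = exp.get("formulation")
    if isinstance(form_spec, str):
        formulation = load_formulation(base / form_spec, registry)
    elif isinstance(form_spec, dict):
        formulation = formulation_from_dict(form_spec, registry)
    else:
        raise ValidationError(
            f"{path}: 'formulation' must be a table or a file path")

    if "dls_csv" in exp:
        diameter, pdi = read_dls_csv(base / exp["dls_csv"])
    else:
        diameter = float(exp["diameter_nm"])
        pdi = exp.get("pdi")

    analysis = AnalysisOptions(**exp.get("analysis", {}))
    out = exp.get("output_dir")
    return ExperimentConfig(
        name=str(exp.get("name", path.stem)),
        sample_csv=base / exp["sample_csv"],
        titrant_molarity=float(exp["titrant_molarity"]),
        ph9_titrant_volume_ml=float(exp.get("ph9_titrant_volume_ml", 0.0)),
        formulation=formulation,
        diameter_nm=diameter,
        pdi=pdi,
        blank_csv=base / exp["blank_csv"] if "blank_csv" in exp else None,
        blank_titrant_molarity=float(
            exp.get("blank_titrant_molarity", exp["titrant_molarity"])),
        blank_ph9_titrant_volume_ml=float(
            exp.get("blank_ph9_titrant_volume_ml", 0.0)),
        analysis=analysis,
        output_dir=base / out if out else None)


def _sig6(x: float) -> float:
    return float(f"{x:.6g}")


def _report_floats(d: dict) -> dict:
    """6-significant-digit copies alongside full-precision values."""
    out = {}
    for key, value in d.items():
        out[key] = value
        if isinstance(value, float):
            out[key] = _sig6(value)
            out[key + "_full"] = value
    return out


def run_pipeline(config: ExperimentConfig) -> dict:
    """Run the complete analysis for one experiment.

    Returns a report dict with the corrected curve summary, the ILR record,
    the mechanistic fit, and their comparison; if ``config.output_dir`` is
    set, also writes release_curve.csv (+ provenance), ilr.json,
    mechanistic.json and summary.txt there.
    """
    log.info("stage=read sample=%s blank=%s", config.sample_csv,
             config.blank_csv)
    sample = read_titration_csv(
        config.sample_csv, titrant_molarity=config.titrant_molarity,
        ph9_titrant_volume_ml=config.ph9_titrant_volume_ml,
        label=config.name)
    blank = None
    if config.blank_csv is not None:
        blank = read_titration_csv(
            config.blank_csv,
            titrant_molarity=config.blank_titrant_molarity,
            ph9_titrant_volume_ml=config.blank_ph9_titrant_volume_ml,
            label=config.name + "_blank")

    curve = process_record(sample, blank)
    log.info("stage=corrections ionization_scale=%.6g blank=%s",
             curve.corrections.get("ionization_scale", 1.0), blank is not None)

    theo_umol = theoretical_fa_release(config.formulation) * 1e3
    rate = segment_curve(
        curve, window_points=config.analysis.window_points,
        smoothing_points=config.analysis.smoothing_points,
        lag_method=config.analysis.lag_method,
        theoretical_fa_umol=theo_umol)
    log.info("stage=segment k=%.6g umol/min lag=%s window=%s",
             rate.k_umol_min, rate.lag_time_min, rate.k_window)

    density = formulation_density(config.formulation)
    droplets = DropletPopulation(
        hydrodynamic_diameter_nm=config.diameter_nm,
        lipid_mass_g=config.formulation.lipid_mass_g,
        lipid_density_g_cm3=density, pdi=config.pdi)
    area = total_surface_area(droplets)
    ilr = compute_ilr(rate, area, formulation_ref=config.formulation.name)
    log.info("stage=ilr area=%.6g cm2 ilr=%.6g umol/min/cm2", area, ilr.ilr)

    fractions = config.formulation.mole_fractions()
    molar_mass = sum(x * lipid.molar_mass for (lipid, _), x
                     in zip(config.formulation.components, fractions))
    fit = fit_release_curve(
        curve, theoretical_fa_umol=theo_umol,
        molar_mass_kg_mol=molar_mass * 1e-3,
        d0_m=config.diameter_nm * M_PER_NM,
        rho0_kg_m3=density * 1e3)
    log.info("stage=mechanistic phi_max=%.6g k=%.6g mol/s/m2 rmse=%.3g",
             fit.params.phi_max, fit.params.k_mol_s_m2, fit.rmse)

    report = {
        "name": config.name,
        "ilr": ilr_record(ilr),
        "mechanistic": mechanistic_record(fit),
        "comparison": _report_floats(compare_rate_constants(ilr, fit)),
        "corrections": {k: v for k, v in curve.corrections.items()},
        "warnings": list(curve.warnings),
    }

    if config.output_dir is not None:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_release_csv(curve, outdir / "release_curve.csv")
        _write_json(outdir / "ilr.json", report["ilr"])
        _write_json(outdir / "mechanistic.json", report["mechanistic"])
        (outdir / "summary.txt").write_text(summary_text(report))
    return report


def ilr_record(ilr: IlrResult) -> dict:
    rec = {
        "formulation": ilr.formulation_ref,
        "k_umol_per_min": ilr.k_umol_min,
        "area_cm2": ilr.area_cm2,
        "ilr_umol_min_cm2": ilr.ilr,
        "ilr_display_e3": ilr.ilr_display,
        "lag_min": ilr.lag_time_min,
        "extent_fraction": ilr.extent_fraction,
    }
    if ilr.replicate_stats is not None:
        rec["replicate_mean"], rec["replicate_sd"] = ilr.replicate_stats
    return _report_floats(rec)


def mechanistic_record(fit: MechanisticFit) -> dict:
    return _report_floats({
        "phi_max": fit.params.phi_max,
        "k_mol_s_m2": fit.params.k_mol_s_m2,
        "k_display_e3": fit.k_display,
        "rmse": fit.rmse,
        "converged": fit.converged,
        "identifiable": fit.identifiable,
        "n_points": fit.n_points,
        "d0_m": fit.params.d0_m,
        "M_kg_mol": fit.params.molar_mass_kg_mol,
        "rho0_kg_m3": fit.params.rho0_kg_m3,
    })


def summary_text(report: dict) -> str:
    i, m = report["ilr"], report["mechanistic"]
    lines = [
        f"experiment: {report['name']}",
        f"  k (max-rate slope)    : {i['k_umol_per_min']} umol/min",
        f"  droplet surface area  : {i['area_cm2']} cm2",
        f"  ILR                   : {i['ilr_display_e3']} x1e-3 umol/min/cm2",
        f"  lag time              : {i['lag_min']} min",
        f"  extent of digestion   : {i['extent_fraction']}",
        f"  mechanistic phi_max   : {m['phi_max']}",
        f"  mechanistic k         : {m['k_display_e3']} x1e-3 umol/min/cm2",
        f"  fit rmse (fraction)   : {m['rmse']}",
    ]
    return "\n".join(lines) + "\n"


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True,
                               default=str) + "\n")


def predict_for_formulation(pure_ilrs: dict[str, float],
                            formulation: Formulation,
                            experimental_ilr: float | None = None,
                            denominator: str = "predicted") -> MixPrediction:
    """Mixing-rule prediction for a formulation from pure-component ILRs.

    ``pure_ilrs`` maps lipid names to ILRs (base µmol·min⁻¹·cm⁻² units);
    every component of the formulation must be present.
    """
    from .ilr import deviation_report  # local to avoid cycle in docs builds

    missing = [lipid.name for lipid, _ in formulation.components
               if lipid.name not in pure_ilrs]
    if missing:
        raise ValidationError(f"no pure-component ILR for: {missing}")
    fractions = fa_molar_fractions(formulation)
    prediction = predict_mixed_ilr(
        [(lipid.name, x, pure_ilrs[lipid.name])
         for (lipid, _), x in zip(formulation.components, fractions)])
    if experimental_ilr is not None:
        prediction = deviation_report(prediction, experimental_ilr,
                                      denominator=denominator)
    return prediction
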