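"""Synthetic pH-stat experiment generator with known ground truth.

Generates complete, pipeline-ready experiments — sample and blank titration
records, a droplet population, and a ground-truth record — so every
analysis stage can be tested without wet-lab data.  The forward model for
the fatty-acid release is the shrinking-droplet curve, time-shifted by a
lag (the lag phase is an input here, a pure delay, not a mechanistic
surfactant-displacement model):

    FA(t) = n_total · Φ_max · (1 − max{0, 1 − g·(t − lag)}³),  t ≥ lag

which reproduces the triphasic shape of real pH-stat records: flat lag,
maximum-rate phase with initial slope 3·Φ_max·g·n_total, plateau.  The
ionized fraction is constant over the run by construction, mirroring the
back-titration correction's own assumption, so that correction is exact on
synthetic data.  The medium blank digests linearly and slowly.  Titration
noise is additive Gaussian on the titrant volume (a seeded random walk),
monotonized by cumulative maximum so generated records always validate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ValidationError
from .geometry import (DropletPopulation, mixture_density,
                       mixture_density_mag_rule, total_surface_area)
from .registry import (Formulation, LipidRegistry, fa_molar_fractions,
                       load_registry, theoretical_fa_release)
from .titration import TitrationRecord
from .units import M_PER_NM, S_PER_MIN
from .datasets import reported_nanoemulsion_table


def formulation_density(formulation: Formulation) -> float:
    """Density convention used for the dispersed acylglycerol phase, g/cm³.

    Single component: its own density.  Binary tri-/diacylglycerol +
    1-monoacylglycerol with ≤ 10% of fatty acids from the mono component:
    the main component's density.  Otherwise ideal molar-volume mixing.
    """
    comps = formulation.components
    if len(comps) == 1:
        return comps[0][0].density
    classes = [lipid.esterification_class for lipid, _ in comps]
    if len(comps) == 2 and "mono" in classes and classes.count("mono") == 1:
        mono_idx = classes.index("mono")
        fa = fa_molar_fractions(formulation)
        if fa[mono_idx] <= 0.10:
            return mixture_density_mag_rule(
                comps[1 - mono_idx][0], comps[mono_idx][0], fa[mono_idx])
    fractions = formulation.mole_fractions()
    return mixture_density(
        [(lipid, x) for (lipid, _), x in zip(comps, fractions)])


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic pH-stat experiment.

    Exactly one of ``ground_truth_ilr`` (µmol·min⁻¹·cm⁻², base scale) or
    ``mechanistic`` ((Φ_max, k in mol·s⁻¹·m⁻²)) must be given.  Defaults
    mirror the study protocol: 90 min runs, 0.6 M titrant (0.2 M for the
    blank), a short ~1 min lag, and autotitrator-rate sampling.
    """

    formulation: Formulation
    diameter_nm: float
    ground_truth_ilr: float | None = None
    mechanistic: tuple[float, float] | None = None
    lag_min: float = 1.0
    ionized_fraction: float = 0.8
    blank_rate_umol_min: float | None = None  # None → 1% of sample max rate
    noise_sd_umol: float = 1.0
    titrant_molarity: float = 0.6
    blank_titrant_molarity: float = 0.2
    duration_min: float = 90.0
    sampling_interval_min: float = 0.01
    pdi: float = 0.25
    seed: int | None = None
    label: str = "synthetic"

    def __post_init__(self) -> None:
        if (self.ground_truth_ilr is None) == (self.mechanistic is None):
            raise ValidationError(
                "give exactly one of ground_truth_ilr or mechanistic")
        if not 0 < self.ionized_fraction <= 1:
            raise ValidationError("ionized_fraction must be in (0, 1]")
        if self.noise_sd_umol > 0 and self.seed is None:
            raise ValidationError("a seed is mandatory when noise_sd > 0")
        for attr in ("diameter_nm", "titrant_molarity",
                     "blank_titrant_molarity", "duration_min",
                     "sampling_interval_min"):
            if getattr(self, attr) <= 0:
                raise ValidationError(f"{attr} must be > 0")
        for attr in ("lag_min", "noise_sd_umol"):
            if getattr(self, attr) < 0:
                raise ValidationError(f"{attr} must be >= 0")


@dataclass(frozen=True)
class SyntheticExperiment:
    """Generated experiment bundle: what the lab bench would hand over,
    plus the ground truth it cannot."""

    sample: TitrationRecord
    blank: TitrationRecord
    droplets: DropletPopulation
    ground_truth: dict
    config: SyntheticConfig


def _noisy_volume(volume_ml: np.ndarray, sd_ml: float,
                  rng: np.random.Generator) -> np.ndarray:
    if sd_ml == 0:
        return volume_ml
    increments = rng.normal(0.0, sd_ml, size=volume_ml.size)
    increments[0] = 0.0
    return np.maximum.accumulate(volume_ml + np.cumsum(increments))


def generate_experiment(config: SyntheticConfig) -> SyntheticExperiment:
    """Generate one synthetic pH-stat experiment from known ground truth."""
    formulation = config.formulation
    n_total_umol = theoretical_fa_release(formulation) * 1e3
    if n_total_umol <= 0:
        raise ValidationError("formulation releases no fatty acids")
    density = formulation_density(formulation)
    droplets = DropletPopulation(
        hydrodynamic_diameter_nm=config.diameter_nm,
        lipid_mass_g=formulation.lipid_mass_g,
        lipid_density_g_cm3=density, pdi=config.pdi)
    area_cm2 = total_surface_area(droplets)

    if config.ground_truth_ilr is not None:
        phi_max = 1.0
        k_umol_min = config.ground_truth_ilr * area_cm2
        g_per_min = k_umol_min / (3.0 * phi_max * n_total_umol)
        k_mol_s_m2 = None
    else:
        phi_max, k_mol_s_m2 = config.mechanistic
        fractions = formulation.mole_fractions()
        molar_mass = sum(x * lipid.molar_mass for (lipid, _), x
                         in zip(formulation.components, fractions))
        g_per_s = (k_mol_s_m2 * molar_mass * 1e-3
                   / (config.diameter_nm * M_PER_NM * density * 1e3))
        g_per_min = g_per_s * S_PER_MIN
        k_umol_min = 3.0 * phi_max * g_per_min * n_total_umol

    ilr_true = k_umol_min / area_cm2
    blank_rate = (config.blank_rate_umol_min
                  if config.blank_rate_umol_min is not None
                  else 0.01 * k_umol_min)

    n_pts = int(round(config.duration_min / config.sampling_interval_min)) + 1
    t = np.arange(n_pts) * config.sampling_interval_min
    shifted = np.maximum(0.0, t - config.lag_min)
    core = np.maximum(0.0, 1.0 - g_per_min * shifted)
    total_fa = n_total_umol * phi_max * (1.0 - core ** 3)
    blank_fa = blank_rate * t
    f = config.ionized_fraction

    rng = np.random.default_rng(config.seed)
    records = []
    for label, fa, molarity in (
            (config.label, total_fa + blank_fa, config.titrant_molarity),
            (config.label + "_blank", blank_fa,
             config.blank_titrant_molarity)):
        ionized = f * fa
        volume = ionized / (molarity * 1e3)
        sd_ml = config.noise_sd_umol / (molarity * 1e3)
        volume = _noisy_volume(volume, sd_ml, rng)
        ph9_ml = float((1.0 - f) / f * ionized[-1] / (molarity * 1e3))
        records.append(TitrationRecord(
            times_min=t, cumulative_volume_ml=volume,
            titrant_molarity=molarity, ph9_titrant_volume_ml=ph9_ml,
            label=label))

    ground_truth = {
        "ilr_umol_min_cm2": ilr_true,
        "k_umol_min": k_umol_min,
        "area_cm2": area_cm2,
        "rate_group_per_min": g_per_min,
        "phi_max": phi_max,
        "k_mol_s_m2": k_mol_s_m2,
        "lag_min": config.lag_min,
        "theoretical_fa_umol": n_total_umol,
        "diameter_nm": config.diameter_nm,
        "density_g_cm3": density,
        "ionized_fraction": f,
        "blank_rate_umol_min": blank_rate,
    }
    return SyntheticExperiment(sample=records[0], blank=records[1],
                               droplets=droplets, ground_truth=ground_truth,
                               config=config)


def generate_study_panel(seed: int, registry: LipidRegistry | None = None,
                         names: list[str] | None = None,
                         **overrides) -> dict[str, SyntheticExperiment]:
    """Synthetic experiments shaped like the published nanoemulsion panel.

    One experiment per reported row (or per requested ``names``), using the
    row's printed diameter and its printed ILR as ground truth, at the
    row's composition.  Per-row seeds are spawned deterministically from
    ``seed``.  ``overrides`` are forwarded to every SyntheticConfig.
    """
    if registry is None:
        registry = load_registry()
    table = reported_nanoemulsion_table()
    if names is None:
        names = list(table.index)
    missing_rows = [n for n in names if n not in table.index]
    if missing_rows:
        raise ValidationError(f"unknown panel rows: {missing_rows}")
    needed = {lipid for n in names for lipid in table.loc[n, "lipids"]}
    missing = sorted(needed - set(registry))
    if missing:
        raise ValidationError(f"registry is missing lipids: {missing}")

    child_seeds = np.random.SeedSequence(seed).generate_state(len(names))
    panel: dict[str, SyntheticExperiment] = {}
    for name, row_seed in zip(names, child_seeds):
        row = table.loc[name]
        formulation = Formulation(
            components=tuple((registry[lipid], conc) for lipid, conc
                             in zip(row.lipids, row.conc_mm)),
            volume_ml=20.0,
            surfactant_mass_fraction=row.surfactant_pct,
            name=name)
        config = SyntheticConfig(
            formulation=formulation,
            diameter_nm=float(row.diameter_nm),
            ground_truth_ilr=row.ilr_e3 * 1e-3,
            seed=int(row_seed % 2**31),
            label=name,
            **overrides)
        panel[name] = generate_experiment(config)
    return panel
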