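"""Droplet surface-area bookkeeping.

The lipolysis rate constant k (µmol/min) scales with the lipid–water
interfacial area, so normalising by the total pre-digestion droplet surface
area A yields a size-independent intrinsic rate.  A is obtained by treating
the DLS z-average hydrodynamic diameter as the diameter of monodisperse
spheres:

    V_lipid = m / ρ                    total acylglycerol volume
    V_droplet = 4πr³/3,  SA = 4πr²     per-droplet volume and area
    n = V_lipid / V_droplet
    A = n · SA  =  6 m / (ρ d)         closed form

The polydispersity index is carried for QC only (a warning is attached
above 0.3, the usual monodispersity bound); no size distribution is
modelled, and A is fixed at its pre-digestion value — droplet shrinkage
during the run belongs to the mechanistic model, not here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .errors import ValidationError
from .registry import LipidSpec
from .units import NM_PER_CM

PDI_WARN_THRESHOLD = 0.3


@dataclass(frozen=True)
class DropletPopulation:
    """Monodisperse-sphere description of a nanoemulsion.

    hydrodynamic_diameter_nm: DLS z-average; lipid_mass_g and
    lipid_density_g_cm3 set the total dispersed volume.
    """

    hydrodynamic_diameter_nm: float
    lipid_mass_g: float
    lipid_density_g_cm3: float
    pdi: float | None = None

    def __post_init__(self) -> None:
        if self.hydrodynamic_diameter_nm <= 0:
            raise ValidationError("droplet diameter must be > 0")
        if self.lipid_mass_g < 0:
            raise ValidationError("lipid mass must be >= 0")
        if self.lipid_density_g_cm3 <= 0:
            raise ValidationError("lipid density must be > 0")
        if self.pdi is not None and self.pdi > PDI_WARN_THRESHOLD:
            warnings.warn(
                f"PDI {self.pdi:.3f} exceeds {PDI_WARN_THRESHOLD}; the "
                "monodisperse-sphere area estimate may be unreliable",
                stacklevel=2)

    @property
    def radius_cm(self) -> float:
        return self.hydrodynamic_diameter_nm / 2.0 / NM_PER_CM

    @property
    def lipid_volume_cm3(self) -> float:
        return self.lipid_mass_g / self.lipid_density_g_cm3

    @property
    def droplet_volume_cm3(self) -> float:
        return 4.0 * math.pi * self.radius_cm ** 3 / 3.0

    @property
    def droplet_surface_cm2(self) -> float:
        return 4.0 * math.pi * self.radius_cm ** 2

    @property
    def n_droplets(self) -> float:
        return self.lipid_volume_cm3 / self.droplet_volume_cm3


def total_surface_area(pop: DropletPopulation) -> float:
    """Total lipid–water interfacial area A in cm².

    Computed through the per-droplet chain (n · SA); algebraically equal to
    6m/(ρd).
    """
    return pop.n_droplets * pop.droplet_surface_cm2


def mixture_density(components: list[tuple[LipidSpec, float]],
                    *, rule: str = "molar_volume",
                    tol: float = 1e-6) -> float:
    """Density of an acylglycerol mixture from mole fractions, g/cm³.

    ``rule="molar_volume"`` is ideal mixing read as molar-volume additivity:
    ρ = Σxᵢ·Mᵢ / Σ(xᵢ·Mᵢ/ρᵢ).  ``rule="mass_linear"`` instead averages
    densities linearly by mass fraction; both bound the result by the
    component densities.
    """
    if not components:
        raise ValidationError("mixture_density needs at least one component")
    fractions = [x for _, x in components]
    if any(x < 0 for x in fractions):
        raise ValidationError("mole fractions must be non-negative")
    if abs(sum(fractions) - 1.0) > tol:
        raise ValidationError(
            f"mole fractions must sum to 1 (got {sum(fractions)!r})")
    masses = [x * lipid.molar_mass for (lipid, _), x
              in zip(components, fractions)]
    if rule == "molar_volume":
        volumes = [mass / lipid.density
                   for (lipid, _), mass in zip(components, masses)]
        return sum(masses) / sum(volumes)
    if rule == "mass_linear":
        total_mass = sum(masses)
        return sum(mass / total_mass * lipid.density
                   for (lipid, _), mass in zip(components, masses))
    raise ValidationError(f"unknown mixing rule {rule!r}")


def mixture_density_mag_rule(tri: LipidSpec, mono: LipidSpec,
                             mono_fa_fraction: float,
                             *, threshold: float = 0.10) -> float:
    """Density convention for triacylglycerol + small monoacylglycerol mixes.

    When the monoacylglycerol contributes at most ``threshold`` of the
    fatty acids, the triacylglycerol's density is used unchanged.  Above
    the threshold this falls back to ideal molar-volume mixing (with a
    warning), converting the fatty-acid fractions to mole fractions via
    the per-molecule release counts.
    """
    if not 0 <= mono_fa_fraction <= 1:
        raise ValidationError("mono fatty-acid fraction must be in [0, 1]")
    if mono_fa_fraction <= threshold:
        return tri.density
    warnings.warn(
        f"monoacylglycerol fatty-acid fraction {mono_fa_fraction:.3f} "
        f"exceeds {threshold}; using ideal molar-volume mixing instead of "
        "the triacylglycerol density", stacklevel=2)
    moles_mono = mono_fa_fraction / mono.fa_per_molecule
    moles_tri = (1.0 - mono_fa_fraction) / tri.fa_per_molecule
    total = moles_mono + moles_tri
    return mixture_density([(tri, moles_tri / total),
                            (mono, moles_mono / total)])
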