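"""Acylglycerol property registry and formulation stoichiometry.

An acylglycerol nanoemulsion is described by a :class:`Formulation`: one or
two lipid components at millimolar concentrations in a given aqueous volume,
stabilised by a polysorbate 80 mass fraction.  Pancreatic lipase cleaves the
sn-1 and sn-3 ester bonds, so triacylglycerols and 1,3-diacylglycerols each
release two titratable fatty acids per molecule while 1-monoacylglycerols
release one.  All stoichiometric bookkeeping below (theoretical release,
fatty-acid molar fractions, composition solving) follows from that rule.

Units: concentrations mM, volumes mL, amounts mmol.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import ValidationError

_FA_PER_CLASS = {"mono": 1, "di_1_3": 2, "tri": 2}

_LIPID_FIELDS = {
    "esterification_class", "fa_per_molecule", "acyl_chain_length",
    "double_bonds", "molar_mass", "density", "melting_point", "provenance",
}


@dataclass(frozen=True)
class LipidSpec:
    """Physicochemical record for one pure acylglycerol.

    ``density`` refers to the liquid (or supercooled-melt) state, since
    nanoemulsions prepared by hot ultrasonication remain supercooled melts.
    2-monoacylglycerols can be represented with ``esterification_class="mono"``
    but note that the sn-1(3) isomer is the one whose digestion this
    stoichiometry describes; sn-2 isomers behave differently under pancreatic
    lipase.
    """

    name: str
    esterification_class: str  # "mono" | "di_1_3" | "tri"
    fa_per_molecule: int
    acyl_chain_length: int
    double_bonds: int
    molar_mass: float  # g/mol
    density: float  # g/cm³
    melting_point: float | None = None  # °C, informational
    provenance: str = "user"

    def __post_init__(self) -> None:
        if self.esterification_class not in _FA_PER_CLASS:
            raise ValidationError(
                f"{self.name}: unknown esterification_class "
                f"{self.esterification_class!r}")
        expected = _FA_PER_CLASS[self.esterification_class]
        if self.fa_per_molecule != expected:
            raise ValidationError(
                f"{self.name}: esterification_class "
                f"{self.esterification_class!r} releases {expected} fatty "
                f"acid(s) per molecule, got fa_per_molecule="
                f"{self.fa_per_molecule}")
        if self.molar_mass <= 0:
            raise ValidationError(f"{self.name}: molar_mass must be > 0")
        if self.density <= 0:
            raise ValidationError(f"{self.name}: density must be > 0")
        if self.acyl_chain_length <= 0 or self.double_bonds < 0:
            raise ValidationError(f"{self.name}: invalid acyl chain fields")


@dataclass(frozen=True)
class Formulation:
    """Nanoemulsion composition: (lipid, concentration mM) pairs in a volume.

    ``surfactant_mass_fraction`` is the polysorbate 80 level in % w/w during
    lipolysis; it takes no part in stoichiometry but ILRs are only comparable
    between formulations at matched surfactant level.
    """

    components: tuple[tuple[LipidSpec, float], ...]
    volume_ml: float
    surfactant_mass_fraction: float = 0.25
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", tuple(
            (lipid, float(conc)) for lipid, conc in self.components))
        if self.volume_ml <= 0:
            raise ValidationError("formulation volume must be > 0")
        if self.surfactant_mass_fraction < 0:
            raise ValidationError("surfactant fraction must be >= 0")
        for lipid, conc in self.components:
            if conc < 0:
                raise ValidationError(
                    f"negative concentration for {lipid.name}: {conc} mM")

    @property
    def lipid_mass_g(self) -> float:
        """Total acylglycerol mass: Σ cᵢ·V·Mᵢ (mmol × g/mol → mg → g)."""
        return sum(conc * self.volume_ml / 1e3 * lipid.molar_mass / 1e3
                   for lipid, conc in self.components)

    def mole_fractions(self) -> tuple[float, ...]:
        """Acylglycerol (not fatty-acid) mole fractions of the components."""
        moles = [conc for _, conc in self.components]
        total = sum(moles)
        if total <= 0:
            raise ValidationError("all-zero formulation has no mole fractions")
        return tuple(m / total for m in moles)


def theoretical_fa_release(formulation: Formulation) -> float:
    """Theoretical fatty-acid release on complete digestion, in mmol.

    Σᵢ cᵢ·V·faᵢ over components.  The study formulations were all composed
    to yield 5 mmol (e.g. 125 mM triacylglycerol in 20 mL).
    """
    return sum(conc * formulation.volume_ml / 1e3 * lipid.fa_per_molecule
               for lipid, conc in formulation.components)


def fa_molar_fractions(formulation: Formulation) -> tuple[float, ...]:
    """Fatty-acid molar fraction xᵢ of each component.

    xᵢ = (theoretical fatty acids from component i) / (total theoretical
    fatty acids); the weights of the linear ILR mixing rule.
    """
    total = theoretical_fa_release(formulation)
    if total <= 0:
        raise ValidationError(
            "fatty-acid fractions undefined for a zero-release formulation")
    return tuple(conc * formulation.volume_ml / 1e3 * lipid.fa_per_molecule
                 / total for lipid, conc in formulation.components)


def solve_composition(lipid_a: LipidSpec, lipid_b: LipidSpec,
                      fa_ratio_a_to_b: tuple[float, float],
                      target_fa_mmol: float, volume_ml: float,
                      surfactant_mass_fraction: float = 0.25,
                      name: str = "") -> Formulation:
    """Solve component concentrations for a binary formulation.

    Given a target fatty-acid ratio a:b and a total theoretical release,
    returns the Formulation whose ``fa_molar_fractions`` equal the ratio and
    whose ``theoretical_fa_release`` equals the target.  A zero ratio term
    degenerates to a single-component formulation.
    """
    ra, rb = (float(x) for x in fa_ratio_a_to_b)
    if ra < 0 or rb < 0 or ra + rb == 0:
        raise ValidationError("ratio terms must be non-negative, not both 0")
    if target_fa_mmol <= 0:
        raise ValidationError("target fatty-acid amount must be > 0")
    if volume_ml <= 0:
        raise ValidationError("volume must be > 0")
    fa_a = target_fa_mmol * ra / (ra + rb)
    fa_b = target_fa_mmol * rb / (ra + rb)
    conc_a = fa_a * 1e3 / (volume_ml * lipid_a.fa_per_molecule)
    conc_b = fa_b * 1e3 / (volume_ml * lipid_b.fa_per_molecule)
    components: list[tuple[LipidSpec, float]] = []
    if conc_a > 0:
        components.append((lipid_a, conc_a))
    if conc_b > 0:
        components.append((lipid_b, conc_b))
    return Formulation(tuple(components), volume_ml,
                       surfactant_mass_fraction, name)


# ---------------------------------------------------------------------------
# Registry / formulation file I/O (TOML)

class LipidRegistry(Mapping[str, LipidSpec]):
    """Name-keyed collection of :class:`LipidSpec` records."""

    def __init__(self, lipids: Iterable[LipidSpec]):
        self._lipids = {lipid.name: lipid for lipid in lipids}

    def __getitem__(self, name: str) -> LipidSpec:
        try:
            return self._lipids[name]
        except KeyError:
            raise ValidationError(
                f"lipid {name!r} not in registry; available: "
                f"{sorted(self._lipids)}") from None

    def __iter__(self):
        return iter(self._lipids)

    def __len__(self) -> int:
        return len(self._lipids)


def load_registry(path: str | Path | None = None) -> LipidRegistry:
    """Load a lipid registry from a TOML file.

    With no path, the packaged registry of the nine study acylglycerols is
    used.  Its molar masses are computed from molecular formulae; densities
    and melting points are placeholder literature-typical values (flagged
    ``provenance = "placeholder"``) that users should override with their
    own measured or supplier data for quantitative work.
    """
    if path is None:
        data = tomllib.loads(
            resources.files("ilrkit.data").joinpath("lipids.toml")
            .read_text())
    else:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    lipids = []
    for name, fields in data.items():
        unknown = set(fields) - _LIPID_FIELDS
        if unknown:
            raise ValidationError(
                f"registry entry {name!r} has unknown keys: {sorted(unknown)}")
        lipids.append(LipidSpec(name=name, **fields))
    return LipidRegistry(lipids)


def load_formulation(path: str | Path, registry: LipidRegistry) -> Formulation:
    """Load a formulation TOML referencing registry entries by name."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    return formulation_from_dict(data.get("formulation", data), registry)


def formulation_from_dict(spec: Mapping, registry: LipidRegistry) -> Formulation:
    allowed = {"name", "volume_ml", "surfactant_mass_fraction", "components"}
    unknown = set(spec) - allowed
    if unknown:
        raise ValidationError(f"formulation has unknown keys: {sorted(unknown)}")
    try:
        components = tuple((registry[name], float(conc))
                           for name, conc in spec["components"])
        return Formulation(
            components=components,
            volume_ml=float(spec["volume_ml"]),
            surfactant_mass_fraction=float(
                spec.get("surfactant_mass_fraction", 0.25)),
            name=str(spec.get("name", "")),
        )
    except KeyError as exc:
        raise ValidationError(f"formulation missing key: {exc}") from None
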