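"""Monomer-level PHA quantification from GC peak tables.

Methanolysed polyester samples are run on GC with 3-methylbenzoic acid
as internal standard (IS); monomer methyl-ester peak areas are converted
to masses by single-point IS calibration, then expressed as polymer
repeat-unit equivalents: mol% composition, PHA content as % of the
sample dry mass, mean repeat-unit mass, and the PHA carbon term for the
culture-level carbon balance.

Monomers are the 3-hydroxyacyl repeat units C6/C8/C10 with repeat-unit
formula CnH(2n-2)O2 (114.14, 142.20, 170.25 g/mol).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

__all__ = [
    "REPEAT_UNIT_MASS",
    "CARBON_ATOMS",
    "INTERNAL_STANDARD",
    "GcRun",
    "MonomerComposition",
    "quantify_monomers",
    "composition",
    "composition_from_molpercent",
    "pha_carbon",
]

#: Polymer repeat-unit molar masses, g/mol (C6H10O2 / C8H14O2 / C10H18O2).
REPEAT_UNIT_MASS: dict[str, float] = {"C6": 114.14, "C8": 142.20, "C10": 170.25}

#: Carbon atoms per repeat unit.
CARBON_ATOMS: dict[str, int] = {"C6": 6, "C8": 8, "C10": 10}

#: Peak label reserved for the internal standard.
INTERNAL_STANDARD = "IS"


@dataclass(frozen=True)
class GcRun:
    """One GC run: peak areas keyed by monomer (plus the IS peak).

    ``internal_standard_mass`` is the IS mass spiked into the sample in
    mg; ``sample_dry_mass`` the lyophilised sample mass in mg.
    ``response_factors`` rescale monomer areas relative to the IS
    (default 1.0 for every monomer).
    """

    areas: Mapping[str, float]
    internal_standard_mass: float
    sample_dry_mass: float
    response_factors: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.areas.values()):
            raise ValueError("peak areas must be >= 0")
        if INTERNAL_STANDARD not in self.areas:
            raise ValueError("GC run is missing the internal-standard peak")
        if self.sample_dry_mass <= 0:
            raise ValueError("sample dry mass must be > 0")


@dataclass(frozen=True)
class MonomerComposition:
    """Monomer mol% composition with derived polymer-level quantities.

    ``pha_content`` is the PHA mass as percent of sample dry mass (None
    when the composition was built from mol% alone);
    ``mean_repeat_mass`` is the mol-fraction-weighted repeat-unit molar
    mass in g/mol.
    """

    mol_percent: Mapping[str, float]
    mean_repeat_mass: float
    pha_content: float | None = None

    def __post_init__(self) -> None:
        total = sum(self.mol_percent.values())
        if abs(total - 100.0) > 0.5:
            raise ValueError(
                f"monomer mol% must sum to 100 +- 0.5, got {total:.2f}"
            )
        if self.pha_content is not None and not 0 <= self.pha_content <= 100:
            raise ValueError("PHA content must be in [0, 100] % of CDW")

    @property
    def mol_fraction(self) -> dict[str, float]:
        return {m: p / 100.0 for m, p in self.mol_percent.items()}

    @property
    def mean_carbon_number(self) -> float:
        """Mol-fraction-weighted carbon atoms per repeat unit."""
        return sum(
            frac * CARBON_ATOMS[m] for m, frac in self.mol_fraction.items()
        )


def quantify_monomers(run: GcRun) -> dict[str, float]:
    """Monomer masses (mg) by single-point internal-standard calibration.

    ``mass_m = area_m / area_IS * m_IS * rf_m``.
    """
    is_area = run.areas[INTERNAL_STANDARD]
    if is_area <= 0:
        raise ValueError("internal-standard peak area must be > 0")
    rf = run.response_factors or {}
    return {
        monomer: area / is_area * run.internal_standard_mass * rf.get(monomer, 1.0)
        for monomer, area in run.areas.items()
        if monomer != INTERNAL_STANDARD
    }


def composition(
    masses_mg: Mapping[str, float], sample_dry_mass_mg: float
) -> MonomerComposition:
    """Monomer composition and PHA content from monomer masses.

    Masses convert to moles of repeat units; mol% is relative to the
    molar total and PHA content is the mass total as percent of sample
    dry mass.
    """
    if sample_dry_mass_mg <= 0:
        raise ValueError("sample dry mass must be > 0")
    unknown = set(masses_mg) - set(REPEAT_UNIT_MASS)
    if unknown:
        raise ValueError(f"unknown monomer(s): {sorted(unknown)}")
    moles = {m: mass / REPEAT_UNIT_MASS[m] for m, mass in masses_mg.items()}
    total_mol = sum(moles.values())
    if total_mol <= 0:
        raise ValueError("all monomer masses are zero")
    mol_percent = {m: 100.0 * n / total_mol for m, n in moles.items()}
    mean_mass = sum(
        (p / 100.0) * REPEAT_UNIT_MASS[m] for m, p in mol_percent.items()
    )
    content = 100.0 * sum(masses_mg.values()) / sample_dry_mass_mg
    return MonomerComposition(
        mol_percent=mol_percent,
        mean_repeat_mass=mean_mass,
        pha_content=content,
    )


def composition_from_molpercent(
    mol_percent: Mapping[str, float],
) -> MonomerComposition:
    """Composition object from a reported mol% breakdown (no content)."""
    unknown = set(mol_percent) - set(REPEAT_UNIT_MASS)
    if unknown:
        raise ValueError(f"unknown monomer(s): {sorted(unknown)}")
    mean_mass = sum(
        (p / 100.0) * REPEAT_UNIT_MASS[m] for m, p in mol_percent.items()
    )
    return MonomerComposition(
        mol_percent=dict(mol_percent), mean_repeat_mass=mean_mass
    )


def pha_carbon(comp: MonomerComposition, pha_mass_g_per_l: float) -> float:
    """Carbon bound in PHA, C-mol per liter.

    ``(m_PHA / mean repeat mass) * mean carbon number``; linear in the
    PHA mass.
    """
    if pha_mass_g_per_l < 0:
        raise ValueError("PHA mass must be >= 0")
    return pha_mass_g_per_l / comp.mean_repeat_mass * comp.mean_carbon_number
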