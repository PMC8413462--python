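"""Theoretical average masses of proteins, RNAs and RNP assemblies.

Residue masses are average (not monoisotopic) values from the IUPAC 2021
atomic weights; a linear polymer weighs the sum of its residue masses plus
one water.  For RNA the residue masses are nucleoside-monophosphate
residues, so the base formula corresponds to a 5'-phosphorylated chain;
the ``triphosphate`` option adds the two extra phosphate groups of a
5'-ppp T7 transcript (~0.16 kDa, below the reporting precision of SEC-MALS
masses).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

MASS_TABLE_VERSION = "avg-iupac-2021"

WATER = 18.0153
HPO3 = 79.9799  # one phosphate group (metaphosphate unit)

#: average amino-acid residue masses (Da)
PROTEIN_RESIDUES = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}

#: average ribonucleotide residue masses (Da, NMP − water)
RNA_RESIDUES = {"A": 329.2059, "C": 305.1808, "G": 345.2053, "U": 306.1653}


def polymer_mass(sequence: str, kind: str, five_prime: str = "OH") -> float:
    """Average mass (Da) of a protein or RNA sequence.

    ``five_prime`` applies to RNA only: "OH" gives the base convention,
    "triphosphate" adds 2 × HPO3 for a 5'-ppp transcript.
    """
    if kind not in ("protein", "rna"):
        raise ValueError(f"kind must be 'protein' or 'rna', got {kind!r}")
    if not sequence:
        raise ValueError("empty sequence")
    table = PROTEIN_RESIDUES if kind == "protein" else RNA_RESIDUES
    seq = sequence.upper()
    if kind == "rna":
        seq = seq.replace("T", "U")
    mass = WATER
    for i, c in enumerate(seq):
        if c not in table:
            raise ValueError(f"illegal {kind} residue {c!r} at position {i + 1} (1-based)")
        mass += table[c]
    if kind == "rna" and five_prime == "triphosphate":
        mass += 2 * HPO3
    elif kind == "rna" and five_prime != "OH":
        raise ValueError(f"five_prime must be 'OH' or 'triphosphate', got {five_prime!r}")
    return mass


@dataclass
class Component:
    """One protein or RNA component of an assembly."""

    name: str
    kind: str  # "protein" or "rna"
    sequence: Optional[str] = None
    mass: Optional[float] = None  # Da; computed from sequence when absent
    monomer_mass_table_version: str = MASS_TABLE_VERSION

    def __post_init__(self) -> None:
        if self.mass is None:
            if self.sequence is None:
                raise ValueError(f"component {self.name!r}: need a sequence or a mass")
            self.mass = polymer_mass(self.sequence, self.kind)
        if self.mass <= 0:
            raise ValueError(f"component {self.name!r}: mass must be positive")


@dataclass
class AssemblyModel:
    """A stoichiometry hypothesis: copies of each component."""

    name: str
    stoichiometry: list[tuple[Component, int]]
    delta_to_observed: Optional[float] = None  # Da, filled by ranking

    def __post_init__(self) -> None:
        for comp, copies in self.stoichiometry:
            if copies < 1:
                raise ValueError(f"model {self.name!r}: copy number for "
                                 f"{comp.name!r} must be >= 1, got {copies}")

    @property
    def mass(self) -> float:
        return assembly_mass(self)

    @property
    def mass_kda(self) -> float:
        return round(self.mass / 1000.0, 1)

    @classmethod
    def from_total_mass(cls, name: str, mass_kda: float) -> "AssemblyModel":
        """Model defined directly by a stated total mass (kDa)."""
        comp = Component(name=name, kind="rna", sequence=None, mass=mass_kda * 1000.0)
        comp.kind = "assembly"
        return cls(name=name, stoichiometry=[(comp, 1)])


def assembly_mass(model: AssemblyModel) -> float:
    """Stoichiometric mass sum in Da (report as kDa to one decimal)."""
    return sum(copies * comp.mass for comp, copies in model.stoichiometry)


def rank_stoichiometries(
    observed_kDa: float, candidates: Sequence[AssemblyModel]
) -> list[AssemblyModel]:
    """Sort candidate models by |mass − observed|; stable on ties.

    Each returned model carries ``delta_to_observed`` in Da.
    """
    if not candidates:
        raise ValueError("need at least one candidate model")
    observed = observed_kDa * 1000.0
    ranked = sorted(candidates, key=lambda m: abs(m.mass - observed))
    for m in ranked:
        m.delta_to_observed = m.mass - observed
    return ranked


def load_stoichiometry_config(
    path: str | Path, components: dict[str, Component]
) -> list[AssemblyModel]:
    """Build assembly models from a YAML mapping: model -> {component: copies}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a mapping of model names to stoichiometries")
    models = []
    for name, stoich in raw.items():
        pairs = []
        for comp_name, copies in stoich.items():
            if comp_name not in components:
                raise ValueError(f"{path}: unknown component {comp_name!r} in model {name!r}")
            pairs.append((components[comp_name], int(copies)))
        models.append(AssemblyModel(name=name, stoichiometry=pairs))
    return models
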