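"""Physical constants for protein physicochemistry.

Average (isotope-abundance-weighted) residue masses and registered pKa
sets for the Henderson-Hasselbalch charge model.  Masses are residue
masses (amino acid minus water); a free water mass is added once per
chain.  pKa sets differ between published calculators, so several named
sets are registered and the active one is a parameter everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

CANONICAL_RESIDUES: str = "ACDEFGHIKLMNPQRSTVWY"

#: Ambiguity codes retained under the default "flag" validation policy.
AMBIGUITY_CODES: str = "XBZUOJ"

# Average residue masses in Da (Expasy/SwissProt convention).
_AVERAGE_RESIDUE_MASS: dict[str, float] = {
    "A": 71.0788,
    "R": 156.1875,
    "N": 114.1038,
    "D": 115.0886,
    "C": 103.1388,
    "E": 129.1155,
    "Q": 128.1307,
    "G": 57.0519,
    "H": 137.1411,
    "I": 113.1594,
    "L": 113.1594,
    "K": 128.1741,
    "M": 131.1926,
    "F": 147.1766,
    "P": 97.1167,
    "S": 87.0782,
    "T": 101.1051,
    "W": 186.2132,
    "Y": 163.1760,
    "V": 99.1326,
}

WATER_MASS: float = 18.01524


@dataclass(frozen=True)
class MassTable:
    """Average residue masses (Da) plus the free-water terminus mass."""

    name: str
    residue_mass: Mapping[str, float]
    water_mass: float = WATER_MASS

    def __post_init__(self) -> None:
        missing = set(CANONICAL_RESIDUES) - set(self.residue_mass)
        if missing:
            raise ValueError(f"mass table {self.name!r} missing residues: {sorted(missing)}")
        if any(m <= 0 for m in self.residue_mass.values()) or self.water_mass <= 0:
            raise ValueError("masses must be strictly positive")
        object.__setattr__(self, "residue_mass", MappingProxyType(dict(self.residue_mass)))


DEFAULT_MASS_TABLE = MassTable("expasy_average", _AVERAGE_RESIDUE_MASS)

#: Mass assigned to each retained ambiguity code: the mean of its
#: plausible substitutes (B = Asn/Asp, Z = Gln/Glu, J = Ile/Leu,
#: X = any residue, U -> Cys, O -> Lys).
AMBIGUITY_MASS_SUBSTITUTES: Mapping[str, str] = MappingProxyType(
    {
        "B": "ND",
        "Z": "QE",
        "J": "IL",
        "X": CANONICAL_RESIDUES,
        "U": "C",
        "O": "K",
    }
)

ACIDIC_GROUPS: tuple[str, ...] = ("cterm", "D", "E", "C", "Y")
BASIC_GROUPS: tuple[str, ...] = ("nterm", "H", "K", "R")
IONIZABLE_SIDE_CHAINS: str = "DECYHKR"


@dataclass(frozen=True)
class PkaSet:
    """Acid-dissociation constants for the ionizable groups of a protein.

    ``side_pka`` covers the seven ionizable side chains (D, E, C, Y
    acidic; H, K, R basic); the chain termini get their own constants.
    """

    name: str
    nterm_pka: float
    cterm_pka: float
    side_pka: Mapping[str, float]

    def __post_init__(self) -> None:
        expected = set(IONIZABLE_SIDE_CHAINS)
        if set(self.side_pka) != expected:
            raise ValueError(
                f"pKa set {self.name!r} must define side chains {sorted(expected)}"
            )
        values = [self.nterm_pka, self.cterm_pka, *self.side_pka.values()]
        if not all(0.0 < v < 14.0 for v in values):
            raise ValueError(f"pKa set {self.name!r} has values outside (0, 14)")
        object.__setattr__(self, "side_pka", MappingProxyType(dict(self.side_pka)))

    def pka(self, group: str) -> float:
        if group == "nterm":
            return self.nterm_pka
        if group == "cterm":
            return self.cterm_pka
        return self.side_pka[group]


# Constants of the IPC 1.0 calculator (Kozlowski 2016), protein and
# peptide optimised sets.
IPC_PROTEIN = PkaSet(
    "ipc_protein",
    nterm_pka=9.094,
    cterm_pka=2.869,
    side_pka={"D": 3.872, "E": 4.412, "C": 7.555, "Y": 10.85, "H": 5.637, "K": 9.052, "R": 11.84},
)

IPC_PEPTIDE = PkaSet(
    "ipc_peptide",
    nterm_pka=9.564,
    cterm_pka=2.383,
    side_pka={"D": 3.887, "E": 4.317, "C": 8.297, "Y": 10.071, "H": 6.018, "K": 10.517, "R": 12.503},
)

# EMBOSS iep defaults.
EMBOSS = PkaSet(
    "emboss",
    nterm_pka=8.6,
    cterm_pka=3.6,
    side_pka={"D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1, "H": 6.5, "K": 10.8, "R": 12.5},
)

# Sillero & Ribeiro (1989).
SILLERO = PkaSet(
    "sillero",
    nterm_pka=8.2,
    cterm_pka=3.2,
    side_pka={"D": 4.0, "E": 4.5, "C": 9.0, "Y": 10.0, "H": 6.4, "K": 10.4, "R": 12.0},
)

PKA_SETS: Mapping[str, PkaSet] = MappingProxyType(
    {s.name: s for s in (IPC_PROTEIN, IPC_PEPTIDE, EMBOSS, SILLERO)}
)

DEFAULT_PKA_SET = IPC_PROTEIN

MASS_TABLES: Mapping[str, MassTable] = MappingProxyType({DEFAULT_MASS_TABLE.name: DEFAULT_MASS_TABLE})


def get_pka_set(name: str | PkaSet) -> PkaSet:
    """Resolve a pKa set by registry name (pass-through for instances)."""
    if isinstance(name, PkaSet):
        return name
    try:
        return PKA_SETS[name]
    except KeyError:
        raise KeyError(f"unknown pKa set {name!r}; registered: {sorted(PKA_SETS)}") from None


def get_mass_table(name: str | MassTable) -> MassTable:
    if isinstance(name, MassTable):
        return name
    try:
        return MASS_TABLES[name]
    except KeyError:
        raise KeyError(f"unknown mass table {name!r}; registered: {sorted(MASS_TABLES)}") from None
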