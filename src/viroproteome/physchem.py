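"""Per-protein physicochemistry: composition, molecular weight, pI.

The isoelectric point follows the bulk-proteome convention: every
ionizable group (the two chain termini and the D/E/C/Y/H/K/R side
chains) is protonated independently according to Henderson-Hasselbalch,

    Z(pH) = sum_basic  n_g / (1 + 10^(pH - pKa_g))
          - sum_acidic n_g / (1 + 10^(pKa_g - pH)),

and pI is the unique root of Z on [0, 14], found by bisection.  Free
cysteine is treated as ionizable (no disulfide modelling) and no
folded-state corrections are applied.  Molecular weight uses average
residue masses plus one water.  Ambiguity codes are excluded from
composition denominators, contribute a substitute-average mass, and
carry no ionizable groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from types import MappingProxyType
from typing import Mapping

from .constants import (
    ACIDIC_GROUPS,
    AMBIGUITY_CODES,
    AMBIGUITY_MASS_SUBSTITUTES,
    BASIC_GROUPS,
    CANONICAL_RESIDUES,
    DEFAULT_MASS_TABLE,
    DEFAULT_PKA_SET,
    IONIZABLE_SIDE_CHAINS,
    MassTable,
    PkaSet,
    get_mass_table,
    get_pka_set,
)
from .io_fasta import ProteinRecord, ValidationError

DEFAULT_PI_TOL = 1e-3

_AMBIGUITY_MASS: Mapping[str, float] = MappingProxyType(
    {
        code: sum(DEFAULT_MASS_TABLE.residue_mass[r] for r in subs) / len(subs)
        for code, subs in AMBIGUITY_MASS_SUBSTITUTES.items()
    }
)


@dataclass(frozen=True)
class CompositionVector:
    """Residue fractions over the canonical residues of one sequence."""

    fraction: Mapping[str, float]
    n_canonical: int
    n_ambiguous: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "fraction", MappingProxyType(dict(self.fraction)))

    def as_list(self) -> list[float]:
        """Fractions in fixed ACDEFGHIKLMNPQRSTVWY order."""
        return [self.fraction[r] for r in CANONICAL_RESIDUES]


@dataclass(frozen=True)
class PhyschemProfile:
    """Length, molecular weight, pI and composition of one protein."""

    id: str
    host_group: str
    length: int
    mw_da: float
    pi: float
    composition: CompositionVector

    @property
    def mw_kda(self) -> float:
        return self.mw_da / 1000.0


def residue_counts(sequence: str) -> dict[str, int]:
    """Counts of every accepted residue code present in ``sequence``."""
    return {
        r: c
        for r in CANONICAL_RESIDUES + AMBIGUITY_CODES
        if (c := sequence.count(r)) > 0
    }


def composition(sequence: str) -> CompositionVector:
    """Residue fractions over canonical residues only.

    Ambiguity codes are counted in ``n_ambiguous`` and excluded from the
    denominator, so fractions always sum to 1 when any canonical residue
    is present.
    """
    counts = residue_counts(sequence)
    n_amb = sum(counts.get(c, 0) for c in AMBIGUITY_CODES)
    n_can = len(sequence) - n_amb
    if n_can == 0:
        raise ValidationError("composition undefined: sequence has no canonical residues")
    fraction = {r: counts.get(r, 0) / n_can for r in CANONICAL_RESIDUES}
    return CompositionVector(fraction=fraction, n_canonical=n_can, n_ambiguous=n_amb)


def molecular_weight(sequence: str, mass_table: str | MassTable = DEFAULT_MASS_TABLE) -> float:
    """Average molecular weight in Da: residue masses plus one water.

    Ambiguity codes contribute the mean mass of their plausible
    substitutes (B = Asn/Asp, Z = Gln/Glu, J = Ile/Leu, X = mean of all
    20, U -> Cys, O -> Lys).
    """
    table = get_mass_table(mass_table)
    if not sequence:
        raise ValidationError("molecular weight undefined for empty sequence")
    total = table.water_mass
    for res, n in residue_counts(sequence).items():
        if res in table.residue_mass:
            total += n * table.residue_mass[res]
        elif res in _AMBIGUITY_MASS:
            total += n * _AMBIGUITY_MASS[res]
        else:
            raise ValidationError(f"residue {res!r} absent from mass table {table.name!r}")
    return total


def ionizable_group_counts(sequence: str) -> dict[str, int]:
    """Counts of ionizable groups: termini plus D/E/C/Y/H/K/R side chains.

    Ambiguity codes contribute no ionizable groups.
    """
    counts = {"nterm": 1, "cterm": 1}
    for res in IONIZABLE_SIDE_CHAINS:
        counts[res] = sequence.count(res)
    return counts


def net_charge(
    ph: float, group_counts: Mapping[str, int], pka_set: str | PkaSet = DEFAULT_PKA_SET
) -> float:
    """Net charge at ``ph`` under Henderson-Hasselbalch protonation."""
    pka = get_pka_set(pka_set)
    charge = 0.0
    for group in BASIC_GROUPS:
        n = group_counts.get(group, 0)
        if n:
            charge += n / (1.0 + 10.0 ** (ph - pka.pka(group)))
    for group in ACIDIC_GROUPS:
        n = group_counts.get(group, 0)
        if n:
            charge -= n / (1.0 + 10.0 ** (pka.pka(group) - ph))
    return charge


def isoelectric_point(
    sequence: str,
    pka_set: str | PkaSet = DEFAULT_PKA_SET,
    tol: float = DEFAULT_PI_TOL,
) -> float:
    """pI of ``sequence``: bisection root of the net charge on [0, 14].

    The charge is strictly decreasing in pH (every term is), positive at
    pH 0 and negative at pH 14, so the root exists and is unique;
    bisection narrows the bracket to width ``tol``.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    pka = get_pka_set(pka_set)
    counts = ionizable_group_counts(sequence)
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(mid, counts, pka) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def profile(
    record: ProteinRecord,
    mass_table: str | MassTable = DEFAULT_MASS_TABLE,
    pka_set: str | PkaSet = DEFAULT_PKA_SET,
    tol: float = DEFAULT_PI_TOL,
) -> PhyschemProfile:
    """Bundle length, composition, MW and pI for one record."""
    try:
        comp = composition(record.sequence)
        mw = molecular_weight(record.sequence, mass_table)
        pi = isoelectric_point(record.sequence, pka_set, tol)
    except (ValidationError, KeyError) as exc:
        raise ValidationError(f"record {record.id!r}: {exc}") from exc
    return PhyschemProfile(
        id=record.id,
        host_group=record.host_group,
        length=len(record.sequence),
        mw_da=mw,
        pi=pi,
        composition=comp,
    )
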