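"""Synthetic host-group proteomes with known ground truth.

Generates protein sequences as i.i.d. draws from per-component residue
frequencies, with right-skewed (discretised log-normal) length
distributions and a 1-, 2- or 3-component mixture structure in pI.
Because every downstream statistic in this package depends only on
composition, length, molecular weight and pI, i.i.d. residue sampling
is a faithful generative model for testing the pipeline; it carries no
positional, phylogenetic or codon-level structure.

The acidic/neutral/basic presets tilt D/E versus K/R (the neutral one
additionally raises Cys and His, whose near-neutral pKa values buffer
the isoelectric point) so that component mean pI lands near 4.6, 7.1
and 10.1 respectively — the classic building blocks of multimodal
proteome-wide pI distributions.

Seed policy: one master seed; each record draws from its own
counter-derived stream, so inserting or removing a record never shifts
the sequences of later records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .constants import CANONICAL_RESIDUES
from .io_fasta import ProteinRecord, UNASSIGNED, normalize_host_group, write_fasta

MIN_LENGTH = 5

_BASE_PERCENT = {
    "A": 6.6, "C": 1.7, "D": 5.3, "E": 5.9, "F": 4.1, "G": 6.4, "H": 2.2,
    "I": 6.1, "K": 6.0, "L": 8.6, "M": 2.5, "N": 4.7, "P": 4.5, "Q": 3.8,
    "R": 5.0, "S": 7.2, "T": 6.2, "V": 6.7, "W": 1.3, "Y": 3.6,
}


def _tilted_freqs(**overrides: float) -> np.ndarray:
    pct = dict(_BASE_PERCENT)
    pct.update(overrides)
    v = np.array([pct[a] for a in CANONICAL_RESIDUES], dtype=float)
    return v / v.sum()


def acidic_profile() -> np.ndarray:
    """Residue frequencies with a D/E excess; component mean pI ~ 4.6."""
    return _tilted_freqs(D=6.5, E=7.5, K=4.0, R=3.5)


def neutral_profile() -> np.ndarray:
    """Charge-balanced frequencies with raised Cys/His; mean pI ~ 7.1.

    The elevated Cys fraction is a deliberate synthetic device: its
    near-neutral pKa buffers the net-charge curve around pH 7, keeping
    the component's pI spread narrow enough to act as a distinct mode.
    """
    return _tilted_freqs(C=10.0, H=5.0, D=3.8, E=4.2, K=5.6, R=4.4, L=7.6, S=6.4)


def basic_profile() -> np.ndarray:
    """Residue frequencies with a K/R excess; component mean pI ~ 10.1."""
    return _tilted_freqs(D=2.5, E=2.5, K=9.0, R=7.0)


def background_profile() -> np.ndarray:
    """Untilted average-proteome frequencies (broad pI distribution)."""
    return _tilted_freqs()


@dataclass(frozen=True)
class ComponentSpec:
    """One mixture component: weight, length distribution, residue frequencies."""

    weight: float
    length_log_mean: float
    length_log_sd: float
    residue_freqs: np.ndarray

    def __post_init__(self) -> None:
        if not 0.0 < self.weight <= 1.0:
            raise ValueError("component weight must be in (0, 1]")
        freqs = np.asarray(self.residue_freqs, dtype=float)
        if freqs.shape != (len(CANONICAL_RESIDUES),):
            raise ValueError(f"residue_freqs must have length {len(CANONICAL_RESIDUES)}")
        if np.any(freqs < 0) or abs(freqs.sum() - 1.0) > 1e-9:
            raise ValueError("residue_freqs must be a probability vector summing to 1")
        if self.length_log_sd < 0:
            raise ValueError("length_log_sd must be non-negative")
        object.__setattr__(self, "residue_freqs", freqs)


@dataclass(frozen=True)
class SyntheticSpec:
    """A named mixture proteome: components, size and master seed."""

    name: str
    components: tuple[ComponentSpec, ...]
    n_proteins: int
    seed: int
    host_group: str = UNASSIGNED

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("at least one component required")
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        total = sum(c.weight for c in self.components)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"component weights must sum to 1 (got {total})")
        object.__setattr__(self, "components", tuple(self.components))
        object.__setattr__(self, "host_group", normalize_host_group(self.host_group))


_RESIDUE_ARRAY = np.frombuffer(CANONICAL_RESIDUES.encode(), dtype="S1")

#: Length distribution used by the host archetypes (median ~450
#: residues, right-skewed): long enough that within-component pI spread
#: stays well below the spacing between the preset pI modes.
ARCHETYPE_LOG_MEAN = float(np.log(450.0))
ARCHETYPE_LOG_SD = 0.3

_ARCHETYPE_PROFILES = {
    "unimodal": (acidic_profile,),
    "bimodal": (acidic_profile, basic_profile),
    "trimodal": (acidic_profile, neutral_profile, basic_profile),
}


def host_archetype(
    label: str,
    n_proteins: int = 2000,
    seed: int = 0,
    host_group: str = UNASSIGNED,
) -> SyntheticSpec:
    """Spec with 1, 2 or 3 near-equal-weight components at well-separated pI modes."""
    try:
        profiles = _ARCHETYPE_PROFILES[label]
    except KeyError:
        raise ValueError(
            f"unknown archetype {label!r}; choose from {sorted(_ARCHETYPE_PROFILES)}"
        ) from None
    k = len(profiles)
    components = tuple(
        ComponentSpec(
            weight=1.0 / k,
            length_log_mean=ARCHETYPE_LOG_MEAN,
            length_log_sd=ARCHETYPE_LOG_SD,
            residue_freqs=make_freqs(),
        )
        for make_freqs in profiles
    )
    return SyntheticSpec(
        name=label, components=components, n_proteins=n_proteins, seed=seed,
        host_group=host_group,
    )


def sample_proteome(spec: SyntheticSpec) -> list[ProteinRecord]:
    """Draw exactly ``spec.n_proteins`` records, reproducibly from the seed.

    Component membership is drawn once for the whole proteome; each
    record then samples its length and residues from a stream keyed by
    (seed, record index).
    """
    master = np.random.default_rng(spec.seed)
    weights = np.array([c.weight for c in spec.components])
    assignment = master.choice(len(spec.components), size=spec.n_proteins, p=weights)
    records: list[ProteinRecord] = []
    for i in range(spec.n_proteins):
        comp = spec.components[assignment[i]]
        rng = np.random.default_rng((spec.seed, i))
        length = max(MIN_LENGTH, int(round(rng.lognormal(comp.length_log_mean, comp.length_log_sd))))
        idx = rng.choice(len(CANONICAL_RESIDUES), size=length, p=comp.residue_freqs)
        sequence = _RESIDUE_ARRAY[idx].tobytes().decode()
        records.append(
            ProteinRecord(
                id=f"{spec.name}_{i:06d}",
                sequence=sequence,
                description=f"{spec.name}_{i:06d} synthetic component={assignment[i]}",
                host_group=spec.host_group,
            )
        )
    return records


def write_proteome(
    spec: SyntheticSpec, fasta_path: str | Path, manifest_path: str | Path | None = None
) -> list[ProteinRecord]:
    """Emit FASTA (plus optional manifest TSV) so synthetic data enters the
    pipeline through the same path as real data."""
    records = sample_proteome(spec)
    write_fasta(records, fasta_path)
    if manifest_path is not None:
        with open(manifest_path, "wt") as out:
            out.write("# path\thost_group\n")
            out.write(f"{Path(fasta_path).name}\t{spec.host_group}\n")
    return records
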