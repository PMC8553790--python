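"""FASTA ingestion and host-group manifests.

Reads multi-FASTA protein files (plain or gzip) into validated
:class:`ProteinRecord` streams and parses the two-column manifest that
assigns each file to one of the nine host groups used throughout the
analysis.
"""

from __future__ import annotations

import glob
import gzip
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio import SeqIO

from .constants import AMBIGUITY_CODES, CANONICAL_RESIDUES

logger = logging.getLogger(__name__)

#: Closed host-group vocabulary. ``unassigned`` is permitted for library
#: use but excluded from host-level reports.
HOST_GROUPS: tuple[str, ...] = (
    "algae",
    "archaea",
    "bacteria",
    "fungi",
    "human",
    "invertebrate",
    "land_plant",
    "protozoa",
    "vertebrate",
)

UNASSIGNED = "unassigned"


class ValidationError(ValueError):
    """A sequence or manifest entry violated the input contract."""


def normalize_host_group(label: str) -> str:
    """Canonicalize a host label (case/space-insensitive) or raise."""
    token = label.strip().lower().replace(" ", "_").replace("-", "_")
    if token == "land_plants":
        token = "land_plant"
    if token in HOST_GROUPS or token == UNASSIGNED:
        return token
    raise ValidationError(
        f"unknown host group {label!r}; allowed: {', '.join(HOST_GROUPS)} (or {UNASSIGNED})"
    )


@dataclass(frozen=True)
class ProteinRecord:
    """One predicted protein sequence with its host-group assignment."""

    id: str
    sequence: str
    description: str = ""
    host_group: str = UNASSIGNED

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"record {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


def validate_sequence(raw: str, policy: str = "flag") -> tuple[str, dict[str, int]]:
    """Clean a raw residue string and report non-canonical codes.

    The sequence is upper-cased, whitespace is removed and a single
    terminal ``*`` (stop-codon translation artifact) is stripped.  Under
    policy ``"flag"`` the IUPAC ambiguity codes X/B/Z/U/O/J are retained
    and counted in the report; under ``"strict"`` any non-canonical code
    raises.  Characters outside the accepted alphabet (digits, gaps,
    internal stops) always raise.
    """
    if policy not in ("flag", "strict"):
        raise ValueError(f"unknown ambiguity policy {policy!r}")
    seq = "".join(raw.split()).upper()
    if seq.endswith("*"):
        seq = seq[:-1]
    if not seq:
        raise ValidationError("empty sequence after cleanup")
    report: dict[str, int] = {}
    for ch in seq:
        if ch in CANONICAL_RESIDUES:
            continue
        if ch in AMBIGUITY_CODES:
            if policy == "strict":
                raise ValidationError(f"non-canonical residue code {ch!r} under strict policy")
            report[ch] = report.get(ch, 0) + 1
        else:
            raise ValidationError(f"character {ch!r} is not an accepted residue code")
    return seq, report


def _open_text(path: str | Path) -> IO[str]:
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(
    path: str | Path,
    host_group: str = UNASSIGNED,
    policy: str = "flag",
) -> Iterator[ProteinRecord]:
    """Yield one validated :class:`ProteinRecord` per FASTA entry, in file order."""
    host = normalize_host_group(host_group)
    with _open_text(path) as handle:
        for entry in SeqIO.parse(handle, "fasta"):
            raw = str(entry.seq)
            if not raw or raw == "*":
                raise ValidationError(f"record {entry.id!r} in {path}: empty sequence")
            try:
                seq, report = validate_sequence(raw, policy=policy)
            except ValidationError as exc:
                raise ValidationError(f"record {entry.id!r} in {path}: {exc}") from None
            if report:
                logger.debug("record %s carries ambiguity codes %s", entry.id, report)
            yield ProteinRecord(
                id=entry.id,
                sequence=seq,
                description=entry.description,
                host_group=host,
            )


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> int:
    """Write records to FASTA, wrapping sequences at ``width`` columns."""
    n = 0
    with open(path, "wt") as out:
        for rec in records:
            header = rec.description if rec.description.startswith(rec.id) else rec.id
            out.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                out.write(rec.sequence[i : i + width] + "\n")
            n += 1
    return n


@dataclass(frozen=True)
class Manifest:
    """Assignment of FASTA paths/patterns to host groups."""

    entries: tuple[tuple[str, str], ...] = field(default_factory=tuple)

    def __len__(self) -> int:
        return len(self.entries)

    def resolve(self, root: str | Path = ".") -> list[tuple[str, str]]:
        """Expand glob patterns relative to ``root`` into (path, host) pairs."""
        out: list[tuple[str, str]] = []
        for pattern, host in self.entries:
            full = pattern if os.path.isabs(pattern) else os.path.join(str(root), pattern)
            matches = sorted(glob.glob(full))
            if not matches:
                raise FileNotFoundError(f"manifest pattern {pattern!r} matched no files")
            out.extend((m, host) for m in matches)
        return out


def read_manifest(path: str | Path) -> Manifest:
    """Parse a two-column TSV manifest (path pattern, host label).

    ``#`` comment lines and blank lines are skipped; host labels are
    validated against the closed nine-group vocabulary.
    """
    entries: list[tuple[str, str]] = []
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValidationError(f"{path}:{lineno}: expected 2 tab-separated columns")
            pattern, label = parts
            entries.append((pattern.strip(), normalize_host_group(label)))
    if not entries:
        logger.warning("manifest %s is empty", path)
    return Manifest(tuple(entries))


def read_manifest_records(
    manifest: Manifest, root: str | Path = ".", policy: str = "flag"
) -> Iterator[ProteinRecord]:
    """Stream records from every file a manifest points at."""
    for path, host in manifest.resolve(root):
        yield from read_fasta(path, host_group=host, policy=policy)
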