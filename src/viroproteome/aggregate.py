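"""Host-group and kingdom-level reduction of per-protein profiles.

Means are unweighted over proteins (every protein counts once,
regardless of which proteome it came from); the pooled kingdom mean is
likewise computed over all proteins, not as a mean of host means.
Proteins are partitioned into acidic / neutral / basic classes by pI
relative to 7 within a narrow tolerance window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import CANONICAL_RESIDUES
from .physchem import PhyschemProfile

#: Half-width of the neutral pI window: a protein is "neutral" iff its
#: pI rounds to 7.00 at two decimals.
DEFAULT_NEUTRAL_TOL = 0.005


@dataclass(frozen=True)
class ExtremeRecord:
    id: str
    length: int
    mw_da: float
    pi: float


@dataclass(frozen=True)
class HostGroupSummary:
    """Aggregate physicochemical statistics of one host group."""

    host_group: str
    n_proteins: int
    mean_length: float
    mean_mw_kda: float
    mean_pi: float
    mean_composition: Mapping[str, float]  # percentages, sum to 100
    pct_acidic: float
    pct_neutral: float
    pct_basic: float
    acidic_mean_pi: float | None
    basic_mean_pi: float | None
    longest: ExtremeRecord
    shortest: ExtremeRecord
    max_pi: ExtremeRecord
    min_pi: ExtremeRecord


@dataclass(frozen=True)
class KingdomSummary:
    """Per-host summaries plus the pooled (per-protein) totals."""

    hosts: tuple[HostGroupSummary, ...]
    pooled: HostGroupSummary


def partition_by_pi(
    profiles: Sequence[PhyschemProfile], neutral_tol: float = DEFAULT_NEUTRAL_TOL
) -> tuple[list[PhyschemProfile], list[PhyschemProfile], list[PhyschemProfile]]:
    """Split profiles into (acidic, neutral, basic) by pI around 7.

    neutral iff |pI - 7| <= neutral_tol; acidic below, basic above.  The
    three subsets are disjoint and exhaustive.
    """
    if neutral_tol < 0:
        raise ValueError("neutral_tol must be >= 0")
    acidic, neutral, basic = [], [], []
    for p in profiles:
        if abs(p.pi - 7.0) <= neutral_tol:
            neutral.append(p)
        elif p.pi < 7.0:
            acidic.append(p)
        else:
            basic.append(p)
    return acidic, neutral, basic


def _extreme(profiles: Sequence[PhyschemProfile], key, reverse: bool) -> ExtremeRecord:
    # ties broken by input order: max/min return the first optimum
    best = max(profiles, key=key) if reverse else min(profiles, key=key)
    return ExtremeRecord(id=best.id, length=best.length, mw_da=best.mw_da, pi=best.pi)


def summarize_group(
    profiles: Sequence[PhyschemProfile],
    host_group: str,
    neutral_tol: float = DEFAULT_NEUTRAL_TOL,
) -> HostGroupSummary:
    """Unweighted per-protein means, pI partition and extreme records."""
    if not profiles:
        raise ValueError(f"cannot summarize empty group {host_group!r}")
    n = len(profiles)
    lengths = np.array([p.length for p in profiles], dtype=float)
    mws = np.array([p.mw_da for p in profiles], dtype=float)
    pis = np.array([p.pi for p in profiles], dtype=float)
    comp = np.array([p.composition.as_list() for p in profiles], dtype=float)
    mean_comp = comp.mean(axis=0) * 100.0

    acidic, neutral, basic = partition_by_pi(profiles, neutral_tol)
    return HostGroupSummary(
        host_group=host_group,
        n_proteins=n,
        mean_length=float(lengths.mean()),
        mean_mw_kda=float(mws.mean()) / 1000.0,
        mean_pi=float(pis.mean()),
        mean_composition={r: float(v) for r, v in zip(CANONICAL_RESIDUES, mean_comp)},
        pct_acidic=100.0 * len(acidic) / n,
        pct_neutral=100.0 * len(neutral) / n,
        pct_basic=100.0 * len(basic) / n,
        acidic_mean_pi=float(np.mean([p.pi for p in acidic])) if acidic else None,
        basic_mean_pi=float(np.mean([p.pi for p in basic])) if basic else None,
        longest=_extreme(profiles, lambda p: p.length, reverse=True),
        shortest=_extreme(profiles, lambda p: p.length, reverse=False),
        max_pi=_extreme(profiles, lambda p: p.pi, reverse=True),
        min_pi=_extreme(profiles, lambda p: p.pi, reverse=False),
    )


def summarize_kingdom(
    profiles: Sequence[PhyschemProfile], neutral_tol: float = DEFAULT_NEUTRAL_TOL
) -> KingdomSummary:
    """Summaries per host group plus pooled per-protein totals.

    The pooled mean weights every protein equally, so hosts contributing
    more proteins weigh more — it is not the mean of host means.
    """
    if not profiles:
        raise ValueError("no profiles to summarize")
    by_host: dict[str, list[PhyschemProfile]] = {}
    for p in profiles:
        by_host.setdefault(p.host_group, []).append(p)
    hosts = tuple(
        summarize_group(by_host[h], h, neutral_tol) for h in sorted(by_host)
    )
    pooled = summarize_group(list(profiles), "pooled", neutral_tol)
    if pooled.n_proteins != sum(s.n_proteins for s in hosts):
        raise ValueError("inconsistent totals: pooled n differs from sum over hosts")
    return KingdomSummary(hosts=hosts, pooled=pooled)


_RANK_KEYS = ("mean_mw_kda", "mean_pi", "mean_length")


def rank_hosts(summaries: Iterable[HostGroupSummary], key: str = "mean_mw_kda") -> list[str]:
    """Host labels in ascending order of ``key``; ties alphabetical."""
    if key not in _RANK_KEYS:
        raise KeyError(f"unknown ranking key {key!r}; choose from {_RANK_KEYS}")
    return [
        s.host_group
        for s in sorted(summaries, key=lambda s: (getattr(s, key), s.host_group))
    ]


def summaries_to_frame(summaries: Iterable[HostGroupSummary]) -> pd.DataFrame:
    """Flatten summaries into a tidy table (one row per host group)."""
    rows = []
    for s in summaries:
        row: dict[str, object] = {
            "host_group": s.host_group,
            "n_proteins": s.n_proteins,
            "mean_length": s.mean_length,
            "mean_mw_kda": s.mean_mw_kda,
            "mean_pi": s.mean_pi,
            "pct_acidic": s.pct_acidic,
            "pct_neutral": s.pct_neutral,
            "pct_basic": s.pct_basic,
            "acidic_mean_pi": s.acidic_mean_pi,
            "basic_mean_pi": s.basic_mean_pi,
            "longest_id": s.longest.id,
            "longest_length": s.longest.length,
            "shortest_id": s.shortest.id,
            "shortest_length": s.shortest.length,
            "max_pi_id": s.max_pi.id,
            "max_pi": s.max_pi.pi,
            "min_pi_id": s.min_pi.id,
            "min_pi": s.min_pi.pi,
        }
        for r in CANONICAL_RESIDUES:
            row[f"pct_{r}"] = s.mean_composition[r]
        rows.append(row)
    return pd.DataFrame(rows)


def composition_matrix(summaries: Iterable[HostGroupSummary]) -> pd.DataFrame:
    """Hosts x 20-residue matrix of mean composition percentages."""
    data = {s.host_group: [s.mean_composition[r] for r in CANONICAL_RESIDUES] for s in summaries}
    return pd.DataFrame(data, index=list(CANONICAL_RESIDUES)).T
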