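"""Virtual 2D proteome maps and KDE-based modality classification.

A virtual 2D map is a computed analogue of a two-dimensional
electrophoresis gel: each protein is a point at (pI, log10 MW).  The
visual unimodal/bimodal/trimodal reading of such maps is formalised
here as peak counting on a Gaussian kernel density estimate of each
marginal: a mode is a local density maximum whose topographic
prominence exceeds a fixed fraction of the global density maximum, so
small ripples are ignored.

Molecular weight is analysed on a log10 scale — proteome MW spans more
than three orders of magnitude (roughly 0.5 to 1500 kDa), which makes
a linear-scale density estimate meaningless.  The headline label is
driven by the pI marginal (multimodality of bulk proteomes is
classically a pI phenomenon); the MW mode count is reported alongside,
never merged into the label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde

from .physchem import PhyschemProfile

logger = logging.getLogger(__name__)

PI_RANGE = (2.0, 14.0)
DEFAULT_BANDWIDTH_FACTOR = 1.0
DEFAULT_PROMINENCE_FRAC = 0.05
DEFAULT_GRID_POINTS = 512
MIN_PROFILES = 50

_LABELS = {1: "unimodal", 2: "bimodal", 3: "trimodal"}


class InsufficientDataError(ValueError):
    """Too few profiles for a meaningful modality call."""


@dataclass(frozen=True)
class Map2D:
    """2D histogram of a proteome over (pI, log10 MW) cells."""

    pi_edges: np.ndarray
    mw_edges: np.ndarray  # log10(Da)
    counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per cell (pi_bin, mw_bin, count)."""
        rows = []
        for i in range(self.counts.shape[0]):
            for j in range(self.counts.shape[1]):
                rows.append(
                    {
                        "pi_low": self.pi_edges[i],
                        "pi_high": self.pi_edges[i + 1],
                        "log10_mw_low": self.mw_edges[j],
                        "log10_mw_high": self.mw_edges[j + 1],
                        "count": int(self.counts[i, j]),
                    }
                )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class ModalityResult:
    """Mode counts of the pI and log10-MW marginals plus the label."""

    pi_modes: int
    mw_modes: int
    label: str
    mode_locations: tuple[float, ...]  # pI marginal, ascending pH
    bandwidth_factor: float
    prominence_frac: float
    n_profiles: int


def build_map(
    profiles: Sequence[PhyschemProfile], pi_bins: int = 60, mw_bins: int = 60
) -> Map2D:
    """2D histogram over pI in [2, 14] and log10 MW; out-of-range values
    are clamped into the edge bins with a logged warning."""
    if not profiles:
        raise ValueError("cannot build a map from zero profiles")
    if pi_bins < 10 or mw_bins < 10:
        raise ValueError("bin counts must be >= 10")
    pis = np.array([p.pi for p in profiles], dtype=float)
    log_mw = np.log10([p.mw_da for p in profiles])
    pi_edges = np.linspace(*PI_RANGE, pi_bins + 1)
    lo, hi = log_mw.min(), log_mw.max()
    if hi - lo < 1e-9:
        lo, hi = lo - 0.5, hi + 0.5
    mw_edges = np.linspace(lo, hi, mw_bins + 1)

    n_clamped = int(np.sum((pis < PI_RANGE[0]) | (pis > PI_RANGE[1])))
    if n_clamped:
        logger.warning("%d pI values outside [2, 14] clamped into edge bins", n_clamped)
    pis = np.clip(pis, PI_RANGE[0], PI_RANGE[1])

    counts, _, _ = np.histogram2d(pis, log_mw, bins=[pi_edges, mw_edges])
    return Map2D(pi_edges=pi_edges, mw_edges=mw_edges, counts=counts.astype(int))


def silverman_bandwidth(values: np.ndarray) -> float:
    """Silverman's rule-of-thumb bandwidth for a 1D Gaussian KDE."""
    values = np.asarray(values, dtype=float)
    return float(values.std(ddof=1) * (4.0 / (3.0 * len(values))) ** 0.2)


def kde_1d(
    values: Sequence[float],
    grid: np.ndarray | None = None,
    bandwidth_factor: float = DEFAULT_BANDWIDTH_FACTOR,
    grid_points: int = DEFAULT_GRID_POINTS,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian KDE with bandwidth = factor x Silverman's rule.

    Returns (grid, density).  The default grid spans the data plus three
    bandwidths on each side, so the density integrates to ~1 over it.
    Raises on fewer than two distinct values (degenerate distribution;
    treated as a single mode by callers).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2 or np.ptp(values) == 0.0:
        raise ValueError("KDE requires at least two distinct values")
    h = bandwidth_factor * silverman_bandwidth(values)
    kde = gaussian_kde(values, bw_method=h / values.std(ddof=1))
    if grid is None:
        grid = np.linspace(values.min() - 3 * h, values.max() + 3 * h, grid_points)
    density = kde(grid)
    return grid, density


def count_modes(
    density: np.ndarray,
    prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
    grid: np.ndarray | None = None,
) -> tuple[int, list[float]]:
    """Count local maxima with topographic prominence >= frac x max density.

    The density is padded with zeros so maxima at the grid boundary are
    eligible.  Returns (count, mode locations ascending); locations are
    grid coordinates when ``grid`` is given, else indices.
    """
    density = np.asarray(density, dtype=float)
    if density.size == 0:
        raise ValueError("empty density")
    if not 0.0 < prominence_frac < 1.0:
        raise ValueError("prominence_frac must be in (0, 1)")
    padded = np.concatenate([[0.0], density, [0.0]])
    threshold = prominence_frac * density.max()
    peaks, _ = find_peaks(padded, prominence=threshold)
    idx = peaks - 1
    if grid is not None:
        locations = [float(grid[i]) for i in idx]
    else:
        locations = [float(i) for i in idx]
    return len(idx), locations


def classify_modality(
    profiles: Sequence[PhyschemProfile],
    bandwidth_factor: float = DEFAULT_BANDWIDTH_FACTOR,
    prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
    grid_points: int = DEFAULT_GRID_POINTS,
) -> ModalityResult:
    """Label a proteome unimodal/bimodal/trimodal/multimodal from its pI marginal.

    Mode counts are computed independently for the pI and log10-MW
    marginals; the label follows the pI count.  Refuses (raises
    :class:`InsufficientDataError`) below 50 profiles — KDE peak counts
    on smaller samples are noise, not signal.
    """
    if len(profiles) < MIN_PROFILES:
        raise InsufficientDataError(
            f"modality classification requires >= {MIN_PROFILES} profiles, got {len(profiles)}"
        )
    pis = np.array([p.pi for p in profiles], dtype=float)
    log_mw = np.log10([p.mw_da for p in profiles])

    def marginal_modes(values: np.ndarray) -> tuple[int, list[float]]:
        if np.ptp(values) == 0.0:
            return 1, [float(values[0])]
        grid, density = kde_1d(
            values, bandwidth_factor=bandwidth_factor, grid_points=grid_points
        )
        return count_modes(density, prominence_frac, grid=grid)

    pi_modes, pi_locs = marginal_modes(pis)
    mw_modes, _ = marginal_modes(log_mw)
    label = _LABELS.get(pi_modes, "multimodal")
    return ModalityResult(
        pi_modes=pi_modes,
        mw_modes=mw_modes,
        label=label,
        mode_locations=tuple(pi_locs),
        bandwidth_factor=bandwidth_factor,
        prominence_frac=prominence_frac,
        n_profiles=len(profiles),
    )
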