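"""Correlation structure and NIPALS PCA of composition matrices.

Pearson product-moment correlation is used for both host-by-host
(rows of a hosts x residues composition matrix) and residue-by-residue
(columns across hosts) relationships, with 95% confidence intervals
from the Fisher z-transform.  Principal components are extracted by
NIPALS (nonlinear iterative partial least squares): power iteration on
the column-centered matrix with deflation after each component.  The
matrix is centered but not scaled — the columns of a compositional
percentage table already share a common unit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


class ConstantVectorError(ValueError):
    """Pearson correlation is undefined for a constant vector."""


def pearson(x, y) -> float:
    """Pearson product-moment correlation of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ConstantVectorError("correlation undefined for a constant vector")
    r, _ = sps.pearsonr(x, y)
    return float(r)


def fisher_ci(r: float, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Confidence interval for a correlation via the Fisher z-transform."""
    if not -1.0 < r < 1.0:
        return (r, r)
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    zcrit = sps.norm.ppf(0.5 + confidence / 2.0)
    return float(np.tanh(z - zcrit * se)), float(np.tanh(z + zcrit * se))


def _pairwise(frame: pd.DataFrame) -> pd.DataFrame:
    labels = list(frame.index)
    n = len(labels)
    out = np.eye(n)
    vectors = frame.to_numpy(dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = pearson(vectors[i], vectors[j])
    return pd.DataFrame(out, index=labels, columns=labels)


def host_correlation(matrix: pd.DataFrame) -> pd.DataFrame:
    """Host x host Pearson correlation of composition rows."""
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 residue columns")
    return _pairwise(matrix)


def residue_correlation(matrix: pd.DataFrame) -> pd.DataFrame:
    """Residue x residue Pearson correlation of across-host abundance columns."""
    if matrix.shape[0] < 3:
        raise ValueError("need at least 3 host rows")
    return _pairwise(matrix.T)


def correlation_long(corr: pd.DataFrame, n_obs: int | None = None) -> pd.DataFrame:
    """Long-format (label1, label2, r [, ci]) table of the upper triangle."""
    rows = []
    labels = list(corr.index)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            r = float(corr.loc[a, b])
            row = {"label1": a, "label2": b, "r": r}
            if n_obs is not None:
                lo, hi = fisher_ci(r, n_obs)
                row["ci95_low"], row["ci95_high"] = lo, hi
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PCAResult:
    """Scores, unit-norm loadings and explained variance per component."""

    scores: np.ndarray  # rows x components
    loadings: np.ndarray  # columns x components
    explained_variance_fraction: np.ndarray
    n_iterations: np.ndarray
    converged: np.ndarray
    row_labels: tuple[str, ...] = ()
    column_labels: tuple[str, ...] = ()


def pca_nipals(
    matrix,
    n_components: int = 2,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> PCAResult:
    """Sequential NIPALS extraction of principal components with deflation.

    Each component is found by alternating least squares on the
    column-centered residual: t = X p / (p'p), p = X' t / (t't),
    normalising p each sweep, until the score vector changes by less
    than ``tol`` (relative) or ``max_iter`` sweeps elapse.  The sign of
    each component is fixed by forcing its largest-magnitude loading
    positive.
    """
    if isinstance(matrix, pd.DataFrame):
        row_labels = tuple(str(i) for i in matrix.index)
        column_labels = tuple(str(c) for c in matrix.columns)
        X = matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
        row_labels = column_labels = ()
    n, m = X.shape
    if n < 2:
        raise ValueError("need at least 2 rows")
    if n_components > min(n - 1, m):
        raise ValueError(
            f"n_components={n_components} exceeds min(rows-1, cols)={min(n - 1, m)}"
        )
    Xc = X - X.mean(axis=0)
    total_var = float(np.sum(Xc**2))
    residual = Xc.copy()

    scores = np.zeros((n, n_components))
    loadings = np.zeros((m, n_components))
    explained = np.zeros(n_components)
    iters = np.zeros(n_components, dtype=int)
    converged = np.zeros(n_components, dtype=bool)

    for k in range(n_components):
        # start from the column with the largest residual variance
        start = int(np.argmax(np.sum(residual**2, axis=0)))
        t = residual[:, start].copy()
        if np.allclose(t, 0.0):
            break
        for it in range(1, max_iter + 1):
            p = residual.T @ t / (t @ t)
            p /= np.linalg.norm(p)
            t_new = residual @ p
            delta = np.linalg.norm(t_new - t) / max(np.linalg.norm(t_new), 1e-300)
            t = t_new
            if delta < tol:
                converged[k] = True
                break
        iters[k] = it
        # sign convention: largest-magnitude loading positive
        if p[np.argmax(np.abs(p))] < 0:
            p, t = -p, -t
        scores[:, k] = t
        loadings[:, k] = p
        explained[k] = float(t @ t) / total_var if total_var > 0 else 0.0
        residual = residual - np.outer(t, p)

    return PCAResult(
        scores=scores,
        loadings=loadings,
        explained_variance_fraction=explained,
        n_iterations=iters,
        converged=converged,
        row_labels=row_labels,
        column_labels=column_labels,
    )
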