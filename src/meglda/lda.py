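"""Regularized linear discriminant analysis via a generalized eigenproblem.

Given k annotated clusters of n-dimensional samples, the separating
directions q maximize the regularized Rayleigh ratio

    H_δ(q) = (qᵀ S_b q) / (qᵀ (S_w + δI) q),

where S_w is the within-cluster and S_b the between-cluster spread
(unnormalized scatter) matrix. The maximizers solve the generalized
eigenproblem S_b q = λ (S_w + δI) q; at most k−1 eigenvalues are positive,
and the corresponding eigenvectors — kept *without* orthogonalization —
are the separating directions. The analysis is purely data driven: no
distributional assumption is made about the clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.linalg

#: Positive-eigenvalue tolerance, relative to the largest eigenvalue.
POSITIVE_EIG_RTOL = 1e-10


@dataclass
class ClusterSet:
    """k ≥ 2 sample matrices sharing row (region) order, one per state.

    ``region_ids`` records which atlas region each row corresponds to, so
    that row bookkeeping survives restriction and sequential filtering.
    """

    matrices: list[np.ndarray]
    labels: list[str]
    region_ids: np.ndarray | None = None

    def __post_init__(self):
        self.matrices = [np.asarray(X, dtype=float) for X in self.matrices]
        if len(self.matrices) < 2:
            raise ValueError("need at least two clusters")
        if len(self.labels) != len(self.matrices):
            raise ValueError("one label per cluster required")
        n = self.matrices[0].shape[0]
        for X in self.matrices:
            if X.ndim != 2 or X.shape[0] != n or X.shape[1] < 1:
                raise ValueError("clusters must be n×p_i with identical n "
                                 "and p_i >= 1")
            if not np.all(np.isfinite(X)):
                raise ValueError("cluster matrices must be finite")
        if self.region_ids is None:
            self.region_ids = np.arange(n)
        else:
            self.region_ids = np.asarray(self.region_ids, dtype=int)
            if self.region_ids.shape != (n,):
                raise ValueError("region_ids must have one entry per row")

    @property
    def n_features(self) -> int:
        return self.matrices[0].shape[0]

    @property
    def k(self) -> int:
        return len(self.matrices)

    def take_rows(self, rows: np.ndarray) -> "ClusterSet":
        """Row-restricted copy (rows are positional indices)."""
        rows = np.asarray(rows, dtype=int)
        return ClusterSet([X[rows] for X in self.matrices], list(self.labels),
                          self.region_ids[rows])


@dataclass
class LDAResult:
    """Separating directions and derived quantities.

    ``directions`` is n×r with unit-2-norm columns (r ≤ k−1),
    ``eigenvalues`` the matching positive generalized eigenvalues in
    descending order, ``projections`` the per-cluster component matrices
    Z^(j) = QᵀX^(j).
    """

    directions: np.ndarray
    eigenvalues: np.ndarray
    delta: float
    projections: list[np.ndarray]
    labels: list[str]
    region_ids: np.ndarray

    @property
    def n_directions(self) -> int:
        return self.directions.shape[1]


def spread_matrices(clusters: ClusterSet) -> tuple[np.ndarray, np.ndarray]:
    """Within- and between-cluster spread matrices (S_w, S_b).

    S^(i) = (X^(i) − x̄^(i))(X^(i) − x̄^(i))ᵀ; S_w = Σ_i S^(i);
    S_b = Σ_i p_i (x̄^(i) − x̄)(x̄^(i) − x̄)ᵀ with x̄ the grand mean of the
    pooled columns. Both are symmetric positive semidefinite, and
    S_w + S_b equals the total scatter of the pooled data.
    """
    n = clusters.n_features
    Sw = np.zeros((n, n))
    total = np.zeros(n)
    p_total = 0
    means = []
    for X in clusters.matrices:
        m = X.mean(axis=1)
        Xc = X - m[:, None]
        Sw += Xc @ Xc.T
        means.append(m)
        total += X.sum(axis=1)
        p_total += X.shape[1]
    grand = total / p_total
    Sb = np.zeros((n, n))
    for X, m in zip(clusters.matrices, means):
        d = m - grand
        Sb += X.shape[1] * np.outer(d, d)
    return Sw, Sb


def h_delta(q: np.ndarray, Sw: np.ndarray, Sb: np.ndarray,
            delta: float) -> float:
    """Regularized between/within spread ratio H_δ evaluated at q."""
    q = np.asarray(q, dtype=float)
    denom = q @ Sw @ q + delta * (q @ q)
    return float((q @ Sb @ q) / denom)


def default_delta(Sw: np.ndarray) -> float:
    """Default regularization δ = 1e−6 · trace(S_w)/n (scale-following)."""
    n = Sw.shape[0]
    return 1e-6 * float(np.trace(Sw)) / n


def lda_directions(clusters: ClusterSet,
                   delta: float | None = None) -> LDAResult:
    """Solve S_b q = λ(S_w + δI)q and keep the positive-λ directions.

    Directions are unit 2-norm with a deterministic sign (the
    largest-magnitude component is made positive) and are *not* mutually
    orthogonalized. At most k−1 directions are returned; zero directions
    (all eigenvalues ≤ tolerance, e.g. identical clusters) is a valid
    result, not an error.
    """
    Sw, Sb = spread_matrices(clusters)
    Sw = 0.5 * (Sw + Sw.T)
    Sb = 0.5 * (Sb + Sb.T)
    if delta is None:
        delta = default_delta(Sw)
        if delta == 0.0:
            # degenerate clusters (zero within-spread): fall back to the
            # between-spread scale so S_w + δI stays invertible
            delta = 1e-6 * max(float(np.trace(Sb)) / clusters.n_features,
                               np.finfo(float).tiny)
    if delta < 0:
        raise ValueError("delta must be >= 0")
    n = clusters.n_features
    A = Sw + delta * np.eye(n)
    w, V = scipy.linalg.eigh(Sb, A)
    lam_max = max(float(w[-1]), 0.0)
    tol = POSITIVE_EIG_RTOL * lam_max
    keep = np.nonzero(w > tol)[0][::-1]          # descending order
    keep = keep[: clusters.k - 1]
    Q = V[:, keep]
    lams = w[keep]
    # unit 2-norm columns with the largest-|component| entry positive
    for j in range(Q.shape[1]):
        q = Q[:, j]
        q = q / np.linalg.norm(q)
        if q[np.argmax(np.abs(q))] < 0:
            q = -q
        Q[:, j] = q
    projections = [Q.T @ X for X in clusters.matrices]
    return LDAResult(directions=Q, eigenvalues=np.asarray(lams, dtype=float),
                     delta=float(delta), projections=projections,
                     labels=list(clusters.labels),
                     region_ids=clusters.region_ids.copy())


def project(clusters: ClusterSet, result: LDAResult) -> list[np.ndarray]:
    """Per-cluster LDA components Z^(j) = QᵀX^(j)."""
    if clusters.n_features != result.directions.shape[0]:
        raise ValueError("row dimension of clusters does not match the "
                         "separating directions")
    return [result.directions.T @ X for X in clusters.matrices]
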