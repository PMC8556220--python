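"""Cluster-overlap quantification in the LDA plane.

Separation quality is scored by histogram overlap: the 2-D LDA components
of all clusters are binned on one shared rectangle Ω (Bayesian optimal
bin counts per axis), and each unordered pair of clusters contributes a
Bhattacharyya index BI = Σ√(h_i h_j) ∈ [0, 1] (1 − BI is the Hellinger-
style distance between the binned distributions). The mean pairwise index
(MPBI) over all pairs is the headline separation score; scanning it over
bootstrap window lengths selects the window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from . import lda as _lda
from . import spectral as _spectral
from .bands import BandDefinition
from .containers import BRALISeries

logger = logging.getLogger(__name__)

#: Default maximum bin count per axis for the optimal-binning scan.
M_MAX_DEFAULT = 200

#: Relative margin by which the shared rectangle Ω is expanded so that
#: maximal points fall inside the last pixel.
OMEGA_MARGIN = 1e-9

#: MPBI at or below which two clusters are declared completely separated
#: when selecting the bootstrap window length.
SEPARATION_THRESHOLD = 0.05


@dataclass(frozen=True)
class BinningSpec:
    """Shared binning: rectangle Ω (per-axis min/max) and bins per axis."""

    omega: tuple[tuple[float, float], ...]
    bins_per_axis: tuple[int, ...]

    def __post_init__(self):
        if len(self.omega) != len(self.bins_per_axis):
            raise ValueError("one bin count per axis required")
        for (lo, hi), m in zip(self.omega, self.bins_per_axis):
            if not (lo < hi) or m < 1:
                raise ValueError("omega must have positive extent and "
                                 "bins_per_axis >= 1")

    def edges(self) -> list[np.ndarray]:
        return [np.linspace(lo, hi, m + 1)
                for (lo, hi), m in zip(self.omega, self.bins_per_axis)]


@dataclass
class OverlapReport:
    """Pairwise BI matrix (diagonal 1), their mean, and the binning used."""

    pairwise: np.ndarray
    mpbi: float
    binning: BinningSpec
    labels: list[str]


def knuth_log_posterior(values: np.ndarray, M: int) -> float:
    """Log-posterior of M equal-width bins for the sample (up to a constant).

    logP(M) = n·logM + logΓ(M/2) − M·logΓ(1/2) − logΓ(n + M/2)
              + Σ_k logΓ(c_k + 1/2), with c_k the bin counts over the
    sample range.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    counts, _ = np.histogram(values, bins=M,
                             range=(values.min(), values.max()))
    return float(
        n * np.log(M) + gammaln(M / 2.0) - M * gammaln(0.5)
        - gammaln(n + M / 2.0) + gammaln(counts + 0.5).sum()
    )


def knuth_bins(values: np.ndarray, m_max: int = M_MAX_DEFAULT) -> int:
    """Bayesian optimal equal-width bin count (exhaustive posterior scan).

    Returns the smallest maximizer of the log-posterior over
    M ∈ {1, …, m_max}; a degenerate (constant) sample yields 1.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 2:
        raise ValueError("need at least two sample values")
    if m_max < 1:
        raise ValueError("m_max must be >= 1")
    if values.min() == values.max():
        return 1
    best_m, best_lp = 1, -np.inf
    for M in range(1, m_max + 1):
        lp = knuth_log_posterior(values, M)
        if lp > best_lp:
            best_m, best_lp = M, lp
    return best_m


def histogram2d(points: np.ndarray, spec: BinningSpec) -> np.ndarray:
    """Normalized flattened histogram of 2×p (or 1×p) points on the spec.

    Entries sum to 1; a point outside Ω is an error (the shared Ω is built
    from the pooled data, so this indicates mismatched binning).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    d, p = points.shape
    if p == 0:
        raise ValueError("empty point set")
    if d != len(spec.omega):
        raise ValueError("point dimension does not match the binning spec")
    for ax, (lo, hi) in enumerate(spec.omega):
        if points[ax].min() < lo or points[ax].max() > hi:
            raise ValueError("points fall outside the binning rectangle")
    edges = spec.edges()
    h, _ = np.histogramdd(points.T, bins=edges)
    return h.ravel() / p


def bhattacharyya(h1: np.ndarray, h2: np.ndarray,
                  tol: float = 1e-8) -> float:
    """Bhattacharyya index Σ√(h1·h2) of two normalized histograms."""
    h1 = np.asarray(h1, dtype=float).ravel()
    h2 = np.asarray(h2, dtype=float).ravel()
    if h1.shape != h2.shape:
        raise ValueError("histograms must have equal length")
    for h in (h1, h2):
        if np.any(h < -tol) or abs(h.sum() - 1.0) > max(tol, tol * h.size):
            raise ValueError("histograms must be normalized and non-negative")
    return float(np.clip(np.sqrt(np.clip(h1, 0, None)
                                 * np.clip(h2, 0, None)).sum(), 0.0, 1.0))


def shared_binning(clusters_Z: Sequence[np.ndarray],
                   m_max: int = M_MAX_DEFAULT) -> BinningSpec:
    """Shared rectangle Ω and per-axis optimal bin counts for projections.

    Ω is the bounding box of the pooled projections, expanded by a tiny
    relative margin so maximal points land inside the last (closed) pixel;
    the bin count per axis comes from the optimal-binning scan on the
    pooled per-axis values.
    """
    pooled = np.concatenate([np.atleast_2d(np.asarray(Z, dtype=float))
                             for Z in clusters_Z], axis=1)
    omega = []
    bins = []
    for ax in range(pooled.shape[0]):
        lo, hi = pooled[ax].min(), pooled[ax].max()
        span = max(hi - lo, abs(hi), abs(lo), 1.0)
        margin = OMEGA_MARGIN * span
        omega.append((lo - margin, hi + margin))
        bins.append(1 if lo == hi else knuth_bins(pooled[ax], m_max))
    return BinningSpec(omega=tuple(omega), bins_per_axis=tuple(bins))


def mpbi(clusters_Z: Sequence[np.ndarray], labels: Sequence[str] | None = None,
         m_max: int = M_MAX_DEFAULT) -> OverlapReport:
    """Mean pairwise Bhattacharyya index of c ≥ 2 projected clusters.

    All clusters are binned on one shared Ω; the MPBI is the mean of the
    c(c−1)/2 unordered pairwise indices.
    """
    c = len(clusters_Z)
    if c < 2:
        raise ValueError("need at least two clusters")
    for Z in clusters_Z:
        if np.atleast_2d(np.asarray(Z)).shape[1] == 0:
            raise ValueError("empty cluster projection")
    if labels is None:
        labels = [f"cluster{i}" for i in range(c)]
    spec = shared_binning(clusters_Z, m_max)
    hists = [histogram2d(Z, spec) for Z in clusters_Z]
    pairwise = np.eye(c)
    for i in range(c):
        for j in range(i + 1, c):
            pairwise[i, j] = pairwise[j, i] = bhattacharyya(hists[i], hists[j])
    value = float(pairwise[np.triu_indices(c, k=1)].mean())
    return OverlapReport(pairwise=pairwise, mpbi=value, binning=spec,
                         labels=list(labels))


def projection_overlap(result: _lda.LDAResult,
                       m_max: int = M_MAX_DEFAULT) -> float:
    """MPBI of an LDA result's top-2 (or top-1) projections.

    With no separating direction at all the clusters are indistinguishable
    along any discriminant axis and the overlap is 1 by convention.
    """
    if result.n_directions == 0:
        return 1.0
    r = min(2, result.n_directions)
    return mpbi([Z[:r] for Z in result.projections], result.labels,
                m_max).mpbi


@dataclass
class WindowScanResult:
    """MPBI per (window length, band) plus the selected window per band."""

    table: pd.DataFrame
    selected: dict[str, int | None]
    threshold: float


def window_scan(series_by_state: Mapping[str, BRALISeries],
                window_lengths: Sequence[int],
                bands: Sequence[BandDefinition],
                p: int,
                seed: int = 0,
                delta: float | None = None,
                threshold: float = SEPARATION_THRESHOLD) -> WindowScanResult:
    """Bootstrap → periodogram → band power → LDA → MPBI per window length.

    For each window length N, p windows are drawn per state, band-power
    cluster sets are built per band, and the LDA-plane overlap is scored.
    ``selected`` holds, per band, the smallest window whose MPBI is at or
    below the separation threshold (None if never reached).
    """
    states = list(series_by_state)
    if len(states) < 2:
        raise ValueError("need at least two states")
    T_min = min(s.n_samples for s in series_by_state.values())
    if max(window_lengths) > T_min:
        raise ValueError("largest window exceeds the shortest series")
    ss = np.random.SeedSequence(seed)
    rows = []
    for N in window_lengths:
        stacks = {}
        for state, child in zip(states, ss.spawn(len(states))):
            series = series_by_state[state]
            rng = np.random.default_rng(child)
            samples = _spectral.draw_bootstrap_windows(series, N, p, rng)
            stacks[state] = _spectral.periodogram_stack(samples, series.dt,
                                                        state=state)
            del samples
        for band in bands:
            mats = [_spectral.band_power_matrix(stacks[s], band).values
                    for s in states]
            clusters = _lda.ClusterSet(mats, states)
            result = _lda.lda_directions(clusters, delta)
            row = {"window": N, "band": band.name}
            if result.n_directions == 0:
                row["mpbi"] = 1.0
                for i in range(len(states)):
                    for j in range(i + 1, len(states)):
                        row[f"bi_{states[i].lower()}_{states[j].lower()}"] = 1.0
            else:
                r = min(2, result.n_directions)
                report = mpbi([Z[:r] for Z in result.projections], states)
                row["mpbi"] = report.mpbi
                for i in range(len(states)):
                    for j in range(i + 1, len(states)):
                        row[f"bi_{states[i].lower()}_{states[j].lower()}"] = \
                            report.pairwise[i, j]
            rows.append(row)
        logger.info("window scan: N=%d done (%d bands)", N, len(bands))
    table = pd.DataFrame(rows)
    selected: dict[str, int | None] = {}
    for band in bands:
        sub = table[table["band"] == band.name].sort_values("window")
        ok = sub[sub["mpbi"] <= threshold]
        selected[band.name] = int(ok["window"].iloc[0]) if len(ok) else None
    return WindowScanResult(table=table, selected=selected,
                            threshold=threshold)
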