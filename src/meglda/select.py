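"""Interpreting separating vectors: which brain regions drive separation.

A region is a significant separator when the amplitude of its component
in at least one separating vector reaches 10% of that vector's maximum
amplitude. Three tools build on this rule:

* sequential filtering — repeatedly discard the sub-threshold regions and
  re-run the discriminant analysis on the reduced data, recording the
  overlap so the (expected, gradual) degradation of separation is
  observable;
* the session tally — with two independent sessions per state there are
  2³ = 8 ways to combine them into one three-cluster problem; a region's
  tally counts in how many of the 8 it passes the amplitude rule;
* subset restriction — rerun the analysis on the left or right
  hemisphere, the cortical regions, or the internal structures only.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .atlas import RegionAtlas
from .bands import BandDefinition
from .containers import BandPowerMatrix
from .lda import ClusterSet, LDAResult, lda_directions
from .overlap import projection_overlap

#: Default amplitude-rule threshold: 10% of a vector's maximum amplitude.
THRESHOLD_FRACTION = 0.1

SUBSETS = ("left", "right", "cortical", "internal", "all")


def significant_regions(result: LDAResult,
                        threshold_fraction: float = THRESHOLD_FRACTION
                        ) -> np.ndarray:
    """Region ids whose component passes the amplitude rule.

    Region ℓ is retained iff |q_ℓ^(j)| ≥ threshold · max_i |q_i^(j)| for at
    least one separating direction j (a tie at the threshold retains). With
    zero directions nothing can be selected; an empty set is returned with
    a warning.
    """
    if result.n_directions == 0:
        warnings.warn("LDA produced no separating direction; no region "
                      "selected", stacklevel=2)
        return np.empty(0, dtype=int)
    Q = np.abs(result.directions)
    cut = threshold_fraction * Q.max(axis=0, keepdims=True)
    keep = (Q >= cut).any(axis=1)
    return np.sort(result.region_ids[keep])


@dataclass
class FilterStep:
    region_ids: np.ndarray
    lda: LDAResult
    mpbi: float


@dataclass
class FilterTrace:
    """Ordered record of a sequential filtering run (entry 0 = all regions).

    Retained sets are nested and non-increasing in size.
    """

    iterations: list[FilterStep]

    @property
    def retained(self) -> np.ndarray:
        return self.iterations[-1].region_ids

    def sizes(self) -> list[int]:
        return [len(step.region_ids) for step in self.iterations]

    def to_frame(self, atlas: RegionAtlas | None = None) -> pd.DataFrame:
        rows = []
        for it, step in enumerate(self.iterations):
            for rid in step.region_ids:
                row = {"iteration": it, "region_id": int(rid),
                       "mpbi": step.mpbi}
                if atlas is not None:
                    row["name"] = atlas[int(rid)].name
                    row["hemisphere"] = atlas[int(rid)].hemisphere
                rows.append(row)
        return pd.DataFrame(rows)


def sequential_filter(clusters: ClusterSet,
                      threshold_fraction: float = THRESHOLD_FRACTION,
                      max_iter: int = 3, min_regions: int = 2,
                      delta: float | None = None) -> FilterTrace:
    """Iterate LDA → amplitude rule → row restriction.

    Stops when the retained set stabilizes, falls below ``min_regions``
    (kept as-is, not an error), or after ``max_iter`` reductions. The
    overlap (MPBI) of each iteration's projections is recorded.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    current = clusters
    result = lda_directions(current, delta)
    trace = [FilterStep(np.sort(current.region_ids.copy()), result,
                        projection_overlap(result))]
    for _ in range(max_iter):
        selected = significant_regions(result, threshold_fraction)
        if selected.size == 0 or selected.size < min_regions:
            break
        if selected.size == len(current.region_ids):
            break  # stabilized: nothing removed
        rows = np.nonzero(np.isin(current.region_ids, selected))[0]
        current = current.take_rows(rows)
        result = lda_directions(current, delta)
        trace.append(FilterStep(np.sort(current.region_ids.copy()), result,
                                projection_overlap(result)))
    return FilterTrace(iterations=trace)


@dataclass
class TallyTable:
    """Region × band selection counts over the session combinations."""

    counts: pd.DataFrame           # index region_id, columns band names
    combination_log: list[dict[str, str]]

    @property
    def n_combinations(self) -> int:
        return len(self.combination_log)

    def to_report(self, atlas: RegionAtlas) -> pd.DataFrame:
        """Named per-region table, omitting regions never selected."""
        df = self.counts.copy()
        df = df[df.sum(axis=1) > 0]
        df.insert(0, "name", [atlas[int(i)].name for i in df.index])
        df.insert(1, "hemisphere", [atlas[int(i)].hemisphere
                                    for i in df.index])
        return df


def tally(sessions: Mapping[tuple[str, str], Mapping[str, BandPowerMatrix]],
          bands: Sequence[BandDefinition],
          threshold_fraction: float = THRESHOLD_FRACTION,
          delta: float | None = None,
          include_dc: bool = False) -> TallyTable:
    """Count, per band, how often each region passes the amplitude rule
    across all session combinations.

    ``sessions`` maps (state, session_id) to that session's band-power
    matrices keyed by band name; exactly two sessions per state are
    required, giving 2^(#states) combinations. The DC band is excluded
    unless ``include_dc`` (its separation can reflect arbitrary
    per-session scaling rather than brain state).
    """
    states: list[str] = []
    per_state: dict[str, list[str]] = {}
    for (state, sid) in sessions:
        if state not in per_state:
            states.append(state)
            per_state[state] = []
        per_state[state].append(sid)
    for state, sids in per_state.items():
        if len(sids) != 2:
            raise ValueError(f"state {state!r} needs exactly two sessions, "
                             f"got {sorted(sids)}")
        per_state[state] = sorted(sids)
    use_bands = [b for b in bands if include_dc or not b.is_dc]
    if not use_bands:
        raise ValueError("no band left to tally")

    first = next(iter(sessions.values()))
    n = next(iter(first.values())).n_regions
    counts = pd.DataFrame(0, index=pd.RangeIndex(n, name="region_id"),
                          columns=[b.name for b in use_bands], dtype=int)
    combos = [dict(zip(states, choice)) for choice in
              itertools.product(*(per_state[s] for s in states))]
    for band in use_bands:
        for combo in combos:
            mats = [sessions[(s, combo[s])][band.name].values for s in states]
            clusters = ClusterSet(mats, states)
            result = lda_directions(clusters, delta)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ids = significant_regions(result, threshold_fraction)
            counts.loc[ids, band.name] += 1
    return TallyTable(counts=counts, combination_log=combos)


def restrict(clusters: ClusterSet, atlas: RegionAtlas,
             subset: str) -> ClusterSet:
    """Restrict cluster rows to a hemisphere or tissue-class subset.

    ``internal`` includes the brainstem (the midline internal structure);
    ``left``/``right`` select by hemisphere, excluding midline regions.
    """
    if subset not in SUBSETS:
        raise ValueError(f"subset must be one of {SUBSETS}")
    if subset == "all":
        return clusters
    if subset in ("left", "right"):
        ids = atlas.ids_where(hemisphere=subset)
    elif subset == "cortical":
        ids = atlas.ids_where(region_class="cortical")
    else:
        ids = atlas.ids_where(region_class=("internal", "brainstem"))
    rows = np.nonzero(np.isin(clusters.region_ids, ids))[0]
    if rows.size == 0:
        raise ValueError(f"subset {subset!r} selects no region")
    return clusters.take_rows(rows)
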