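"""End-to-end orchestration of the brain-state separation pipeline.

One configured run simulates (or loads) three-state activity series,
draws bootstrap windows, computes band-power sample matrices, runs the
regularized discriminant analysis per band, scores the cluster overlap,
performs sequential region filtering, and tallies region selections over
the eight A/B session combinations. Every output table is deterministic
given (config, seed) and is written with provenance (config hash, seed,
package version).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .atlas import RegionAtlas
from .bands import (SUBJECT1_BANDS, SUBJECT2_BANDS, BandDefinition, DC_BAND,
                    bands_to_frame)
from .containers import BRALISeries
from .io import read_brali, write_table
from .lda import ClusterSet, lda_directions
from .overlap import projection_overlap, window_scan
from .select import sequential_filter, tally
from .spectral import band_power_matrices, draw_bootstrap_windows, \
    periodogram_stack
from .synthetic import Scenario, default_scenario, simulate_brali

logger = logging.getLogger(__name__)

BAND_TABLES = {"subject1": SUBJECT1_BANDS, "subject2": SUBJECT2_BANDS}


@dataclass
class PipelineConfig:
    """Declarative description of one pipeline run.

    Either ``scenario`` (inline JSON object / path) or ``brali_paths``
    (state label → two file paths, sessions A and B) must be provided.
    ``band_table`` names a shipped table ('subject1'/'subject2') or a path
    to a delimited band table.
    """

    scenario: dict | str | None = None
    brali_paths: dict[str, list[str]] | None = None
    window_length: int = 2000
    samples_p: int = 1000
    seed: int = 0
    band_table: str = "subject1"
    include_dc: bool = False
    delta: float | None = None
    threshold_fraction: float = 0.1
    subset: str = "all"
    window_grid: list[int] = field(default_factory=lambda: [200, 400, 800,
                                                            1200, 2000])
    duration_s: float = 60.0
    atlas_path: str | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PipelineConfig":
        if isinstance(source, Path) or not str(source).lstrip().startswith("{"):
            source = Path(source).read_text()
        d = json.loads(source)
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]

    def resolve_bands(self) -> tuple[BandDefinition, ...]:
        if self.band_table in BAND_TABLES:
            return BAND_TABLES[self.band_table]
        from .bands import load_bands
        return load_bands(self.band_table)

    def resolve_scenario(self) -> Scenario | None:
        if self.scenario is None:
            return None
        if isinstance(self.scenario, dict):
            return Scenario.from_json(json.dumps(self.scenario))
        return Scenario.from_json(self.scenario)


def _resolve_atlas(config: PipelineConfig, n: int) -> RegionAtlas:
    """Atlas matching the n regions of the inputs (needed for subsets)."""
    from .atlas import make_atlas
    from .synthetic import desk_atlas
    if config.atlas_path:
        atlas = RegionAtlas.load(config.atlas_path)
        if len(atlas) != n:
            raise StageError("region_select",
                             f"atlas has {len(atlas)} regions, data has {n}")
        return atlas
    if n == 20:
        return desk_atlas()
    if n == 165:
        return make_atlas()
    raise StageError("region_select",
                     f"subset {config.subset!r} needs an atlas_path for "
                     f"n={n} regions")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"{stage}: {message}")
        self.stage = stage


def _seed_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def load_or_simulate(config: PipelineConfig, sessions: Sequence[str] = ("A", "B")
                     ) -> dict[tuple[str, str], BRALISeries]:
    """State×session activity series from files or from the scenario."""
    if config.brali_paths:
        out = {}
        for state, paths in config.brali_paths.items():
            for sid, path in zip(sessions, paths):
                out[(state, sid)] = read_brali(path)
        return out
    scenario = config.resolve_scenario()
    if scenario is None:
        scenario = default_scenario()
    ss = np.random.SeedSequence(config.seed)
    out = {}
    # one independent seed per (state, session): A/B emulate temporally
    # separated, independently preprocessed recordings
    for state in scenario.states:
        for sid in sessions:
            child = ss.spawn(1)[0]
            out[(state, sid)] = simulate_brali(
                scenario, state, config.duration_s, seed=_seed_int(child),
                session=sid)
    return out


def run_pipeline(config: PipelineConfig, out_dir: str | Path,
                 run_window_scan: bool = False) -> dict:
    """Execute the full pipeline; write tables under ``out_dir``.

    Returns a report dict with the per-band overlap, filter traces, the
    tally, and provenance. Any stage error surfaces as
    :class:`StageError` naming the failing stage.
    """
    t0 = time.time()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bands = config.resolve_bands()
    osc_bands = [b for b in bands if not b.is_dc]
    all_bands = list(bands) + ([DC_BAND] if config.include_dc else [])

    series = load_or_simulate(config)
    states = []
    for (state, _sid) in series:
        if state not in states:
            states.append(state)
    n_regions = next(iter(series.values())).n_regions
    keep_ids = np.arange(n_regions)
    if config.subset != "all":
        atlas = _resolve_atlas(config, n_regions)
        if config.subset in ("left", "right"):
            ids = atlas.ids_where(hemisphere=config.subset)
        elif config.subset == "cortical":
            ids = atlas.ids_where(region_class="cortical")
        elif config.subset == "internal":
            ids = atlas.ids_where(region_class=("internal", "brainstem"))
        else:
            raise StageError("region_select",
                             f"unknown subset {config.subset!r}")
        if not ids:
            raise StageError("region_select",
                             f"subset {config.subset!r} selects no region")
        keep_ids = np.asarray(ids)
    T_min = min(s.n_samples for s in series.values())
    if config.window_length > T_min:
        raise StageError("spectral", f"window length N={config.window_length} "
                         f"exceeds series length T={T_min}")
    logger.info("inputs: %d series, n=%d regions, T=%d samples",
                len(series), next(iter(series.values())).n_regions, T_min)

    # spectra and band powers per (state, session)
    ss = np.random.SeedSequence(config.seed + 1)
    band_powers: dict[tuple[str, str], dict] = {}
    for key, s in series.items():
        rng = np.random.default_rng(_seed_int(ss.spawn(1)[0]))
        try:
            samples = draw_bootstrap_windows(s, config.window_length,
                                             config.samples_p, rng)
            stack = periodogram_stack(samples, s.dt, state=s.state)
            powers = band_power_matrices(stack, all_bands)
            if len(keep_ids) != n_regions:      # subset restriction
                for bp in powers.values():
                    bp.values = bp.values[keep_ids]
            band_powers[key] = powers
        except ValueError as e:
            raise StageError("spectral", str(e)) from e
        del samples, stack
    logger.info("spectra: N=%d, p=%d, %d bands", config.window_length,
                config.samples_p, len(all_bands))

    # per-band LDA + overlap + sequential filtering on session A
    report_rows = []
    traces = {}
    for band in osc_bands:
        mats = [band_powers[(st, "A")][band.name].values for st in states]
        clusters = ClusterSet(mats, states, region_ids=keep_ids)
        try:
            result = lda_directions(clusters, config.delta)
        except Exception as e:  # pragma: no cover - defensive
            raise StageError("lda", str(e)) from e
        ov = projection_overlap(result)
        trace = sequential_filter(clusters, config.threshold_fraction,
                                  delta=config.delta)
        traces[band.name] = trace
        report_rows.append({
            "band": band.name,
            "n_directions": result.n_directions,
            "lambda1": result.eigenvalues[0] if result.n_directions else 0.0,
            "lambda2": result.eigenvalues[1] if result.n_directions > 1 else 0.0,
            "delta": result.delta,
            "mpbi": ov,
            "regions_after_filtering": len(trace.retained),
        })
        logger.info("lda/overlap/filter band=%s: r=%d mpbi=%.4g retained=%d",
                    band.name, result.n_directions, ov, len(trace.retained))
    band_report = pd.DataFrame(report_rows)
    write_table(band_report, out_dir / "band_report.tsv")
    filter_frames = []
    for name, trace in traces.items():
        df = trace.to_frame()
        df.insert(0, "band", name)
        filter_frames.append(df)
    write_table(pd.concat(filter_frames, ignore_index=True),
                out_dir / "filter_trace.tsv")

    # tally over the 8 session combinations
    tally_table = tally(band_powers, osc_bands, config.threshold_fraction,
                        config.delta)
    tally_table.counts.index = pd.Index(keep_ids, name="region_id")
    write_table(tally_table.counts.reset_index(), out_dir / "tally.tsv")
    logger.info("tally: %d combinations, %d bands",
                tally_table.n_combinations, len(osc_bands))

    scan = None
    if run_window_scan:
        series_a = {st: series[(st, "A")] for st in states}
        scan = window_scan(series_a, config.window_grid, osc_bands,
                           config.samples_p, seed=config.seed + 2,
                           delta=config.delta)
        write_table(scan.table, out_dir / "window_scan.tsv")
        logger.info("window scan: grid=%s", config.window_grid)

    write_table(bands_to_frame(bands), out_dir / "bands.tsv")
    provenance = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "elapsed_s": round(time.time() - t0, 3),
    }
    (out_dir / "provenance.json").write_text(
        json.dumps(provenance, indent=2, sort_keys=True))
    config.to_json(out_dir / "config.json")
    return {
        "band_report": band_report,
        "filter_traces": traces,
        "tally": tally_table,
        "window_scan": scan,
        "provenance": provenance,
    }
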