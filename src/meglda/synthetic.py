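"""Synthetic region-level MEG activity generator.

The recordings the pipeline was designed for cannot be redistributed, so
this module generates surrogate region activity with the same statistical
skeleton: per-region 1/f-like background noise, narrow-band θ/α/β/γ
oscillations with slowly drifting phase, a dominant DC level (activity is
a magnitude, hence non-negative), and *planted* state-dependent band-power
differences confined to a chosen subset of regions. Non-planted regions
have identical oscillation amplitudes in every state, so any apparent
state difference there is pure sampling noise.

Oscillators are realized as sinusoids whose instantaneous phase carries an
Ornstein–Uhlenbeck perturbation: the peak frequency stays exactly
controllable while the finite phase coherence broadens the spectral line
to a few Hz, qualitatively matching measured source-space spectra.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import lfilter

from .atlas import RegionAtlas, make_atlas
from .bands import SUBJECT1_BANDS, BandDefinition
from .containers import BRALISeries, DipoleSeries

#: Baseline oscillation amplitudes per band (arbitrary units, applied to
#: every region at rest).
BASE_AMPLITUDES: dict[str, float] = {
    "theta": 1.0,
    "alpha": 1.5,
    "beta": 0.8,
    "gamma": 0.5,
}

#: Multiplicative amplitude modulations of the planted regions per state.
#: Planted regions cycle through the patterns: one subgroup is up-modulated
#: during focused attention, the other during open monitoring. The cluster
#: means then form a well-spread triangle in a two-dimensional subspace of
#: the planted rows, so BOTH separating directions are driven by planted
#: structure (a single shared pattern would make the between-cluster
#: spread rank 1 over the planted rows — or badly lopsided — leaving the
#: second discriminant direction to chase sampling noise).
PLANTED_STATE_GAINS: tuple[dict[str, float], ...] = (
    {"rest": 1.0, "Samatha": 1.75, "Vipassana": 1.0},
    {"rest": 1.0, "Samatha": 1.0, "Vipassana": 1.75},
)

#: Baseline-amplitude factor of the planted (deep/internal) regions
#: relative to the cortical baseline: deep structures aggregate less
#: dipole amplitude than large cortical parcels.
PLANTED_BASE_FACTOR = 0.5


@dataclass
class Scenario:
    """Full description of a synthetic experiment.

    ``amplitude_table`` maps (state, region_id, band_name) to the
    oscillation amplitude; missing entries mean amplitude 0. For regions
    not in ``planted_regions`` the amplitudes must be identical across
    states.
    """

    n_regions: int
    states: tuple[str, ...] = ("rest", "Samatha", "Vipassana")
    bands: tuple[BandDefinition, ...] = SUBJECT1_BANDS
    amplitude_table: dict = field(default_factory=dict)
    background_exponent: float = 1.0
    noise_sd: float = 1.0
    planted_regions: frozenset[int] = frozenset()
    dt: float = 0.001
    dc_offset: float | None = None
    phase_tau: float = 0.5
    phase_rms: float = 0.5

    def __post_init__(self):
        self.planted_regions = frozenset(int(r) for r in self.planted_regions)
        for p in (self.background_exponent, self.noise_sd, self.dt,
                  self.phase_tau, self.phase_rms):
            if not math.isfinite(p):
                raise ValueError("scenario parameters must be finite")
        if self.noise_sd < 0 or self.dt <= 0:
            raise ValueError("noise_sd must be >= 0 and dt > 0")
        if any(v < 0 for v in self.amplitude_table.values()):
            raise ValueError("amplitudes must be non-negative")
        if not self.planted_regions <= set(range(self.n_regions)):
            raise ValueError("planted_regions must be valid region ids")
        for m in range(self.n_regions):
            if m in self.planted_regions:
                continue
            rows = [tuple(self.amplitude(s, m, b.name) for b in self.bands
                          if not b.is_dc) for s in self.states]
            if any(r != rows[0] for r in rows[1:]):
                raise ValueError(
                    f"non-planted region {m} has state-dependent amplitudes")

    def amplitude(self, state: str, region: int, band_name: str) -> float:
        return float(self.amplitude_table.get((state, region, band_name), 0.0))

    def offsets(self) -> np.ndarray:
        """Per-region DC offset added before rectification.

        Defaults to 5·noise_sd plus twice the largest per-state total
        oscillation amplitude of the region, which keeps the rectification
        |offset + signal| in its linear regime (the spectral peaks stay at
        the oscillator frequencies) and makes the DC component dominant, as
        in the measured activity. State-independent by construction.
        """
        if self.dc_offset is not None:
            return np.full(self.n_regions, float(self.dc_offset))
        osc = np.zeros(self.n_regions)
        for m in range(self.n_regions):
            osc[m] = max(
                sum(self.amplitude(s, m, b.name)
                    for b in self.bands if not b.is_dc)
                for s in self.states
            )
        return 5.0 * self.noise_sd + 2.0 * osc

    # -- JSON round-trip -------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "n_regions": self.n_regions,
            "states": list(self.states),
            "bands": [
                {"name": b.name, "nu_min": b.nu_min, "nu_max": b.nu_max,
                 "nu_peak": b.nu_peak}
                for b in self.bands
            ],
            "amplitude_table": [
                {"state": s, "region": r, "band": b, "amplitude": a}
                for (s, r, b), a in sorted(self.amplitude_table.items())
            ],
            "background_exponent": self.background_exponent,
            "noise_sd": self.noise_sd,
            "planted_regions": sorted(self.planted_regions),
            "dt": self.dt,
            "dc_offset": self.dc_offset,
            "phase_tau": self.phase_tau,
            "phase_rms": self.phase_rms,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "Scenario":
        if isinstance(source, Path) or (isinstance(source, str)
                                        and not source.lstrip().startswith("{")):
            source = Path(source).read_text()
        d = json.loads(source)
        return cls(
            n_regions=int(d["n_regions"]),
            states=tuple(d["states"]),
            bands=tuple(BandDefinition(b["name"], b["nu_min"], b["nu_max"],
                                       b["nu_peak"]) for b in d["bands"]),
            amplitude_table={
                (e["state"], int(e["region"]), e["band"]): float(e["amplitude"])
                for e in d["amplitude_table"]
            },
            background_exponent=float(d["background_exponent"]),
            noise_sd=float(d["noise_sd"]),
            planted_regions=frozenset(d["planted_regions"]),
            dt=float(d["dt"]),
            dc_offset=d["dc_offset"],
            phase_tau=float(d["phase_tau"]),
            phase_rms=float(d["phase_rms"]),
        )


def desk_atlas() -> RegionAtlas:
    """20-region atlas used by the desk-scale scenario (8+8 cortical, 2+2
    internal, no brainstem)."""
    return make_atlas(8, 2, include_brainstem=False)


def scenario_for_atlas(atlas: RegionAtlas,
                       planted_regions: Sequence[int] | None = None,
                       states: Sequence[str] = ("rest", "Samatha", "Vipassana"),
                       bands: Sequence[BandDefinition] = SUBJECT1_BANDS,
                       base_amplitudes: Mapping[str, float] | None = None,
                       state_gains: Sequence[Mapping[str, float]] | None = None,
                       planted_base_factor: float = PLANTED_BASE_FACTOR,
                       noise_sd: float = 1.0,
                       background_exponent: float = 1.0) -> Scenario:
    """Scenario with baseline amplitudes everywhere and planted state gains.

    If ``planted_regions`` is None, the internal structures (plus the
    brainstem, if present) are planted. Planted regions cycle through the
    ``state_gains`` patterns in id order.
    """
    if planted_regions is None:
        planted_regions = atlas.ids_where(region_class=("internal", "brainstem"))
    base = dict(BASE_AMPLITUDES if base_amplitudes is None else base_amplitudes)
    gains = tuple(PLANTED_STATE_GAINS if state_gains is None else state_gains)
    planted = frozenset(int(r) for r in planted_regions)
    pattern_of = {m: gains[i % len(gains)]
                  for i, m in enumerate(sorted(planted))}
    table: dict = {}
    for s in states:
        for m in range(len(atlas)):
            if m in planted:
                g = planted_base_factor * pattern_of[m].get(s, 1.0)
            else:
                g = 1.0
            for b in bands:
                if b.is_dc:
                    continue
                amp = base.get(b.name, 0.0)
                table[(s, m, b.name)] = amp * g
    return Scenario(
        n_regions=len(atlas), states=tuple(states), bands=tuple(bands),
        amplitude_table=table, background_exponent=background_exponent,
        noise_sd=noise_sd, planted_regions=planted,
    )


def default_scenario() -> Scenario:
    """Desk-scale study conditions: 20 regions, the 4 internal ones planted."""
    return scenario_for_atlas(desk_atlas())


def _colored_noise(rng: np.random.Generator, shape: tuple[int, int],
                   exponent: float, sd: float, dt: float = 0.001,
                   plateau_hz: float = 1.0) -> np.ndarray:
    """Gaussian noise with power ∝ 1/ν^exponent above ``plateau_hz``,
    row-wise std = sd.

    The spectrum plateaus below ``plateau_hz``, emulating the high-pass
    preprocessing of physiological recordings; without the plateau the
    infra-slow components (periods comparable to the session length) would
    dominate the windowed means and have far too few independent cycles
    per session. The DC component is zeroed; the mean activity level is
    carried by the scenario offset instead.
    """
    n, T = shape
    if sd == 0:
        return np.zeros(shape)
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(T, dt)
    scale = np.zeros_like(f)
    scale[1:] = np.maximum(f[1:], plateau_hz) ** (-exponent / 2.0)
    x = np.fft.irfft(spec * scale, T, axis=1)
    std = x.std(axis=1, keepdims=True)
    std[std == 0] = 1.0
    return x * (sd / std)


def _ou_phase(rng: np.random.Generator, n: int, T: int, dt: float,
              tau: float, rms: float) -> np.ndarray:
    """Stationary Ornstein–Uhlenbeck phase paths, shape (n, T), in radians."""
    if rms == 0 or T == 0:
        return np.zeros((n, T))
    a = math.exp(-dt / tau)
    s = rms * math.sqrt(1.0 - a * a)
    eps = rng.standard_normal((n, T))
    phi0 = rms * rng.standard_normal(n)
    out, _ = lfilter([s], [1.0, -a], eps, axis=1, zi=(a * phi0)[:, None])
    return out


def simulate_brali(scenario: Scenario, state: str, duration_s: float = 60.0,
                   seed: int = 0, subject: str = "sim",
                   session: str = "A") -> BRALISeries:
    """Simulate one session's region activity matrix for the given state.

    Each region is the rectified sum of a DC offset, 1/f background noise,
    and one phase-drifting sinusoid per oscillatory band with amplitude
    taken from the scenario's (state, region, band) table. Reproducible
    bit-for-bit given the seed.
    """
    if state not in scenario.states:
        raise ValueError(f"unknown state {state!r}; scenario has "
                         f"{scenario.states}")
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    n = scenario.n_regions
    dt = scenario.dt
    T = int(round(duration_s / dt))
    rng = np.random.default_rng(seed)

    signal = _colored_noise(rng, (n, T), scenario.background_exponent,
                            scenario.noise_sd, dt)
    t = np.arange(T) * dt
    for band in scenario.bands:
        if band.is_dc:
            continue
        nu = band.nu_peak if band.nu_peak is not None else band.midpoint
        amps = np.array([scenario.amplitude(state, m, band.name)
                         for m in range(n)])
        phi0 = rng.uniform(0.0, 2.0 * np.pi, size=n)
        drift = _ou_phase(rng, n, T, dt, scenario.phase_tau,
                          scenario.phase_rms)
        signal += amps[:, None] * np.cos(
            2.0 * np.pi * nu * t[None, :] + phi0[:, None] + drift)

    values = np.abs(signal + scenario.offsets()[:, None])
    return BRALISeries(values=values, dt=dt, state=state, subject=subject,
                       session=session)


def simulate_dipoles(scenario: Scenario, atlas: RegionAtlas,
                     dipoles_per_region: int, state: str,
                     duration_s: float = 60.0, seed: int = 0) -> DipoleSeries:
    """Dipole-level surrogate whose per-region aggregate has the scenario's
    structure.

    Each region's activity is split equally across its dipoles, so summing
    intensities over a parcel recovers the region activity exactly.
    """
    if dipoles_per_region < 1:
        raise ValueError("dipoles_per_region must be >= 1")
    if len(atlas) != scenario.n_regions:
        raise ValueError("atlas size does not match scenario.n_regions")
    brali = simulate_brali(scenario, state, duration_s, seed)
    d = dipoles_per_region
    intensities = np.repeat(brali.values / d, d, axis=0)
    parcel_map = np.repeat(np.arange(len(atlas)), d)
    return DipoleSeries(intensities=intensities, parcel_map=parcel_map,
                        dt=scenario.dt, state=state)
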