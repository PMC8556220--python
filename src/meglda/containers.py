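"""Array containers passed between pipeline stages.

All containers validate their invariants at construction so that stage
preconditions fail early with a clear message rather than deep inside a
NumPy call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bands import BandDefinition


def _check_finite(a: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{what} contains non-finite values")


@dataclass
class BRALISeries:
    """Region-aggregated activity time series (one state, one session).

    ``values`` is the n_regions × T matrix of non-negative activity levels
    (summed dipole intensities per region); row order follows a
    :class:`~meglda.atlas.RegionAtlas`. ``dt`` is the sampling interval in
    seconds (≈1 ms).
    """

    values: np.ndarray
    dt: float = 0.001
    state: str = ""
    subject: str = ""
    session: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] < 1:
            raise ValueError("values must be an n×T matrix with T >= 1")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        _check_finite(self.values, "activity matrix")
        if np.any(self.values < 0):
            raise ValueError("activity levels must be non-negative")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples * self.dt


@dataclass
class DipoleSeries:
    """Dipole intensity time series ‖q_j(t)‖ with a region parcellation map.

    ``intensities`` is M × T (M source-space dipoles); ``parcel_map`` assigns
    each dipole to a region id.
    """

    intensities: np.ndarray
    parcel_map: np.ndarray
    dt: float = 0.001
    state: str = ""

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.parcel_map = np.asarray(self.parcel_map, dtype=int)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be an M×T matrix")
        if self.parcel_map.shape != (self.intensities.shape[0],):
            raise ValueError("parcel_map must have one entry per dipole")
        _check_finite(self.intensities, "dipole intensities")
        if np.any(self.intensities < 0):
            raise ValueError("dipole intensities must be non-negative")


@dataclass
class PeriodogramStack:
    """Bootstrapped one-sided periodograms, n_regions × p samples × K freqs.

    ``freqs`` is the one-sided grid ν_k = k/(NΔt), k = 0..⌊N/2⌋, so
    K = ⌊N/2⌋ + 1 for window length N (in samples).
    """

    values: np.ndarray
    freqs: np.ndarray
    window_length: int
    dt: float
    state: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("periodogram stack must be n×p×K")
        K = self.window_length // 2 + 1
        if self.values.shape[2] != K or self.freqs.shape != (K,):
            raise ValueError("frequency grid must have K = N//2 + 1 points")
        if self.freqs[0] != 0 or np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing from 0")
        _check_finite(self.values, "periodograms")
        if np.any(self.values < 0):
            raise ValueError("periodograms must be non-negative")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def delta_nu(self) -> float:
        """Grid spacing Δν = 1/(NΔt)."""
        return 1.0 / (self.window_length * self.dt)


@dataclass
class BandPowerMatrix:
    """n_regions × p sample matrix of band-integrated (or DC) powers.

    For oscillatory bands each entry is the DC-scaled integrated power
    Σ_k Φ(ν_k)/Φ(0)·Δν over the band; for the DC band it is Φ(0) itself
    (``normalized`` False).
    """

    values: np.ndarray
    band: BandDefinition
    normalized: bool
    state: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("band-power matrix must be n×p")
        _check_finite(self.values, "band powers")
        if self.normalized and np.any(self.values < 0):
            raise ValueError("normalized band powers must be non-negative")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


@dataclass
class PSDMatrix:
    """Power spectral density estimate per region (averaged periodograms).

    ``kind`` is ``"raw"`` (plain average over bootstrap samples) or
    ``"normalized"`` (each region divided by its zero-frequency value, so
    the ν = 0 entry is exactly 1).
    """

    values: np.ndarray
    freqs: np.ndarray
    kind: str
    state: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.kind not in ("raw", "normalized"):
            raise ValueError("kind must be 'raw' or 'normalized'")
        if self.values.ndim != 2 or self.values.shape[1] != self.freqs.shape[0]:
            raise ValueError("values must be n×K matching freqs")
        _check_finite(self.values, "PSD")
        if np.any(self.values < 0):
            raise ValueError("PSD values must be non-negative")
        if self.kind == "normalized" and not np.allclose(self.values[:, 0], 1.0):
            raise ValueError("normalized PSD must equal 1 at nu = 0")
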