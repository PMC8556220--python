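"""Dipole aggregation, bootstrap windowing, periodograms and band powers.

The spectral sample generation follows a bootstrap scheme: windows of
fixed length N are cut at uniformly random start positions (with
replacement) from the region activity time series, each window is Fourier
transformed row by row, and the squared transform magnitudes scaled by 1/N
form one periodogram sample per window. Averaging the samples estimates
the power spectral density; summing DC-scaled samples over a frequency
band yields the band-power sample matrices that feed the discriminant
analysis.

Periodograms are stored one-sided on the grid ν_k = k/(NΔt),
k = 0..⌊N/2⌋; the two-sided spectrum needed e.g. for Parseval checks is
recovered by mirroring the interior bins.
"""

from __future__ import annotations

import numpy as np

from .atlas import RegionAtlas
from .bands import BandDefinition
from .containers import (BandPowerMatrix, BRALISeries, DipoleSeries,
                         PeriodogramStack, PSDMatrix)

#: Relative tolerance for matching band edges to grid frequencies.
_EDGE_RTOL = 1e-9


def aggregate_dipoles(dipoles: DipoleSeries, atlas: RegionAtlas) -> BRALISeries:
    """Sum dipole intensities over each atlas parcel.

    The aggregate (rather than the average) is used so that activity
    patches of roughly invariant size are not biased towards small
    regions. Regions containing no dipole get an all-zero row.
    """
    n = len(atlas)
    if dipoles.parcel_map.size and (dipoles.parcel_map.min() < 0
                                    or dipoles.parcel_map.max() >= n):
        raise IndexError("parcel_map contains region ids outside the atlas")
    values = np.zeros((n, dipoles.intensities.shape[1]))
    np.add.at(values, dipoles.parcel_map, dipoles.intensities)
    return BRALISeries(values=values, dt=dipoles.dt, state=dipoles.state)


def draw_bootstrap_windows(series: BRALISeries, N: int, p: int,
                           seed: int | np.random.Generator = 0) -> np.ndarray:
    """Draw p random windows of length N; returns an n×p×N array.

    Start indices are drawn uniformly with replacement from {0, …, T−N}.
    """
    T = series.n_samples
    if N > T:
        raise ValueError(f"window length N={N} exceeds series length T={T}")
    if N < 1 or p < 1:
        raise ValueError("N and p must be positive")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    starts = rng.integers(0, T - N + 1, size=p)
    windows = np.lib.stride_tricks.sliding_window_view(series.values, N, axis=1)
    return np.ascontiguousarray(windows[:, starts, :])


def periodogram_stack(samples: np.ndarray, dt: float,
                      state: str = "") -> PeriodogramStack:
    """Periodograms Φ = |FFT(y)|²/N of each window, one-sided.

    The stored one-sided values are the raw |FFT|²/N bins (no doubling);
    the two-sided sum for Parseval-type identities counts interior bins
    twice.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 3 or samples.shape[2] < 2:
        raise ValueError("samples must be n×p×N with N >= 2")
    if not np.all(np.isfinite(samples)):
        raise ValueError("samples contain non-finite values")
    N = samples.shape[2]
    ft = np.fft.rfft(samples, axis=2)
    values = (ft.real ** 2 + ft.imag ** 2) / N
    freqs = np.fft.rfftfreq(N, dt)
    return PeriodogramStack(values=values, freqs=freqs, window_length=N,
                            dt=dt, state=state)


def estimate_psd(stack: PeriodogramStack, kind: str = "raw") -> PSDMatrix:
    """Average the periodogram samples; optionally scale by the DC value.

    ``kind="raw"`` returns the plain sample mean per region and frequency;
    ``kind="normalized"`` divides each region's PSD by its zero-frequency
    value so the result is the relative power density (1 at ν = 0).
    """
    psd = stack.values.mean(axis=1)
    if kind == "raw":
        return PSDMatrix(values=psd, freqs=stack.freqs, kind="raw",
                         state=stack.state)
    if kind != "normalized":
        raise ValueError("kind must be 'raw' or 'normalized'")
    dc = psd[:, 0]
    if np.any(dc <= 0):
        raise ValueError("zero DC power; cannot normalize PSD")
    return PSDMatrix(values=psd / dc[:, None], freqs=stack.freqs,
                     kind="normalized", state=stack.state)


def band_bin_mask(freqs: np.ndarray, band: BandDefinition) -> np.ndarray:
    """Boolean mask of grid frequencies inside the closed band interval.

    Edges coinciding with a grid point (to 1e-9 relative) are included on
    both sides, matching the closed intervals of the band table.
    """
    if band.is_dc:
        mask = np.zeros(freqs.shape, dtype=bool)
        mask[0] = True
        return mask
    tol = _EDGE_RTOL * max(abs(band.nu_min), abs(band.nu_max), 1.0)
    return (freqs >= band.nu_min - tol) & (freqs <= band.nu_max + tol)


def band_power_matrix(stack: PeriodogramStack,
                      band: BandDefinition) -> BandPowerMatrix:
    """Band-integrated DC-scaled power samples (or the DC matrix).

    For an oscillatory band: x = Σ_{ν_k ∈ [ν_min, ν_max]} Φ(ν_k)/Φ(0)·Δν
    with Δν = 1/(NΔt). For the DC band: x = Φ(0), unscaled.
    """
    if band.is_dc:
        return BandPowerMatrix(values=stack.values[:, :, 0].copy(), band=band,
                               normalized=False, state=stack.state)
    nyquist = stack.freqs[-1]
    if band.nu_min > nyquist:
        raise ValueError(f"band {band.name} lies beyond the Nyquist "
                         f"frequency {nyquist:g} Hz")
    mask = band_bin_mask(stack.freqs, band)
    if not mask.any():
        raise ValueError(f"no grid frequency inside band {band.name} "
                         f"[{band.nu_min}, {band.nu_max}] Hz at "
                         f"Δν = {stack.delta_nu:g} Hz")
    dc = stack.values[:, :, 0]
    if np.any(dc <= 0):
        raise ValueError("zero DC component in a periodogram sample")
    x = stack.values[:, :, mask].sum(axis=2) / dc * stack.delta_nu
    return BandPowerMatrix(values=x, band=band, normalized=True,
                           state=stack.state)


def band_power_matrices(stack: PeriodogramStack,
                        bands) -> dict[str, BandPowerMatrix]:
    """Band-power matrices for every band in ``bands``, keyed by name."""
    return {b.name: band_power_matrix(stack, b) for b in bands}


def detect_band_offset(psd_ref: PSDMatrix, psd_other: PSDMatrix, bands,
                       search_lo: float = 0.6,
                       search_hi: float = 1.15) -> float:
    """Median peak-frequency ratio (other/ref) over bands with a peak.

    For each band with a stated peak, the peak is located as the argmax of
    the region-median relative PSD inside a generous search interval
    [search_lo·ν_min, search_hi·ν_max]; the returned scale factor is the
    median ratio. An argmax landing on an interval boundary means no
    interior peak and is an error. Scaled band tables are obtained with
    ``BandDefinition.scaled``.
    """
    ratios = []
    for band in bands:
        if band.is_dc or band.nu_peak is None:
            continue
        peaks = []
        for psd in (psd_ref, psd_other):
            vals = psd.values
            if psd.kind == "raw":
                dc = vals[:, 0]
                if np.any(dc <= 0):
                    raise ValueError("zero DC power in PSD")
                vals = vals / dc[:, None]
            med = np.median(vals, axis=0)
            lo, hi = search_lo * band.nu_min, search_hi * band.nu_max
            idx = np.nonzero((psd.freqs >= lo) & (psd.freqs <= hi)
                             & (psd.freqs > 0))[0]
            if idx.size < 3:
                raise ValueError(f"search interval for band {band.name} "
                                 "contains too few grid points")
            k = idx[np.argmax(med[idx])]
            if k == idx[0] or k == idx[-1]:
                raise ValueError(f"no interior peak found in band "
                                 f"{band.name}")
            peaks.append(psd.freqs[k])
        ratios.append(peaks[1] / peaks[0])
    if not ratios:
        raise ValueError("no band with a stated peak frequency")
    return float(np.median(ratios))
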