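# Methods

`meglda` separates annotated brain states (eyes-closed rest, focused-
attention meditation "Samatha", open-monitoring meditation "Vipassana")
from region-aggregated MEG source time series, and identifies the brain
regions that drive the separation. This note documents the model, the
parameters that matter, the synthetic data the package is validated on,
and the numerical choices.

## Pipeline

1. **Region aggregation.** Dipole intensity time series ‖q_j(t)‖ on a
   source space are summed (not averaged) over each atlas parcel to give
   the region activity vector a(t) ∈ ℝⁿ; summing avoids biasing activity
   toward small regions when active patches have roughly invariant size.
   The default atlas has n = 165 parcels: 74 cortical regions per
   hemisphere, 8 internal structures per hemisphere, and the brainstem.
2. **Bootstrapped periodograms.** Windows of N samples are cut at start
   positions drawn uniformly *with replacement* from the session
   (sampling interval Δt ≈ 1 ms). Each window is Fourier transformed row
   by row and Φ = |FFT(y)|²/N is evaluated on the one-sided grid
   ν_k = k/(NΔt). Averaging the p samples estimates the PSD; the DC value
   Φ(0) is the average-power (total power) component.
3. **Band powers.** For each band I = [ν_min, ν_max] (θ 3–7.5, α 7.5–12,
   β 12–20, γ 25–40 Hz; closed intervals) the sample entry is
   x = Σ_{ν_k∈I} Φ(ν_k)/Φ(0) · Δν. DC scaling removes arbitrary
   per-session amplitude scaling. The DC matrix itself (x = Φ(0)) is kept
   separately and excluded from region tallies by default. A second band
   table shifted by the between-subject peak-alignment factor (median
   edge ratio 0.85) is shipped; `detect_band_offset` measures that factor
   from two PSD stacks as the median θ/α/β peak-frequency ratio.
4. **Regularized LDA.** For k state-annotated n×p matrices, the within-
   and between-cluster spread matrices are S_w = Σ S^(i) and
   S_b = Σ p_i (x̄^(i)−x̄)(x̄^(i)−x̄)ᵀ. Directions maximize
   H_δ(q) = qᵀS_b q / qᵀ(S_w+δI)q via the symmetric-definite generalized
   eigenproblem S_b q = λ(S_w+δI)q; at most k−1 eigenvalues are positive
   and the corresponding eigenvectors (unit 2-norm, not orthogonalized)
   are the separating directions.
5. **Overlap.** The 2-D LDA components of all clusters are histogrammed
   on one shared rectangle Ω (pooled bounding box, expanded by a 1e−9
   relative margin so maximal points land in the closed last pixel), with
   the per-axis bin count chosen by Bayesian optimal binning on the
   pooled axis values. Pairs are scored by the Bhattacharyya index
   BI = Σ√(h_i h_j) ∈ [0,1]; the mean pairwise index (MPBI) over the
   k(k−1)/2 pairs is the separation score. Scanning MPBI over window
   lengths selects N: separation improves with longer windows and is
   essentially complete at N = 2000 (2 s).
6. **Region selection.** A region is a significant separator when at
   least one separating vector has ≥10% of its maximum amplitude at that
   region. Sequential filtering discards the sub-threshold rows, reruns
   the LDA on the reduced data (per band), and repeats — by default 3
   rounds, mirroring the observation that separation degrades gracefully
   but is not lost. With two independent sessions per state, the 2³ = 8
   session combinations give a per-region tally ∈ {0..8} of how often the
   amplitude rule fires. Analyses can be restricted to one hemisphere,
   the cortical regions, or the internal structures (the latter includes
   the brainstem: 8+8+1 = 17 regions on the default atlas).

## Key parameters

| parameter | default | meaning |
|---|---|---|
| N (window length) | 2000 samples (2 s) | bootstrap window; chosen by the MPBI scan |
| p (samples) | 10 000 full scale; 500–1000 in tests/desk runs | bootstrap periodograms per state |
| δ (regularization) | 1e−6 · trace(S_w)/n | ridge keeping S_w + δI invertible; falls back to the S_b scale if S_w = 0 |
| threshold_fraction | 0.1 | amplitude rule: 10% of a vector's max component; ties retained |
| positive-λ tolerance | 1e−10 · λ_max | eigenvalues below it count as zero |
| m_max | 200 | cap of the optimal-binning scan per axis |
| separation threshold | 0.05 | MPBI at or below which a window "completely separates" |

The study never states δ; the trace-scaled default keeps H_δ scale-
equivariant (scaling the data by c and δ by c² leaves directions
unchanged). Only the top two directions feed the 2-D overlap and plots
even when k > 3; the full set is retained in `LDAResult`.

## Synthetic study conditions

The recordings the method was developed on are not redistributable, so
`meglda.synthetic` generates surrogate sessions. Each region is the
rectified sum |offset + background + oscillations| of:

* **1/f background** with spectral exponent 1.0 and unit standard
  deviation, plateaued below 1 Hz. The plateau emulates the high-pass
  stage of physiological preprocessing; without it, infra-slow components
  with only a handful of independent cycles per 60 s session dominate the
  windowed means and contaminate the DC normalization with spurious
  correlated fluctuations.
* **Band oscillators**: one sinusoid per band at the band's peak
  frequency (γ: band midpoint), with Ornstein–Uhlenbeck phase drift
  (τ = 0.5 s, rms 0.5 rad, ≈1 Hz linewidth). This keeps peak frequencies
  exactly controllable — a filtered-noise realization would not — while
  giving realistic finite line widths. Baseline amplitudes θ 1.0, α 1.5,
  β 0.8, γ 0.5 (arbitrary units).
* **DC offset** 5·noise_sd + 2·(largest per-state total oscillation
  amplitude of the region). Tying the offset to the oscillation budget
  keeps the rectification in its linear regime, so spectral peaks stay at
  the oscillator frequencies and the DC component dominates, as in
  measured activity; taking the max over states makes the offset
  state-independent, so non-planted regions have state-independent
  DC-normalized band powers by construction.

The desk-scale scenario has 20 regions (8 cortical per hemisphere, 2
internal per hemisphere) sampled for 60 s at 1 kHz. The 4 internal
regions are *planted*: their amplitudes differ between states. Two design
choices matter here:

* Planted regions carry a baseline factor 0.5 relative to cortical
  regions (deep structures aggregate less dipole amplitude than large
  cortical parcels).
* Planted regions alternate between two modulation patterns — one
  subgroup gains ×1.75 amplitude during Samatha, the other during
  Vipassana (rest is the reference). The three cluster means then span a
  well-conditioned two-dimensional subspace of the planted rows, so both
  separating directions are driven by planted structure. A single shared
  pattern would make the between-cluster spread (nearly) rank-1 over the
  planted rows and leave the second direction to fit sampling noise.

**What the generator does not emulate**: volume conduction / source
leakage between regions, non-stationarity across a session, artifacts,
inverse-solution bias, and any realistic amplitude distribution of the
activity values (the rectified-Gaussian form is a stand-in, not an
inference about real data). Passing tests therefore demonstrate the
correctness and statistical behavior of the *pipeline*, not claims about
real recordings.

**A known statistical limitation** worth stating explicitly: a 60 s
session contains only T/N ≈ 30 effectively independent positions of a
2000-sample window, so the empirical correlation between any two regions'
band-power samples is ~1/√30 ≈ 0.15 for a given session, regardless of
effect size or p. Propagated through S_w⁻¹, this mixes components of
order 10% of the maximum amplitude into the separating vectors. In
consequence the single-pass 10% rule tags many non-signal regions (their
session tallies have medians well above 1), even though sequential
filtering reliably retains all planted regions and the planted tallies
are maximal. Cleanly sparse single-pass selections would require roughly
10× longer sessions.

## Numerical choices

* Band membership is a closed interval test with 1e−9 relative edge
  tolerance. Adjacent bands sharing a printed edge (α/β at 12 Hz) both
  include the shared grid bin; partitions used to check additivity must
  cut between grid points.
* One-sided periodogram storage; Parseval-type identities reconstruct the
  two-sided sum by doubling interior bins.
* `estimate_psd` normalizes after averaging (PSD(ν)/PSD(0) per region).
* Eigenvector signs are fixed by making each direction's largest-
  magnitude component positive (reproducible tallies).
* Degenerate inputs: identical clusters return zero directions (valid
  result); the overlap of a result with no directions is defined as 1;
  constant samples get a single histogram bin; sequential filtering stops
  (does not fail) when fewer than 2 regions would remain.
* Bootstrap draws are with replacement; whether the original procedure
  replaces is unstated, and at p ≫ T/N the distinction is immaterial.
* The periodogram uses the complex-exponential FFT definition throughout
  (the cosine-transform variant mentioned alongside it would change
  nothing downstream, since all formulas are stated in FFT terms).

## Problem sizes used in the shipped checks

Tests and `scripts/acceptance.py` run the desk scenario with p = 500
(recovery/tally, 50 replicates) and p = 1000 (window scan over
N ∈ {200, 400, 800, 1200, 2000}); full-scale runs (n = 165, p = 10 000)
use the same code paths via `PipelineConfig`.
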