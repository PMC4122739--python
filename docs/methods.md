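# Methods

## Model and estimators

All measures operate on per-trial, per-frequency Fourier coefficients of two
channels, written `A_k(f) e^{jφ_k(f)}` and `B_k(f) e^{jθ_k(f)}` for trials
`k = 1..N`. The coefficients come from a *direct* spectral estimator: each
trial segment is multiplied by a single data taper and transformed with an
unpadded FFT, so the frequency spacing is the reciprocal epoch duration
(5 Hz for the default 200-ms epochs). Single-taper estimation maximizes
frequency resolution and gives the estimator its characteristic sampling
statistics — for a noisy signal the coefficient is asymptotically a 2-D
isotropic complex Gaussian, so across trials the amplitude is Rayleigh
(CV = √(4/π − 1) ≈ 0.523) and the power exponential (CV = 1). Those
statistics are not a nuisance here; they are what the bias theory is about.

The six measures (coherence; phase coherence / PLV; amplitude coherence;
amplitude cross-correlation; random-phase coherence; pairwise phase
consistency) are defined in `cohbias.measures`. Two definitional choices
deserve emphasis:

- **Random-phase coherence** replaces the phase difference of *each trial*
  with an independent uniform draw on [−π, π] (independent per frequency as
  well). A single draw shared across trials would leave the phasor sum
  coherent and collapse the measure onto amplitude coherence, destroying its
  purpose of isolating the amplitude contribution at realistic scale.
- **PPC** is computed on per-trial relative phases `δ_k = θ_k − φ_k`,
  averaging `cos(δ_j − δ_k)` over all trial pairs. Formulations that pair
  channel phases across *different* trials mix the marginal phase
  distributions of the two channels into what should be a statement about
  their trial-by-trial relationship; the per-trial-relative-phase form is
  the one with the unbiasedness property the measure exists for.

Undefined cases (an all-zero amplitude vector, zero amplitude variance for
the cross-correlation, fewer than two trials for PPC) raise typed errors
rather than returning 0, so a pipeline cannot silently average dead channels.

## Bias laws

Under uniform phases and Rayleigh amplitudes the expected values are, for
large N:

- `E[PLV] = sqrt(π/(4N)) = 0.8862…/√N` — the mean modulus of an N-step
  planar random walk;
- `E[C] = E[PLV]` when the two channels' amplitudes are independent (the
  amplitude weights decouple from the phase resultant);
- `E[C] = √2 · sqrt(π/(4N))` when the amplitudes are equal, because the
  resultant is then weighted by `A²` ~ exponential and
  `E[W²]/E[W]² = 2` for an exponential weight `W`.

The √2 is worth a note: informal accounts sometimes state that perfect
amplitude correlation "doubles" the bias. The factor 2 applies on the
*squared*-coherence scale; on the coherence scale the factor is √2, which a
20,000-replicate Monte-Carlo oracle in the test suite confirms
(0.249 measured vs 0.251 = √2·sqrt(π/100) at N = 25).

`sqrt(π/(4N))` itself is asymptotic. The exact expectation for finite N sits
slightly above it: +0.005 at N = 5, +0.0005 at N = 25, negligible beyond
(measured against a 2×10⁶-replicate oracle). Tests therefore hold N ≥ 25 to
a strict 3-standard-error comparison with the formula but check N = 5
against an exact-expectation oracle, with the formula required only to
*describe* the simulation to within 0.01.

For von Mises phase differences with concentration κ the true phase
coherence is `I₁(κ)/I₀(κ)`, evaluated with exponentially scaled Bessel
functions so it remains finite for κ well beyond 700. When phases and
amplitudes are independent, coherence factorizes for large N into
`C ≈ C_amp · C_phase`; with independent Rayleigh amplitudes `C_amp = π/4`,
so the independent-amplitude coherence curve tracks `(π/4)·I₁(κ)/I₀(κ)`.
The factorization is itself asymptotic in the phase-coherence level: at
κ = 2 (PLV ≈ 0.70, N = 25) the simulated coherence sits ≈ 0.018 above the
product, shrinking to ≈ 0.010 by κ = 8; the 0.02 agreement asserted in the
acceptance tests is therefore tight, not slack.

## Simulations

Ensemble simulations draw the *relative* phase from a von Mises distribution
(numpy's exact Best–Fisher rejection sampler; κ = 0 handled as uniform) and
assign it to channel B with channel A fixed at phase 0 — absolute phases
enter no measure, so the convention is free. Amplitudes are Rayleigh with
scale σ = 1; every asserted quantity is invariant to σ, so the scale is
arbitrary. Coupling modes: `independent`, `equal` (channel B's amplitude
vector is channel A's), and a Gaussian `copula` with tunable correlation for
intermediate coupling (a testing convenience; the two named modes are the
extremes of interest). Phases and amplitudes are mutually independent.

The experiment drivers (`run_fig2_experiment`, `run_bias_vs_trials`) are
vectorized over replicates through the same reduction kernels the scalar
measures use, so the Monte-Carlo means are means of exactly the quantity the
per-ensemble API computes. Default replicate counts are 20,000; the κ-sweep
acceptance check runs at 20,000 as well (a few seconds). All randomness
flows through one `numpy.random.Generator` per call; equal seeds give
bit-identical outputs.

`synth_sinusoid_trials` realizes the same draws as time-domain sinusoid
pairs so the full path — taper, FFT, measure at the target bin — can be
checked against the direct ensemble statistics; with a rectangular taper and
an on-bin frequency the agreement is exact to floating-point error.

## Synthetic grid data

`generate_grid_dataset` emulates a 10×10 microelectrode array (400 µm pitch,
2 kHz sampling, trials spanning −500..+500 ms around stimulus onset) with
three ingredients:

1. a 1/f^slope background (slope 2 by default, the typical LFP power-law
   exponent in the 1–3 range), spatially correlated across channels with an
   exponential kernel `exp(−d/source_corr_length)`;
2. a stimulus-window narrowband gamma component at 50 Hz whose per-trial
   complex coefficient is a channel-correlated complex Gaussian — hence
   Rayleigh amplitudes and phases whose trial-to-trial correlation decays
   with distance, the coupling structure the measures are designed to
   dissect;
3. volume conduction as premultiplication by a row-normalized
   `exp(−d/mixing_length)` mixing kernel (length 0 disables mixing).

A ground-truth sidecar JSON (generator parameters, mixing matrix, source
correlation kernel) is always written next to the HDF5 file, so pipeline
tests assert against known structure. What the generator does *not* emulate:
line noise and monitor-refresh artifacts (the pipeline's noise-frequency
flags are exercised on the frequency grid, not on injected artifacts),
evoked transients, non-stationarity within epochs, electrode impedance
variation, and any physiological 1/f deviation. Passing tests on this data
show the estimators and pipeline behave as the theory predicts under the
model's assumptions — not that real recordings satisfy those assumptions.

## CSD

The 2-D current source density subtracts the mean of the four one-pitch
lattice neighbors from each electrode. Conductivity and the 1/d² factor are
omitted as common positive scalings that cancel in every coherence-type
measure. Edge electrodes are excluded by default (an optional Vaknin-style
padding replicates the center potential for missing neighbors, off by
default because it invents border data). Neighbor lookup tolerates lattice
deviations up to pitch/100. Two caveats are inherent to the construction:
CSDs one pitch apart share a −¼ term of each other's center potential and
are therefore negatively correlated even for independent noise, and any
affine spatial field — not just a common mode — is annihilated.

## Pipeline choices

Epoch windows are half-open `[start, end)` in ms relative to stimulus onset
(defaults: baseline −300..−100 ms, stimulus 200..400 ms). Distance bins are
half-open in mm; defaults span one pitch to ~4 mm. Noise frequencies
(60 Hz and harmonics, 100/200 Hz refresh) are *flagged* within half a
frequency bin, never removed. With per-trial orientation labels, measures
are computed per orientation and arithmetically averaged (not Fisher-z
averaged — the measures are bounded and the averaging convention is part of
the measure definition here); pooling is available as a flag, and for trials
identical across orientations the two agree exactly for the deterministic
measures (PPC and random-phase coherence change with trial count by
construction). Every run can write a manifest (config echo, seed, per-bin
pair counts, excluded channels) alongside the tidy CSV.

## Numerical conventions

- Tapers are normalized to unit energy, making white-noise power levels
  taper-independent; the Slepian taper uses time-bandwidth product 1
  (single-taper convention) and the rectangular taper is available for
  exact on-bin oracles.
- The phase of an exactly-zero Fourier coefficient is defined as 0.
- PPC is evaluated through the resultant identity
  `Σ_{j<k} cos(δ_j−δ_k) = (|Σ e^{jδ}|² − N)/2`, O(N) per frequency and
  algebraically identical to the pairwise sum.
- Goodness-of-fit in the distribution diagnostics is the Kolmogorov–Smirnov
  distance: power is scaled by its across-trial mean and compared against a
  unit-mean exponential; amplitude is compared against a Rayleigh whose
  scale is fitted from the mean amplitude.

## Problem sizes

Test-suite and acceptance computations use 10,000–20,000 Monte-Carlo
replicates for ensemble statistics, 50,000–100,000 trials for the
white-noise CV checks, and 4×4 to 6×6 grids with 25–30 trials for pipeline
and CSD properties; these sizes put Monte-Carlo standard errors one order of
magnitude below every asserted tolerance.

## Known limitations

- No multitaper averaging, jackknife confidence intervals, spectrograms, or
  artifact rejection; one taper, one epoch per window.
- No spike-field coherence and no phase-lag index.
- The analysis pipeline reads the package's own HDF5/CSV containers only;
  vendor formats must be converted upstream.
- The grid generator is a statistical emulator, not a biophysical forward
  model; its ground truth is the coupling structure it imposes, not cortical
  geometry.
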