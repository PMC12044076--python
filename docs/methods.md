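# Methods

This note documents the models, numerical choices and validation logic of
`sleepcrit`, in the order data flows through the package.

## Synthetic study generator (`synthetic_data`)

The generator emulates a paired two-condition sleep study: 40 subjects
(22 young, 18 middle-aged) by default, two recordings each ("placebo" and
"caffeine" nights), 20 channels of the 10–20 montage, 256 Hz, 20-s epochs
labeled NREM or REM in a 3:1 ratio. Signals are built by inverse-spectral
synthesis: complex Gaussian Fourier coefficients are shaped by
`f^(−χ/2)` and inverse-transformed, giving exact control of the aperiodic
exponent χ. Oscillatory peaks are added as band-limited Gaussian noise
whose spectral bump rises a prescribed number of log10 units above the
aperiodic line at its center.

Defaults (per stage): NREM χ₀ = 1.6, offset 2.0 log10 µV²/Hz, peaks at
1.2 Hz (slow/delta, below the 3 Hz fit floor, height 0.6), 13.5 Hz
(spindle/sigma, 0.8) and 20 Hz (beta, 0.15); REM χ₀ = 1.4, offset 1.5,
theta/alpha peaks and the same small beta peak. These exponents place the
raw-signal DFA near 1.3 (NREM) and 1.2 (REM) through the mapping
α = (χ+1)/2, the range typical of non-stationary sleep EEG. Epoch counts
default to 60 NREM / 20 REM per recording — the 3:1 stage ratio of real
overnight data at a size whose full study fits comfortably in memory;
paper-scale counts (~1400/480) are supported by generating one subject at
a time (`generate_subject`) and writing EDFs to disk.

The condition effect is parameterized as Δχ (default 0.3, caffeine
flatter) plus per-band peak-height changes (δ −0.15, θ −0.10, α −0.10,
σ 0, β +0.15 log10 units). Between-subject variability comes from
truncated-Gaussian draws around each parameter (SD 0.15 for χ, 0.2 for
offset, 0.08 for peak heights), shared across the two nights of a subject
so the paired sign-flip test has its exchangeability structure. No study
effect sizes are published in a reusable form, so these values were chosen
once for testability — large enough to be recoverable at 8–40 subjects,
small enough that recovery is not trivial — and are not revisited.

Deliberate simplifications: long-range temporal correlations are *not* an
independent dial. For spectrally synthesized noise DFA obeys
α = (χ+1)/2, so a second LRTC knob could contradict the spectral ground
truth; the Δχ effect therefore moves the aperiodic slope and DFA together
(flatter ⇒ lower α), which is also the empirically coherent direction.
Channel noise is white at 1% of signal SD — a stronger sensor floor
visibly flattens steep (χ≈2) spectra above 20 Hz and would bias exponent
recovery. Peaks are kept narrow (widths ≤ 1 Hz) so the spectral
parameterization can separate them from the line at single-epoch SNR.
The generator produces no sleep microstructure (no K-complexes or
spindle waveforms, no stage transitions within an epoch), no artifacts,
no volume conduction and no channel covariance beyond shared subject
parameters — so passing tests demonstrate correctness of the analysis
machinery, not robustness to every pathology of clinical EEG.

## Preprocessing (`io_preprocess`)

Recordings are stored as (epoch × channel × sample) arrays with one stage
label per 20-s epoch. EDF files are read through `mne`; writing uses a
minimal 16-bit EDF writer with 1-s records (round-trip error is bounded by
the 16-bit quantization step, asserted in tests against mne's independent
reader). Classic R&K substages S1–S4 collapse to NREM on read.

Band-pass filtering is a 4th-order Butterworth (0.5–32 Hz) applied
forward–backward per epoch (zero phase, effective order 8). Padding uses
constant extension: with the steep 0.5 Hz high-pass, the default odd
extension rings at the epoch edges (a 50 Hz tone leaves ~12% residual RMS
from edge transients; constant padding brings it to ~5%, and passband
amplitude/DC-rejection contracts are unaffected).

Artifact rejection is a fixed ±300 µV amplitude threshold across
channels — a deterministic surrogate for visual screening, applied to
whole 20-s epochs only. Epoch-count equating between two recordings
subsamples the larger side without replacement, per stage, reproducibly
from a seed.

## Spectral model (`spectral`)

Welch PSDs use 4-s Hann windows with 50% overlap (nine segments per 20-s
epoch, 0.25 Hz resolution, one-sided density normalization — Parseval is
asserted to 10%).

The aperiodic fit follows the spectral-parameterization scheme: a robust
line fit in log10-power vs log10-frequency (OLS, refit on the 60% of
points with smallest residuals so peaks cannot tilt the line), then
iterative Gaussian peak extraction on the residual (largest positive
residual seeds center/height; width initialized from the half-height
crossing and clipped to [0.5, 12] Hz; bounded least squares), capped at
five peaks. Two numerical choices differ from the common reference
implementation, both adopted after measuring recovery on synthetic
spectra:

* the peak-detection stop threshold is 2.5 × a MAD-based noise SD
  estimated **once** from the initial residual (plus an absolute floor of
  0.15 log10 units). Re-estimating the residual SD after each subtraction
  lets the threshold collapse and admits spurious peaks, which biased the
  recovered exponent by ≈ +0.1 at single-epoch SNR.
* the final aperiodic line is refit on the spectrum with fitted peak
  neighborhoods (center ± 2.5 widths) *excluded* rather than subtracted;
  exclusion is insensitive to imperfect peak shapes. If exclusion leaves
  fewer than 10 bins, the subtraction refit is used as fallback.

With these settings the mean recovered exponent is within 0.01 of truth
for χ ∈ {0.5, 1, 1.5, 2}, with or without an injected oscillation, and
the fit is exact on noiseless power-law spectra. The aperiodic component
is a pure line in log–log space (no knee), matching the 3–32 Hz fit
range. Corrected band power is the mean log10 residual over band bins
(the flattened-spectrum convention); linear-space subtraction and
uncorrected means are available as documented options. The delta band
uses the extrapolated line only — no peaks are fitted below 3 Hz.

## Complexity metrics (`complexity`)

* **SampEn(m=2, r=0.2·SD)**: Chebyshev distance, self-matches excluded,
  the same template population (the first n−m windows) at lengths m and
  m+1. Implemented with a k-d tree pair count; tests assert exact
  equality with a naive double-loop oracle. When no pair still matches at
  length m+1 the value is +∞ — a flag, not an error — and flagged epochs
  are skipped by downstream averaging. Zero-variance input raises, since
  the tolerance degenerates.
* **Spectral entropy**: Shannon entropy of the 0.5–32 Hz PSD normalized
  as a probability distribution, divided by log(#bins) to lie in [0, 1].
* **SpecSampEn**: SampEn applied to the ordered sequence of linear-power
  PSD bins over 0.5–32 Hz (log-power mode behind a switch). Sensitive to
  local spectral patterns, unlike the permutation-invariant Shannon form.
* **LZc**: median binarization with a fixed tie rule (strictly greater
  than the median → 1, so integer-quantized EDF data stay deterministic),
  LZ76 phrase count c(n) normalized by c(n)·log₂(n)/n. The production
  parser uses C-level substring search; tests cross-check it against an
  independent Kaspar–Schuster scan, exhaustively on short strings.
* **Permutation entropy** (order 3, delay 1, normalized by log 3!):
  computed and stored but excluded from the 11-feature canonical set;
  its parameters are conventional defaults, not study-derived.

All time-domain metrics are invariant under positive affine rescaling of
the signal (asserted in tests).

## DFA (`criticality`)

The profile (cumulative sum of the mean-subtracted signal) is cut into
non-overlapping windows at ~16 log-spaced sizes in [16, n/4]; segments
are taken from both ends of the profile so trailing samples contribute
(this also halves the variance of F(n) at the largest sizes); each
segment is linearly detrended (DFA-1) and α is the OLS slope of
log F(n) vs log n. Calibration: white noise α = 0.50 ± 0.05 (mean over
100 epochs), Brownian paths 1.5, spectrally synthesized fGn recovers its
Hurst exponent within 0.1. F(n) for a single realization can dip at the
largest window sizes (few segments); only the ensemble-mean curve is
strictly monotone.

Band-limited DFA filters to the band, takes the Hilbert amplitude
envelope, trims 1 s per side (filtfilt/Hilbert edge transients), and runs
DFA on the envelope. The envelope of band-limited noise is smooth on
scales below the filter's memory (~2/bandwidth seconds) regardless of any
neural correlation, so the default minimum window is raised to
2·fs/bandwidth samples; even so, the crossover decays slowly — on white
noise the envelope α reaches 0.55 only with ≥ 80-s signals and 2-s
minimum windows, which is what the no-LRTC calibration test uses. A
constant envelope (pure in-band tone) raises a documented
"zero fluctuation" error.

## Feature table (`feature_table`)

Eleven canonical features per (epoch, channel): five corrected band
powers, SpecEn, SampEn, SpecSampEn, LZc, DFA α, aperiodic slope. Metric
failures on degenerate epochs become NaN cells, excluded from the
subject-level arithmetic mean (a cell with zero valid epochs is an
error, not a silent NaN). The z-transform is strictly within-subject:
for each (subject, feature), the mean and SD of that subject's
epoch-level values — pooled across channels, epochs and *both*
conditions — standardize that subject's subject-level values. Pooling
across conditions preserves the within-subject condition contrast
(per-condition pooling would erase it; a switch exposes that variant),
and no cross-subject statistic enters any subject's transform, so
train/test subjects in the decoding analyses remain independent by
construction (asserted by a perturbation test).

## Inference (`stats_inference`)

Paired pseudo-T per channel: mean difference divided by (SE + ε) with
ε = 10% of the median SE across channels — enough to stabilize
near-degenerate channels, negligible for typical ones (ε = 0 gives the
plain paired t). The null flips the sign of each subject's whole
difference vector, preserving cross-channel covariance; each permutation
contributes max |t| across channels, and corrected p-values use the
add-one Monte-Carlo form (1 + #{null ≥ |t|})/(n_perm + 1) with 10⁴ draws
by default. For ≤ 14 subjects all 2ⁿ sign patterns are enumerated and
p-values are exact. Calibration tests hold the family-wise error rate at
0.05 within the binomial 95% interval over 500 null datasets of the full
design size (40 × 20, 1000 flips — the statistic is vectorized over
permutations, so this costs seconds). Age contrasts are Welch t-tests on
the per-subject condition differences with Benjamini–Hochberg correction
across channels.

## Decoding (`decoding`)

All cross-validation is grouped by subject (both nights of a subject stay
in one fold; an internal assertion fires on any leakage). Single-feature
decoding: per channel, grouped 10-fold CV accuracy of an RBF-SVM (C = 1,
scale gamma) or LDA on the z-scored subject-level feature; significance
from 1000 label permutations that swap the two condition labels within a
random subset of subjects (the exchangeable unit of the paired design),
max-statistic corrected across channels (across-features correction is
possible by stacking, but not the default). Single-epoch decoding uses
LDA with automatic shrinkage (lsqr solver — epoch-level covariance is
noisy) scored by balanced accuracy, which is exactly 0.5 for any constant
classifier under class imbalance. The multi-feature random forest runs a
nested loop: each repeat holds out 5 random subjects, tunes
{trees 100/300, depth ∞/5/10, features √p/0.2p} by grouped 7-fold grid
search on the rest, scores on the held-out subjects and records impurity
importances (which sum to 1 per fitted model). The default is 25 repeats;
published-scale analyses would use 1000 (`n_rf_repeats`).

## Validation scales

Test and calibration problem sizes are the package's own choices, picked
so the whole suite runs on a laptop-class single core: 100 × 5120-sample
epochs for DFA anchors; 50–100 epochs per χ for fit recovery; 500 null
datasets at full design size for FWER; 40 null datasets for
permutation-p uniformity (Kolmogorov–Smirnov); and an 8-subject,
6-channel, 128 Hz, 20-epoch synthetic study for end-to-end effect
recovery (the planted sign pattern must appear on ≥ 90% of channels and
planted features must carry > 60% of random-forest importance mass).

## Known limitations

* Absolute DFA α and SpecEn values depend on window schemes and
  normalization conventions; condition *contrasts* are the validated
  quantities.
* The artifact-rejection surrogate (fixed amplitude threshold) does not
  reproduce visual scoring decisions.
* Welch log-PSD noise at nine segments puts a floor (~0.15 log10 units,
  2.5 MAD) on detectable oscillatory peaks in single epochs; weaker peaks
  are absorbed into band-power residuals but not reported as peaks.
* The EDF writer covers the subset of the format the pipeline emits
  (uniform integer sampling rates, 1-s records).
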