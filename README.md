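# sleepcrit

Complexity and criticality analysis of sleep EEG, built around a paired
two-condition (stimulant vs. placebo) within-subject design.

Polysomnographic studies increasingly characterize sleeping brain activity
not only by oscillatory band power but by information-theoretic and
scale-free properties: sample entropy of the raw trace, entropy of the
power spectrum, Lempel–Ziv compressibility, long-range temporal
correlations (DFA), and the aperiodic 1/f exponent of the spectrum — the
last two serving as indices of how close cortical dynamics sit to a
critical regime. `sleepcrit` implements this feature set together with the
statistical machinery such studies need (paired sign-flip permutation
tests with maximum-statistic FWER control, subject-grouped cross-validated
decoding) and a synthetic sleep-EEG generator with known ground truth, so
the entire pipeline is verifiable end to end without access to clinical
recordings.

## The model

The power spectrum of each 20-s EEG epoch (Welch, 4 s Hann windows, 2 s
overlap) is decomposed over 3–32 Hz as

```
log10 P(f) = b − χ · log10 f + Σ_k  h_k · exp(−(f − c_k)² / 2w_k²)
```

an aperiodic line with offset `b` and exponent `χ` (reported positive;
smaller = flatter = relatively more excitation) plus at most five Gaussian
oscillatory peaks with widths in [0.5, 12] Hz. Band powers (δ 0.5–4,
θ 4–8, α 8–12, σ 12–16, β 16–32 Hz) are means of the flattened spectrum
`log10 P(f) − (b − χ log10 f)`, with the line extrapolated below 3 Hz for
the delta band.

Complexity metrics per epoch and channel: SampEn(m=2, r=0.2·SD) =
−log(A/B) with Chebyshev distance and self-matches excluded; Shannon
spectral entropy normalized to [0, 1]; SpecSampEn (SampEn applied to the
ordered PSD bin sequence); Lempel–Ziv complexity of the median-binarized
signal, normalized by log₂(n)/n. Criticality metrics: DFA-1 scaling
exponent α (0.5 = white noise, >0.5 persistent, >1 non-stationary) on the
band-passed signal, optionally on Hilbert amplitude envelopes of
individual bands, and the aperiodic exponent χ.

Inference contrasts the two conditions per channel with a paired
permutation pseudo-T (sign flips applied jointly across channels;
corrected p from the permutation distribution of the maximum |t|), plus
paired Cohen's d and Welch t-tests with Benjamini–Hochberg FDR for
age-group contrasts. Decoding uses subject-grouped cross-validation
(RBF-SVM / LDA per channel with label-permutation significance, balanced
accuracy for single-epoch LDA, and a 220-feature random forest with
nested grouped CV and impurity importances).

## Worked example

Simulate a small paired study, extract features, and test the planted
slope flattening:

```python
import dataclasses, pandas as pd
from sleepcrit import synthetic_data as sd, feature_table, stats_inference

cfg = sd.SyntheticStudyConfig(
    n_subjects=8, n_young=4, n_middle=4,
    channel_names=("F3", "F4", "C3", "C4", "O1", "O2"),
    fs=128.0, n_nrem=20, n_rem=2, seed=99)
recs, truth = sd.generate_study(cfg)

epoch = pd.concat([feature_table.extract_features(r, "NREM") for r in recs],
                  ignore_index=True)
subject = feature_table.average_by_subject(epoch)
z = feature_table.z_transform(subject, epoch)

channels = sorted(z["channel"].unique())
pivot = lambda cond: (z[z.condition == cond]
                      .pivot_table(index="subject_id", columns="channel",
                                   values="slope", sort=True)[channels]
                      .to_numpy())
res = stats_inference.paired_perm_pseudo_t(pivot("caffeine"),
                                           pivot("placebo"),
                                           n_perm=500, seed=0)
for ch, t, p in zip(channels, res.pseudo_t, res.p_corrected):
    print(f"{ch}: pseudo-t = {t:+.2f}, corrected p = {p:.3f}")
```

prints

```
C3: pseudo-t = -30.62, corrected p = 0.008
C4: pseudo-t = -25.60, corrected p = 0.008
F3: pseudo-t = -23.67, corrected p = 0.008
F4: pseudo-t = -27.06, corrected p = 0.008
O1: pseudo-t = -44.36, corrected p = 0.008
O2: pseudo-t = -25.68, corrected p = 0.008
```

The aperiodic-slope feature is significantly *lower* under the simulated
stimulant on every channel — the planted spectral flattening (Δχ = 0.3),
recovered through the full feature-extraction → z-scoring →
permutation-inference chain. With 8 subjects the sign-flip null is
enumerated exhaustively (256 patterns), so p = 2/256 ≈ 0.008 is the
smallest achievable two-sided value (the all-plus and all-minus patterns
both reach the observed maximum).

The same pipeline is scriptable from the shell:

```
sleepcrit simulate --config study.yaml --out data/
sleepcrit run --config study.yaml --out results/
sleepcrit stats --features results/features_NREM_subject.tsv \
    --feature lzc --n-perm 10000 --seed 0 --out lzc_stats.tsv
```

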