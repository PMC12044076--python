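"""Synthetic sleep-EEG generator with known ground truth.

Produces paired "caffeine"/"placebo" recordings whose aperiodic (1/f)
exponent, oscillatory peak structure and long-range temporal correlations
are controlled exactly, so every downstream stage of the pipeline
(spectral parameterization, entropy metrics, DFA, inference, decoding)
can be validated by parameter recovery instead of against unavailable
study data.

Signals are built by inverse-spectral synthesis: white Gaussian Fourier
coefficients are shaped by ``f**(-chi/2)`` and inverse-transformed, which
gives exact control of the spectral exponent chi.  For such noise the DFA
scaling exponent is tied to chi via ``alpha = (chi + 1) / 2`` (exact in
the fGn regime ``0 <= chi < 1`` and a good approximation for DFA-1 up to
``chi ~ 3``), so long-range temporal correlations are not an independent
dial — flattening the spectrum under "caffeine" flattens the slope and
lowers DFA together, mirroring the coherent effect directions the
analysis is designed to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_preprocess import EpochedRecording

#: 20 scalp electrodes of the international 10-20 system.
CHANNELS_1020 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "Oz", "O2",
]

BAND_EDGES = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "sigma": (12.0, 16.0),
    "beta": (16.0, 32.0),
}


@dataclass(frozen=True)
class StageParams:
    """Baseline spectral parameters of one sleep stage.

    exponent
        Aperiodic 1/f exponent chi (dimensionless, >= 0).
    offset
        Aperiodic offset, log10(uV^2/Hz) at 1 Hz.
    peaks
        Oscillatory peaks as (center Hz, height log10-power, width Hz).
    """

    exponent: float
    offset: float
    peaks: tuple[tuple[float, float, float], ...]


@dataclass(frozen=True)
class ConditionEffects:
    """Additive condition ("caffeine") effects applied to stage baselines.

    d_exponent
        Slope flattening: chi_caffeine = chi_placebo - d_exponent, so a
        positive value means a flatter spectrum (and lower DFA alpha).
    d_peak_height
        Per-band additive change of oscillatory peak height (log10 power);
        applied to every baseline peak whose center falls in the band.
    """

    d_exponent: float = 0.3
    d_peak_height: dict[str, float] = field(
        default_factory=lambda: {
            "delta": -0.15, "theta": -0.10, "alpha": -0.10,
            "sigma": 0.0, "beta": +0.15,
        }
    )


# NREM: steep slope, slow-oscillation/delta peak (below the 3 Hz fit floor),
# a prominent narrow sigma (spindle) peak and a small narrow beta peak for
# the condition effect to act on.  REM: flatter slope, theta/alpha peaks.
# Exponents put raw-signal DFA near 1.3 (NREM) and 1.2 (REM) via
# alpha = (chi + 1) / 2.  Peaks are kept narrow so the spectral
# parameterization can separate them from the line without bias.
DEFAULT_STAGE_PARAMS = {
    "NREM": StageParams(
        exponent=1.6, offset=2.0,
        peaks=((1.2, 0.6, 0.8), (13.5, 0.8, 1.0), (20.0, 0.15, 0.8)),
    ),
    "REM": StageParams(
        exponent=1.4, offset=1.5,
        peaks=((6.0, 0.4, 1.0), (9.0, 0.5, 1.0), (20.0, 0.15, 0.8)),
    ),
}


@dataclass(frozen=True)
class SyntheticStudyConfig:
    """Design of a paired two-condition synthetic sleep study."""

    n_subjects: int = 40
    n_young: int = 22
    n_middle: int = 18
    channel_names: tuple[str, ...] = tuple(CHANNELS_1020)
    fs: float = 256.0
    epoch_len: float = 20.0
    n_nrem: int = 60
    n_rem: int = 20
    stage_params: dict[str, StageParams] = field(
        default_factory=lambda: dict(DEFAULT_STAGE_PARAMS)
    )
    condition_effects: ConditionEffects = field(default_factory=ConditionEffects)
    #: between-subject SDs (truncated-Gaussian draws)
    sd_exponent: float = 0.15
    sd_offset: float = 0.2
    sd_peak_height: float = 0.08
    #: per-age-group multiplier on condition_effects; None = no age modulation
    age_effect: dict[str, float] | None = None
    #: SD of white measurement noise relative to signal SD, per channel;
    #: kept small so the sensor floor does not flatten steep spectra
    channel_noise: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        n_samp = self.epoch_len * self.fs
        if abs(n_samp - round(n_samp)) > 1e-9:
            raise ValueError("epoch_len * fs must be an integer sample count")
        if self.n_nrem < 1 or self.n_rem < 1:
            raise ValueError("epoch counts must be >= 1")
        if self.n_young + self.n_middle != self.n_subjects:
            raise ValueError("age-group split must sum to n_subjects")
        for stage, p in self.stage_params.items():
            if p.exponent < 0:
                raise ValueError(f"{stage}: aperiodic exponent must be >= 0")
            for c, h, w in p.peaks:
                if not 0 < w < self.fs / 2:
                    raise ValueError(f"{stage}: peak width {w} outside (0, fs/2)")

    @property
    def n_samples(self) -> int:
        return int(round(self.epoch_len * self.fs))


def _spectral_noise(beta: float, n_samples: int, fs: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with power spectral density proportional to f**(-beta).

    beta may be negative (blue noise); beta = 0 is white noise.  The output
    is standardized to zero mean and unit variance.
    """
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-beta / 2.0)
    # Gaussian real/imag coefficients == Rayleigh amplitudes + uniform phases
    coeffs = amp * (rng.standard_normal(freqs.size)
                    + 1j * rng.standard_normal(freqs.size))
    coeffs[0] = 0.0
    x = np.fft.irfft(coeffs, n=n_samples)
    sd = x.std()
    if sd == 0:
        return x
    return (x - x.mean()) / sd


def synth_aperiodic_epoch(exponent: float, n_samples: int, fs: float,
                          seed: int | np.random.Generator) -> np.ndarray:
    """One epoch of 1/f^chi noise, zero mean and unit variance.

    The Welch log-log PSD slope over 3-32 Hz equals ``-exponent`` up to
    estimation noise.
    """
    if not np.isfinite(exponent):
        raise ValueError("exponent must be finite")
    if exponent < 0:
        raise ValueError("exponent must be >= 0")
    if n_samples < 64:
        raise ValueError("n_samples must be >= 64")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return _spectral_noise(exponent, n_samples, fs, rng)


def synth_fgn(hurst: float, n_samples: int, fs: float,
              seed: int | np.random.Generator) -> np.ndarray:
    """Fractional Gaussian noise via spectral synthesis.

    fGn with Hurst exponent H has PSD ~ f**(-(2H-1)); its DFA scaling
    exponent equals H (anti-correlated for H < 0.5, white at H = 0.5).
    """
    if not 0 < hurst < 1:
        raise ValueError("hurst must be in (0, 1)")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return _spectral_noise(2.0 * hurst - 1.0, n_samples, fs, rng)


def synth_oscillation(center: float, width: float, amplitude: float,
                      n_samples: int, fs: float,
                      seed: int | np.random.Generator) -> np.ndarray:
    """Narrowband (band-limited Gaussian) oscillation.

    The PSD is a Gaussian bump at ``center`` with SD ``width`` Hz, so power
    is concentrated within center +/- 2 width.  ``amplitude`` sets the
    output RMS in uV; amplitude = 0 returns the zero vector.
    """
    nyq = fs / 2.0
    if not 0 < center < nyq:
        raise ValueError("center must lie in (0, fs/2)")
    if not 0 < width < nyq:
        raise ValueError("width must lie in (0, fs/2)")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    amp = np.exp(-((freqs - center) ** 2) / (2.0 * width ** 2))
    coeffs = amp * (rng.standard_normal(freqs.size)
                    + 1j * rng.standard_normal(freqs.size))
    coeffs[0] = 0.0
    x = np.fft.irfft(coeffs, n=n_samples)
    sd = x.std()
    if sd == 0 or amplitude == 0:
        return np.zeros(n_samples)
    return amplitude * (x - x.mean()) / sd


def _aperiodic_density(f: np.ndarray, offset: float, exponent: float) -> np.ndarray:
    return 10.0 ** offset * f ** (-exponent)


def _epoch_signal(params: StageParams, n_samples: int, fs: float,
                  rng: np.random.Generator) -> np.ndarray:
    """One epoch: scaled aperiodic noise plus oscillatory peaks (uV)."""
    base = _spectral_noise(params.exponent, n_samples, fs, rng)
    # variance implied by the aperiodic PSD, integrated over the resolvable band
    f = np.fft.rfftfreq(n_samples, d=1.0 / fs)[1:]
    var_ap = np.trapezoid(_aperiodic_density(f, params.offset, params.exponent), f)
    x = base * np.sqrt(var_ap)
    for center, height, width in params.peaks:
        # oscillation power such that its PSD bump rises ~`height` log10
        # units above the aperiodic density at the peak center
        ap_c = _aperiodic_density(np.array([center]), params.offset,
                                  params.exponent)[0]
        p_osc = (10.0 ** height - 1.0) * ap_c * width * np.sqrt(2.0 * np.pi)
        x = x + synth_oscillation(center, width, np.sqrt(p_osc), n_samples, fs, rng)
    return x


def _apply_effects(params: StageParams, eff: ConditionEffects,
                   scale: float) -> StageParams:
    """Stage parameters under the treated condition (effects scaled)."""
    new_exp = max(params.exponent - scale * eff.d_exponent, 0.0)
    new_peaks = []
    for center, height, width in params.peaks:
        d = 0.0
        for band, (lo, hi) in BAND_EDGES.items():
            if lo <= center < hi:
                d = eff.d_peak_height.get(band, 0.0)
                break
        new_peaks.append((center, max(height + scale * d, 0.0), width))
    return replace(params, exponent=new_exp, peaks=tuple(new_peaks))


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float = -np.inf, hi: float = np.inf) -> float:
    """Gaussian draw truncated to [lo, hi] by redrawing (sd = 0 passes through)."""
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(100):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    return float(np.clip(mean, lo, hi))


def generate_subject(config: SyntheticStudyConfig, subject_index: int
                     ) -> tuple[list[EpochedRecording], pd.DataFrame]:
    """Both recordings (placebo, caffeine) of one subject plus ground truth.

    Deterministic in (config, subject_index): each subject derives an
    independent random stream from the config seed.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed) % (2 ** 31), subject_index])
    )
    subject_id = f"S{subject_index:03d}"
    age_group = "young" if subject_index < config.n_young else "middle"
    eff_scale = 1.0
    if config.age_effect is not None:
        eff_scale = float(config.age_effect.get(age_group, 1.0))

    # subject-level parameter offsets, shared across conditions (paired design)
    subj_params: dict[str, StageParams] = {}
    for stage, p in config.stage_params.items():
        chi = _truncnorm(rng, p.exponent, config.sd_exponent, lo=0.0)
        off = _truncnorm(rng, p.offset, config.sd_offset)
        peaks = tuple(
            (c, _truncnorm(rng, h, config.sd_peak_height, lo=0.0), w)
            for c, h, w in p.peaks
        )
        subj_params[stage] = StageParams(chi, off, peaks)

    n_samples = config.n_samples
    recs: list[EpochedRecording] = []
    truth_rows: list[dict] = []
    for condition in ("placebo", "caffeine"):
        stage_cond = {
            s: (_apply_effects(p, config.condition_effects, eff_scale)
                if condition == "caffeine" else p)
            for s, p in subj_params.items()
        }
        counts = {"NREM": config.n_nrem, "REM": config.n_rem}
        labels: list[str] = []
        epochs = np.empty(
            (config.n_nrem + config.n_rem, len(config.channel_names), n_samples)
        )
        i = 0
        for stage in ("NREM", "REM"):
            p = stage_cond[stage]
            for _ in range(counts[stage]):
                for ch in range(len(config.channel_names)):
                    x = _epoch_signal(p, n_samples, config.fs, rng)
                    if config.channel_noise > 0:
                        x = x + rng.normal(0.0, config.channel_noise * x.std(),
                                           n_samples)
                    epochs[i, ch] = x
                labels.append(stage)
                i += 1
            row = {
                "subject_id": subject_id, "condition": condition,
                "age_group": age_group, "stage": stage,
                "exponent": p.exponent, "offset": p.offset,
            }
            for c, h, w in p.peaks:
                for band, (lo, hi) in BAND_EDGES.items():
                    if lo <= c < hi:
                        row[f"peak_height_{band}"] = h
            truth_rows.append(row)
        recs.append(EpochedRecording(
            subject_id=subject_id, condition=condition, age_group=age_group,
            channel_names=list(config.channel_names), fs=config.fs,
            epochs=epochs, stage_labels=np.array(labels),
        ))
    return recs, pd.DataFrame(truth_rows)


def generate_study(config: SyntheticStudyConfig
                   ) -> tuple[list[EpochedRecording], pd.DataFrame]:
    """Full paired study: two recordings per subject and a ground-truth table.

    Memory scales with n_subjects x epochs x channels x samples; for
    paper-scale designs prefer iterating ``generate_subject`` and writing
    each recording to disk.
    """
    recordings: list[EpochedRecording] = []
    truths = []
    for idx in range(config.n_subjects):
        recs, truth = generate_subject(config, idx)
        recordings.extend(recs)
        truths.append(truth)
    return recordings, pd.concat(truths, ignore_index=True)
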