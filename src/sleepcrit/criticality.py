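"""Detrended fluctuation analysis (DFA-1) and band-limited envelope DFA.

DFA probes long-range temporal correlations: the signal profile
(cumulative sum of the mean-subtracted signal) is cut into windows, each
window is linearly detrended, and the RMS fluctuation F(n) is measured
as a function of window size n.  The log-log slope alpha generalizes the
Hurst exponent: 0.5 for white noise, < 0.5 anti-correlated, > 0.5
persistent, and > 1 for non-stationary (unbounded) signals such as raw
EEG.  The band-limited variant applies DFA to the Hilbert amplitude
envelope of a band-passed signal, the standard probe for long-range
temporal correlations of neural oscillations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal


@dataclass(frozen=True)
class DFAConfig:
    """Window scheme: ~16 log-spaced sizes in [16, n/4], linear detrend."""

    min_window: int = 16
    max_window: int | None = None  # defaults to n // 4
    n_windows: int = 16
    detrend_order: int = 1

    def sizes(self, n: int) -> np.ndarray:
        max_w = self.max_window if self.max_window is not None else n // 4
        if max_w <= self.min_window:
            raise ValueError("max window must exceed min window")
        sizes = np.unique(np.floor(
            np.logspace(np.log10(self.min_window), np.log10(max_w),
                        self.n_windows)
        ).astype(int))
        if sizes.size < 6:
            raise ValueError("fewer than 6 distinct window sizes")
        return sizes


@dataclass
class DFAResult:
    alpha: float
    fit_r2: float
    window_sizes: np.ndarray
    fluctuations: np.ndarray


def _segment_rms(profile: np.ndarray, size: int) -> float:
    """RMS residual of linearly detrended non-overlapping profile segments.

    Segments are taken from both the start and the end of the profile
    (the standard two-sided scheme), so samples in a trailing partial
    window still contribute and F(n) is less noisy at large n.
    """
    k = profile.size // size
    segs = np.concatenate([
        profile[: k * size].reshape(k, size),
        profile[profile.size - k * size:].reshape(k, size),
    ])
    t = np.arange(size, dtype=float)
    t0 = t - t.mean()
    denom = (t0 ** 2).sum()
    y_mean = segs.mean(axis=1, keepdims=True)
    slope = (segs @ t0)[:, None] / denom
    resid = segs - y_mean - slope * t0[None, :]
    return float(np.sqrt(np.mean(resid ** 2)))


def dfa(x: np.ndarray, config: DFAConfig = DFAConfig()) -> DFAResult:
    """DFA-1 scaling exponent of a 1-D signal.

    Raises on constant input (zero fluctuation at some scale makes the
    log-log fit undefined).
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 4 * config.min_window:
        raise ValueError("signal too short for the window scheme")
    sizes = config.sizes(x.size)
    profile = np.cumsum(x - x.mean())
    flucts = np.array([_segment_rms(profile, s) for s in sizes])
    if np.any(flucts <= 0):
        raise ValueError("zero fluctuation: constant or degenerate input")
    logn = np.log10(sizes)
    logf = np.log10(flucts)
    A = np.column_stack([np.ones_like(logn), logn])
    coef, *_ = np.linalg.lstsq(A, logf, rcond=None)
    fitted = A @ coef
    ss_res = float(((logf - fitted) ** 2).sum())
    ss_tot = float(((logf - logf.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return DFAResult(alpha=float(coef[1]), fit_r2=r2,
                     window_sizes=sizes, fluctuations=flucts)


def band_dfa(x: np.ndarray, band: tuple[float, float], fs: float,
             config: DFAConfig | None = None) -> DFAResult:
    """DFA of the Hilbert amplitude envelope of a band-passed signal.

    Below ~2/bandwidth seconds the envelope of narrowband noise is smooth
    by construction (the filter's own memory, not neural correlations),
    so unless a config is supplied the minimum window is raised to
    2 * fs / bandwidth samples and only slower fluctuations enter the fit.
    """
    lo, hi = band
    if not 0 < lo < hi < fs / 2:
        raise ValueError("band must lie within (0, fs/2)")
    x = np.asarray(x, dtype=float).ravel()
    if config is None:
        config = DFAConfig(min_window=max(16, int(round(2 * fs / (hi - lo)))))
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    filtered = signal.sosfiltfilt(sos, x)
    envelope = np.abs(signal.hilbert(filtered))
    # drop 1 s per side: filtfilt/Hilbert edge transients would otherwise
    # masquerade as slow envelope fluctuations
    trim = int(fs)
    if envelope.size > 4 * trim:
        envelope = envelope[trim:-trim]
    if envelope.std() < 5e-3 * max(envelope.mean(), 1e-300):
        raise ValueError("zero fluctuation: constant amplitude envelope")
    return dfa(envelope, config)
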