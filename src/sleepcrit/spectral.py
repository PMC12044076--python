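"""Welch spectra, aperiodic (1/f) parameterization and corrected band power.

The spectral model follows the spectral-parameterization ("specparam")
approach: in log10-power coordinates the spectrum is a straight line in
log10-frequency (the aperiodic component, slope -chi) plus up to five
Gaussian oscillatory peaks over linear frequency.  Band powers are read
from the flattened spectrum (log residual after removing the aperiodic
line), with the line extrapolated below the 3 Hz fit floor to cover the
delta band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.optimize import curve_fit

#: canonical sleep-EEG band edges in Hz
BANDS = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "sigma": (12.0, 16.0),
    "beta": (16.0, 32.0),
}

FIT_RANGE = (3.0, 32.0)
MAX_PEAKS = 5
PEAK_WIDTH_LIMITS = (0.5, 12.0)


@dataclass
class PowerSpectrum:
    """One-sided Welch PSD per channel (power in uV^2/Hz)."""

    freqs: np.ndarray
    power: np.ndarray  # (n_channels, n_freqs)
    window_len: float = 4.0
    overlap: float = 2.0

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.atleast_2d(np.asarray(self.power, dtype=float))
        if self.power.shape[-1] != self.freqs.size:
            raise ValueError("power/freqs size mismatch")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("negative power values")

    def band_slice(self, lo: float, hi: float) -> np.ndarray:
        """Boolean mask of bins with lo <= f < hi (upper edge included
        when hi is the last band edge of the spectrum's support)."""
        mask = (self.freqs >= lo) & (self.freqs < hi)
        return mask


@dataclass
class AperiodicModel:
    """Aperiodic line plus <= 5 Gaussian peaks, fitted in the 3-32 Hz range.

    offset
        log10 power density at 1 Hz.
    exponent
        The positive 1/f exponent chi (negative log-log slope); larger
        means a steeper spectrum.
    peaks
        (center Hz, height in log10 power over the line, width Hz).
    """

    offset: float
    exponent: float
    peaks: list[tuple[float, float, float]] = field(default_factory=list)
    fit_range: tuple[float, float] = FIT_RANGE
    fit_error: float = np.nan

    def aperiodic_log10(self, freqs: np.ndarray) -> np.ndarray:
        """log10 of the aperiodic line, extrapolated to any f > 0."""
        freqs = np.asarray(freqs, dtype=float)
        if np.any(freqs <= 0):
            raise ValueError("aperiodic line undefined at f <= 0")
        return self.offset - self.exponent * np.log10(freqs)

    def model_log10(self, freqs: np.ndarray) -> np.ndarray:
        out = self.aperiodic_log10(freqs)
        for c, h, w in self.peaks:
            out = out + h * np.exp(-((freqs - c) ** 2) / (2 * w ** 2))
        return out


def welch_psd(epoch: np.ndarray, fs: float, window_len: float = 4.0,
              overlap: float = 2.0) -> PowerSpectrum:
    """Welch PSD of one epoch (channels x samples), Hann taper.

    With the default 4 s window and 2 s overlap a 20-s epoch yields nine
    averaged segments and 0.25 Hz resolution.
    """
    epoch = np.atleast_2d(np.asarray(epoch, dtype=float))
    nperseg = int(round(window_len * fs))
    noverlap = int(round(overlap * fs))
    if epoch.shape[-1] < nperseg:
        raise ValueError("epoch shorter than one Welch window")
    freqs, power = signal.welch(epoch, fs=fs, window="hann", nperseg=nperseg,
                                noverlap=noverlap, detrend="constant",
                                scaling="density", axis=-1)
    return PowerSpectrum(freqs=freqs, power=power,
                         window_len=window_len, overlap=overlap)


def _gauss(f, height, center, width):
    return height * np.exp(-((f - center) ** 2) / (2 * width ** 2))


def _robust_line(logf: np.ndarray, logp: np.ndarray) -> tuple[float, float]:
    """Line fit down-weighting oscillatory peaks.

    First-pass OLS, then refit on the points with the smallest residuals
    (peaks only push residuals up, so trimming the top keeps the
    aperiodic backbone).
    """
    A = np.column_stack([np.ones_like(logf), logf])
    coef, *_ = np.linalg.lstsq(A, logp, rcond=None)
    resid = logp - A @ coef
    thresh = np.percentile(resid, 60.0)
    mask = resid <= thresh
    if mask.sum() >= 3:
        coef, *_ = np.linalg.lstsq(A[mask], logp[mask], rcond=None)
    return float(coef[0]), float(coef[1])


def fit_aperiodic(ps: PowerSpectrum, channel: int = 0,
                  fit_range: tuple[float, float] = FIT_RANGE,
                  max_peaks: int = MAX_PEAKS,
                  peak_width_limits: tuple[float, float] = PEAK_WIDTH_LIMITS,
                  peak_threshold: float = 2.5,
                  min_peak_height: float = 0.15) -> AperiodicModel:
    """Iterative aperiodic + peak decomposition of one channel's spectrum.

    1. robust line fit to log10 power vs log10 frequency;
    2. repeatedly fit-and-subtract a Gaussian at the largest positive
       residual until ``max_peaks`` peaks are found or the residual
       maximum drops below ``peak_threshold`` noise SDs (a MAD-based
       scale estimated once from the initial residual, so already-found
       peaks do not lower the bar for spurious ones) or below
       ``min_peak_height`` log10 units;
    3. refit the line on the spectrum with fitted peak neighborhoods
       (center +/- 2.5 widths) excluded — more robust to imperfect peak
       shapes than subtracting the Gaussian model.
    """
    lo, hi = fit_range
    mask = (ps.freqs >= lo) & (ps.freqs <= hi)
    f = ps.freqs[mask]
    p = ps.power[channel, mask]
    if f.size < 8:
        raise ValueError("fit range covers too few frequency bins")
    if np.any(p <= 0):
        raise ValueError("non-positive power inside the fit range")
    logf = np.log10(f)
    logp = np.log10(p)

    intercept, slope = _robust_line(logf, logp)
    resid = logp - (intercept + slope * logf)
    # robust noise scale of the log-residual, held fixed across iterations
    noise_sd = 1.4826 * np.median(np.abs(resid - np.median(resid)))
    height_floor = max(peak_threshold * noise_sd, min_peak_height)

    wmin, wmax = peak_width_limits
    peaks: list[tuple[float, float, float]] = []
    work = resid.copy()
    for _ in range(max_peaks):
        i = int(np.argmax(work))
        height = work[i]
        if height < height_floor:
            break
        center = f[i]
        # half-height crossing -> width guess
        half = height / 2
        j = i
        while j + 1 < work.size and work[j] > half:
            j += 1
        k = i
        while k - 1 >= 0 and work[k] > half:
            k -= 1
        fwhm = max(f[j] - f[k], 2 * (f[1] - f[0]))
        guess_w = np.clip(fwhm / 2.355, wmin, wmax)
        try:
            popt, _ = curve_fit(
                _gauss, f, work, p0=[height, center, guess_w],
                bounds=([0.0, lo, wmin], [2 * height + 1e-12, hi, wmax]),
                maxfev=2000,
            )
        except RuntimeError:
            break
        h_fit, c_fit, w_fit = popt
        if h_fit <= 0:
            break
        peaks.append((float(c_fit), float(h_fit), float(w_fit)))
        work = work - _gauss(f, *popt)

    # final line refit: exclude fitted peak neighborhoods when enough
    # bins remain, otherwise fall back to subtracting the peak model
    A = np.column_stack([np.ones_like(logf), logf])
    keep = np.ones(f.size, dtype=bool)
    for c, h, w in peaks:
        keep &= np.abs(f - c) > 2.5 * w
    if peaks and keep.sum() >= 10:
        coef, *_ = np.linalg.lstsq(A[keep], logp[keep], rcond=None)
    else:
        peak_sum = np.zeros_like(f)
        for c, h, w in peaks:
            peak_sum += _gauss(f, h, c, w)
        coef, *_ = np.linalg.lstsq(A, logp - peak_sum, rcond=None)
    intercept, slope = float(coef[0]), float(coef[1])
    if not np.isfinite(slope):
        raise ValueError("aperiodic fit diverged")

    model = AperiodicModel(offset=intercept, exponent=-slope,
                           peaks=sorted(peaks), fit_range=fit_range)
    model.fit_error = float(
        np.sqrt(np.mean((model.model_log10(f) - logp) ** 2))
    )
    return model


@dataclass
class BandPowers:
    """Mean (optionally 1/f-corrected) power per canonical band."""

    values: dict[str, float]
    corrected: bool


def corrected_band_power(ps: PowerSpectrum, model: AperiodicModel | None,
                         channel: int = 0,
                         bands: dict[str, tuple[float, float]] = BANDS,
                         mode: str = "log_residual") -> BandPowers:
    """Band powers from the 1/f-flattened spectrum.

    mode
        ``log_residual`` (default): mean over band bins of
        log10(observed) - log10(aperiodic); the line is extrapolated
        below the fit floor so delta is covered.
        ``linear``: mean of observed - aperiodic in linear power units.
        ``uncorrected``: mean of the raw PSD over band bins.
    """
    if mode not in ("log_residual", "linear", "uncorrected"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode != "uncorrected" and model is None:
        raise ValueError("corrected modes require a fitted aperiodic model")
    values: dict[str, float] = {}
    top_edge = max(hi for _, hi in bands.values())
    for name, (lo, hi) in bands.items():
        mask = (ps.freqs >= lo) & (
            (ps.freqs <= hi) if hi == top_edge else (ps.freqs < hi)
        )
        if not mask.any():
            raise ValueError(f"band {name} outside spectrum support")
        p = ps.power[channel, mask]
        if mode == "uncorrected":
            values[name] = float(np.mean(p))
            continue
        ap_log = model.aperiodic_log10(ps.freqs[mask])
        if mode == "log_residual":
            if np.any(p <= 0):
                raise ValueError(f"non-positive power in band {name}")
            values[name] = float(np.mean(np.log10(p) - ap_log))
        else:
            values[name] = float(np.mean(p - 10.0 ** ap_log))
    return BandPowers(values=values, corrected=(mode != "uncorrected"))


def slope_feature(model: AperiodicModel) -> float:
    """The aperiodic-slope feature: the positive exponent chi.

    Reported positive so that a *reduction* corresponds to a flatter
    (more excitable / closer-to-critical) spectrum.
    """
    return float(model.exponent)
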