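"""Entropy and compressibility metrics for single EEG epochs.

Implements sample entropy (Chebyshev distance, self-matches excluded),
Shannon spectral entropy, the SpecSampEn variant (sample entropy applied
to the ordered power-spectrum bin values), normalized Lempel-Ziv (LZ76)
complexity of the median-binarized signal, and Bandt-Pompe permutation
entropy.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial, log

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.spatial import cKDTree

from .spectral import PowerSpectrum

SPECTRAL_RANGE = (0.5, 32.0)


@dataclass(frozen=True)
class EntropyParams:
    """Sample-entropy parameters: embedding length m, tolerance r (x SD)."""

    m: int = 2
    r: float = 0.2

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.r <= 0:
            raise ValueError("r must be positive")


def _match_pairs(x: np.ndarray, m: int, n_templates: int, tol: float) -> int:
    """Number of unordered template pairs of length m within Chebyshev tol.

    Only the first ``n_templates`` windows enter, so counts at lengths m
    and m+1 use the same template population.
    """
    windows = sliding_window_view(x, m)[:n_templates]
    tree = cKDTree(windows)
    # ordered pairs incl. self-pairs -> unordered, self-matches excluded
    total = tree.count_neighbors(tree, r=tol, p=np.inf)
    return int(total - n_templates) // 2


def sample_entropy(x: np.ndarray, params: EntropyParams = EntropyParams()
                   ) -> float:
    """SampEn(m, r) = -log(A / B) with maximum-norm template matching.

    A counts matching template pairs at length m+1 and B at length m; the
    tolerance is ``r`` times the SD of ``x``.  Returns +inf when no pair
    still matches at length m+1 (the epoch is then flagged downstream).
    """
    x = np.asarray(x, dtype=float).ravel()
    m = params.m
    if x.size < m + 2:
        raise ValueError("signal too short for the embedding length")
    sd = x.std()
    if sd == 0:
        raise ValueError("zero variance: SampEn tolerance degenerates")
    tol = params.r * sd
    n_templates = x.size - m  # windows of length m+1 that exist
    b = _match_pairs(x, m, n_templates, tol)
    a = _match_pairs(x, m + 1, n_templates, tol)
    if b == 0:
        return np.inf
    if a == 0:
        return np.inf
    return float(-np.log(a / b))


def _spectral_values(ps: PowerSpectrum, channel: int,
                     freq_range: tuple[float, float]) -> np.ndarray:
    lo, hi = freq_range
    mask = (ps.freqs >= lo) & (ps.freqs <= hi)
    if mask.sum() < 2:
        raise ValueError("fewer than 2 spectral bins in range")
    return ps.power[channel, mask]


def spectral_entropy(ps: PowerSpectrum, channel: int = 0,
                     freq_range: tuple[float, float] = SPECTRAL_RANGE,
                     normalize: bool = True) -> float:
    """Shannon entropy of the PSD treated as a probability distribution.

    Normalized by log(#bins) to lie in [0, 1]: 0 when all power sits in
    one bin, 1 for an exactly flat spectrum.
    """
    p = _spectral_values(ps, channel, freq_range)
    total = p.sum()
    if total <= 0:
        raise ValueError("spectrum has no power in range")
    q = p / total
    nz = q[q > 0]
    h = float(-(nz * np.log(nz)).sum())
    if normalize:
        h /= log(q.size)
    return h


def spectral_sample_entropy(ps: PowerSpectrum, channel: int = 0,
                            params: EntropyParams = EntropyParams(),
                            freq_range: tuple[float, float] = SPECTRAL_RANGE,
                            log_power: bool = False) -> float:
    """Sample entropy of the sequence of PSD bin values (SpecSampEn).

    Treats the spectrum as an ordered signal over frequency, so local
    spectral patterns (peaks, slopes) influence the estimate — unlike
    the permutation-invariant Shannon spectral entropy.
    """
    p = _spectral_values(ps, channel, freq_range)
    if log_power:
        if np.any(p <= 0):
            raise ValueError("log-power mode requires positive spectrum")
        p = np.log10(p)
    return sample_entropy(p, params)


def _lz76_phrases(bits: np.ndarray) -> int:
    """LZ76 phrase count of a binary sequence.

    Each phrase is the shortest continuation that cannot be copied from
    the history (copy sources may overlap the phrase itself); the scan
    uses C-level substring search for speed.
    """
    s = bits.tobytes()
    n = len(s)
    c = 0
    i = 0
    while i < n:
        length = 1
        # phrase s[i:i+length] reproducible while it occurs in s[0:i+length-1]
        while i + length <= n and s.find(s[i:i + length], 0,
                                         i + length - 1) != -1:
            length += 1
        c += 1
        i += length
    return c


def lempel_ziv(x: np.ndarray) -> float:
    """Normalized Lempel-Ziv complexity of the median-binarized signal.

    Samples strictly above the median map to 1 (ties to 0, a fixed rule
    so integer-quantized data stay deterministic); the LZ76 phrase count
    c(n) is scaled by log2(n)/n, which tends to 1 for random sequences.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 samples")
    if x.std() == 0:
        raise ValueError("zero variance: median split degenerates")
    bits = (x > np.median(x)).astype(np.uint8)
    c = _lz76_phrases(bits)
    return float(c * np.log2(n) / n)


def permutation_entropy(x: np.ndarray, order: int = 3, delay: int = 1,
                        normalize: bool = True) -> float:
    """Bandt-Pompe ordinal-pattern entropy, normalized by log(order!).

    Kept outside the 11-feature canonical set; parameters are the common
    defaults since none are dictated by the analysis.
    """
    x = np.asarray(x, dtype=float).ravel()
    if order < 2:
        raise ValueError("order must be >= 2")
    if delay < 1:
        raise ValueError("delay must be >= 1")
    n_patterns = x.size - (order - 1) * delay
    if n_patterns < 1:
        raise ValueError("signal too short for the requested order/delay")
    idx = np.arange(0, order * delay, delay)
    windows = x[np.arange(n_patterns)[:, None] + idx[None, :]]
    ranks = np.argsort(np.argsort(windows, axis=1, kind="stable"), axis=1)
    codes = (ranks * (order ** np.arange(order))[None, :]).sum(axis=1)
    _, counts = np.unique(codes, return_counts=True)
    freq = counts / counts.sum()
    h = float(-(freq * np.log(freq)).sum())
    if normalize:
        h /= log(factorial(order))
    return h
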