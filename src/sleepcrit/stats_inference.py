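"""Permutation inference for the paired two-condition design.

The primary test is a paired sign-flip permutation pseudo-T with
maximum-statistic family-wise error control: each subject's
caffeine-minus-placebo difference vector is multiplied by a random sign
(jointly across channels, preserving the spatial correlation
structure), and each permutation contributes the maximum |t| across
channels to a single null distribution, so the corrected p-value of
every channel is compared against the family's best-case null.

The pseudo-T regularizes the denominator with a small epsilon (10% of
the median standard error across channels) so channels with near-zero
difference variance do not produce explosive statistics; with epsilon=0
it reduces to the plain paired t.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

#: subject counts up to which full sign-pattern enumeration is feasible
EXHAUSTIVE_LIMIT = 14


@dataclass
class PairedTestResult:
    pseudo_t: np.ndarray
    p_corrected: np.ndarray
    cohens_d: np.ndarray
    n_permutations: int
    exhaustive: bool
    seed: int | None


@dataclass
class AgeContrastResult:
    t_independent: np.ndarray
    p_fdr: np.ndarray
    n_young: int
    n_middle: int


def _pseudo_t(diff: np.ndarray, eps: float) -> np.ndarray:
    n = diff.shape[0]
    se = diff.std(axis=0, ddof=1) / np.sqrt(n)
    denom = se + eps
    # identical conditions: zero mean difference and zero spread -> t = 0
    out = np.zeros(diff.shape[1])
    np.divide(diff.mean(axis=0), denom, out=out, where=denom > 0)
    return out


def _epsilon(diff: np.ndarray, eps_fraction: float) -> float:
    n = diff.shape[0]
    se = diff.std(axis=0, ddof=1) / np.sqrt(n)
    return float(eps_fraction * np.median(se))


def paired_perm_pseudo_t(values_a: np.ndarray, values_b: np.ndarray,
                         n_perm: int = 10_000, seed: int | None = 0,
                         eps_fraction: float = 0.1) -> PairedTestResult:
    """Two-sided paired sign-flip permutation test, max-stat corrected.

    values_a, values_b
        (n_subjects, n_channels) paired observations (e.g. caffeine and
        placebo subject-level features); the statistic is computed on
        per-subject differences a - b.

    Sign patterns are enumerated exhaustively when 2**n_subjects is
    small enough, otherwise drawn Monte-Carlo with add-one corrected
    p-values (1 + #{max-null >= |t|}) / (n_perm + 1).
    """
    a = np.atleast_2d(np.asarray(values_a, dtype=float))
    b = np.atleast_2d(np.asarray(values_b, dtype=float))
    if a.shape != b.shape:
        raise ValueError("condition arrays must have identical shape")
    n_subj, n_chan = a.shape
    if n_subj < 5:
        raise ValueError("need at least 5 subjects")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    diff = a - b
    eps = _epsilon(diff, eps_fraction)
    t_obs = _pseudo_t(diff, eps)

    sumsq = (diff ** 2).sum(axis=0)  # invariant under sign flips
    exhaustive = n_subj <= EXHAUSTIVE_LIMIT
    if exhaustive:
        signs = np.array(list(itertools.product((-1.0, 1.0), repeat=n_subj)))
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice((-1.0, 1.0), size=(n_perm, n_subj))
    m = signs @ diff / n_subj                      # (n_perm, n_chan)
    var = np.maximum(sumsq / n_subj - m ** 2, 0.0) * n_subj / (n_subj - 1)
    se = np.sqrt(var / n_subj)
    denom = se + eps
    null_t = np.zeros_like(m)
    np.divide(m, denom, out=null_t, where=denom > 0)
    null_max = np.abs(null_t).max(axis=1)

    abs_t = np.abs(t_obs)
    exceed = (null_max[:, None] >= abs_t[None, :]).sum(axis=0)
    if exhaustive:
        p = exceed / signs.shape[0]
    else:
        p = (1 + exceed) / (n_perm + 1)
    # effect size: 0 for degenerate (zero-spread) channels rather than an
    # error, so identical conditions still yield the full null result
    sd = diff.std(axis=0, ddof=1)
    d = np.zeros(n_chan)
    np.divide(diff.mean(axis=0), sd, out=d, where=sd > 0)
    return PairedTestResult(
        pseudo_t=t_obs, p_corrected=p, cohens_d=d,
        n_permutations=signs.shape[0], exhaustive=exhaustive, seed=seed,
    )


def cohens_d_paired(values_a: np.ndarray, values_b: np.ndarray) -> np.ndarray:
    """Paired Cohen's d per channel: mean(diff) / SD(diff)."""
    a = np.atleast_2d(np.asarray(values_a, dtype=float))
    b = np.atleast_2d(np.asarray(values_b, dtype=float))
    if a.shape != b.shape:
        raise ValueError("condition arrays must have identical shape")
    diff = a - b
    sd = diff.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("zero SD of paired differences")
    return diff.mean(axis=0) / sd


def age_contrast(diff_young: np.ndarray, diff_middle: np.ndarray
                 ) -> AgeContrastResult:
    """Welch independent t per channel on condition differences, BH-FDR.

    Compares (caffeine - placebo) effects between the young and
    middle-aged groups; p-values are Benjamini-Hochberg adjusted across
    channels.
    """
    y = np.atleast_2d(np.asarray(diff_young, dtype=float))
    m = np.atleast_2d(np.asarray(diff_middle, dtype=float))
    if y.shape[1] != m.shape[1]:
        raise ValueError("channel mismatch between groups")
    if y.shape[0] < 3 or m.shape[0] < 3:
        raise ValueError("need at least 3 subjects per group")
    t, p = sps.ttest_ind(y, m, axis=0, equal_var=False)
    _, p_fdr, _, _ = multipletests(p, method="fdr_bh")
    return AgeContrastResult(t_independent=np.asarray(t),
                             p_fdr=np.asarray(p_fdr),
                             n_young=y.shape[0], n_middle=m.shape[0])
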