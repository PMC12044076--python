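"""Feature assembly: per-epoch extraction, subject averaging, z-transform.

The canonical feature set has 11 columns per channel: five 1/f-corrected
band powers (delta, theta, alpha, sigma, beta), spectral entropy, sample
entropy, spectral sample entropy, Lempel-Ziv complexity, the DFA scaling
exponent and the aperiodic slope.  Permutation entropy and uncorrected
band powers can be added as extras but stay outside the canonical set.

Epoch-level cells that cannot be computed (e.g. SampEn with no surviving
template match) are stored as non-finite and skipped when averaging.
The z-transform is strictly within-subject: each subject's epoch-level
values of one feature, pooled across channels, epochs and both
conditions, supply the mean and SD used to standardize that subject's
subject-level values — no cross-subject statistic is ever used, which
keeps train/test subjects independent in the decoding analyses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import complexity, criticality, spectral
from .io_preprocess import EpochedRecording

BAND_FEATURES = ["delta", "theta", "alpha", "sigma", "beta"]
CANONICAL_FEATURES = BAND_FEATURES + [
    "specen", "sampen", "specsampen", "lzc", "dfa", "slope",
]
KEY_COLUMNS = ["subject_id", "condition", "age_group", "stage", "channel"]


def extract_features(rec: EpochedRecording, stage: str,
                     entropy_params: complexity.EntropyParams | None = None,
                     dfa_config: criticality.DFAConfig | None = None,
                     band_mode: str = "log_residual",
                     include_permen: bool = False) -> pd.DataFrame:
    """Epoch-level feature table for one recording and sleep stage.

    Returns one row per (epoch, channel) with the 11 canonical feature
    columns; metric failures on degenerate epochs become NaN cells
    rather than errors.
    """
    entropy_params = entropy_params or complexity.EntropyParams()
    dfa_config = dfa_config or criticality.DFAConfig()
    idx = np.flatnonzero(rec.stage_mask(stage))
    if idx.size == 0:
        raise ValueError(f"recording has no {stage} epochs")
    rows: list[dict] = []
    for ep_i in idx:
        epoch = rec.epochs[ep_i]
        ps = spectral.welch_psd(epoch, rec.fs)
        for ch_i, ch_name in enumerate(rec.channel_names):
            row = {
                "subject_id": rec.subject_id, "condition": rec.condition,
                "age_group": rec.age_group, "stage": stage,
                "channel": ch_name, "epoch_index": int(ep_i),
            }
            x = epoch[ch_i]
            try:
                model = spectral.fit_aperiodic(ps, ch_i)
                bp = spectral.corrected_band_power(ps, model, ch_i,
                                                   mode=band_mode)
                row.update(bp.values)
                row["slope"] = spectral.slope_feature(model)
            except ValueError:
                row.update({b: np.nan for b in BAND_FEATURES})
                row["slope"] = np.nan
            for name, fn in (
                ("specen", lambda: complexity.spectral_entropy(ps, ch_i)),
                ("sampen", lambda: complexity.sample_entropy(x, entropy_params)),
                ("specsampen", lambda: complexity.spectral_sample_entropy(
                    ps, ch_i, entropy_params)),
                ("lzc", lambda: complexity.lempel_ziv(x)),
                ("dfa", lambda: criticality.dfa(x, dfa_config).alpha),
            ):
                try:
                    row[name] = fn()
                except ValueError:
                    row[name] = np.nan
            if include_permen:
                try:
                    row["permen"] = complexity.permutation_entropy(x)
                except ValueError:
                    row["permen"] = np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def _feature_columns(table: pd.DataFrame) -> list[str]:
    keys = set(KEY_COLUMNS) | {"epoch_index"}
    return [c for c in table.columns if c not in keys]


def average_by_subject(epoch_table: pd.DataFrame) -> pd.DataFrame:
    """Mean over valid (finite) epochs per (subject, condition, stage,
    channel).  Raises if any cell has no valid epoch at all."""
    feats = _feature_columns(epoch_table)
    clean = epoch_table.copy()
    clean[feats] = clean[feats].where(np.isfinite(clean[feats]), np.nan)
    out = (clean.groupby(KEY_COLUMNS, sort=True, as_index=False)[feats]
           .mean())
    if out[feats].isna().any().any():
        bad = out.loc[out[feats].isna().any(axis=1), KEY_COLUMNS[:2]]
        raise ValueError(
            f"cells with zero valid epochs: {bad.head().to_dict('records')}"
        )
    return out


def z_transform(subject_table: pd.DataFrame,
                epoch_table: pd.DataFrame) -> pd.DataFrame:
    """Within-subject z-scoring of the subject-level table.

    For each (subject, feature), mu and sigma come from that subject's
    epoch-level values pooled across channels, epochs and conditions;
    subject-level values become (v - mu) / sigma.
    """
    feats = _feature_columns(subject_table)
    out = subject_table.copy()
    clean = epoch_table.copy()
    clean[feats] = clean[feats].where(np.isfinite(clean[feats]), np.nan)
    stats = clean.groupby("subject_id")[feats].agg(["mean", "std"])
    for subj in out["subject_id"].unique():
        if subj not in stats.index:
            raise ValueError(f"no epoch-level statistics for {subj}")
        sel = out["subject_id"] == subj
        for f in feats:
            mu = stats.loc[subj, (f, "mean")]
            sd = stats.loc[subj, (f, "std")]
            if not np.isfinite(sd) or sd == 0:
                raise ValueError(f"zero/undefined SD for ({subj}, {f})")
            out.loc[sel, f] = (out.loc[sel, f] - mu) / sd
    return out


def to_matrix(subject_table: pd.DataFrame, features: list[str] | None = None
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Pivot a subject-level table into a decoding design matrix.

    Returns (X, labels, groups, column_names) where X has one row per
    (subject, condition) sample and one column per (feature, channel).
    """
    feats = features or [f for f in CANONICAL_FEATURES
                         if f in subject_table.columns]
    wide = subject_table.pivot_table(
        index=["subject_id", "condition"], columns="channel", values=feats,
        sort=True,
    )
    wide = wide.reindex(columns=pd.MultiIndex.from_product(
        [feats, sorted(subject_table["channel"].unique())]))
    if wide.isna().any().any():
        raise ValueError("missing (feature, channel) cells in pivot")
    X = wide.to_numpy()
    labels = wide.index.get_level_values("condition").to_numpy()
    groups = wide.index.get_level_values("subject_id").to_numpy()
    names = [f"{f}:{c}" for f, c in wide.columns]
    return X, labels, groups, names
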