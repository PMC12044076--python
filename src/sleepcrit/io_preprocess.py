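"""Recording container, EDF/hypnogram I/O and preprocessing.

The preprocessing chain mirrors standard sleep-EEG practice: 0.5-32 Hz
zero-phase band-pass, contiguous 20-s epochs aligned to the hypnogram,
amplitude-threshold artifact rejection (a reproducible surrogate for
visual inspection), and per-stage epoch-count equating between the two
nights of a subject.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal

from ._edf import write_edf

EPOCH_SECONDS = 20.0
STAGES = ("NREM", "REM", "artifact")

#: classic R&K stage labels collapsed on read
_STAGE_ALIASES = {
    "S1": "NREM", "S2": "NREM", "S3": "NREM", "S4": "NREM",
    "N1": "NREM", "N2": "NREM", "N3": "NREM",
    "NREM": "NREM", "REM": "REM", "R": "REM",
    "artifact": "artifact", "ART": "artifact",
}


@dataclass
class EpochedRecording:
    """One night of one subject under one condition, segmented into epochs.

    epochs
        Array (n_epochs, n_channels, n_samples), microvolts.
    stage_labels
        One of ``NREM``/``REM``/``artifact`` per epoch.
    """

    subject_id: str
    condition: str
    age_group: str
    channel_names: list[str]
    fs: float
    epochs: np.ndarray
    stage_labels: np.ndarray

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.stage_labels = np.asarray(self.stage_labels, dtype=object)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be (epoch, channel, sample)")
        n_ep, n_ch, n_samp = self.epochs.shape
        if n_ch != len(self.channel_names):
            raise ValueError("channel count does not match channel_names")
        expected = self.fs * EPOCH_SECONDS
        if abs(n_samp - expected) > 1e-6:
            raise ValueError(
                f"epoch length {n_samp} != fs * {EPOCH_SECONDS:g} = {expected:g}"
            )
        if len(self.stage_labels) != n_ep:
            raise ValueError("one stage label per epoch required")
        bad = set(self.stage_labels) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stage labels: {sorted(bad)}")
        if not np.all(np.isfinite(self.epochs)):
            raise ValueError("non-finite sample values")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_samples_per_epoch(self) -> int:
        return self.epochs.shape[2]

    def stage_mask(self, stage: str) -> np.ndarray:
        return self.stage_labels == stage

    def select_epochs(self, index: np.ndarray) -> "EpochedRecording":
        return replace(self, epochs=self.epochs[index],
                       stage_labels=self.stage_labels[index])


def write_recording(rec: EpochedRecording, edf_path, hypnogram_path) -> None:
    """Serialize a recording as 16-bit EDF plus a hypnogram TSV."""
    flat = rec.epochs.transpose(1, 0, 2).reshape(len(rec.channel_names), -1)
    write_edf(edf_path, flat, rec.fs, rec.channel_names,
              patient_id=rec.subject_id,
              recording_id=f"{rec.condition} {rec.age_group}")
    pd.DataFrame({
        "epoch_index": np.arange(rec.n_epochs),
        "stage": rec.stage_labels,
    }).to_csv(hypnogram_path, sep="\t", index=False)


def read_hypnogram(path) -> np.ndarray:
    """Read a hypnogram TSV; R&K substage labels collapse to NREM."""
    df = pd.read_csv(path, sep="\t")
    if "stage" not in df.columns:
        raise ValueError("hypnogram must have a 'stage' column")
    labels = []
    for raw in df["stage"].astype(str):
        if raw not in _STAGE_ALIASES:
            raise ValueError(f"unknown hypnogram stage {raw!r}")
        labels.append(_STAGE_ALIASES[raw])
    return np.array(labels, dtype=object)


def read_recording(edf_path, hypnogram_path, subject_id: str,
                   condition: str, age_group: str) -> EpochedRecording:
    """Load an EDF + hypnogram pair into an epoched recording.

    Epochs are cut contiguously from time zero; a trailing partial epoch
    is dropped.  The hypnogram must match the epoch count exactly (one
    epoch of slack is tolerated by truncating the longer side).
    """
    import mne

    raw = mne.io.read_raw_edf(str(edf_path), preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    data = raw.get_data() * 1e6  # mne returns volts
    n_per = int(round(fs * EPOCH_SECONDS))
    n_ep = data.shape[1] // n_per
    if n_ep < 1:
        raise ValueError("recording shorter than one epoch")
    labels = read_hypnogram(hypnogram_path)
    if abs(len(labels) - n_ep) > 1:
        raise ValueError(
            f"hypnogram has {len(labels)} labels for {n_ep} epochs"
        )
    n_ep = min(n_ep, len(labels))
    epochs = data[:, : n_ep * n_per].reshape(len(raw.ch_names), n_ep, n_per)
    return EpochedRecording(
        subject_id=subject_id, condition=condition, age_group=age_group,
        channel_names=list(raw.ch_names), fs=fs,
        epochs=epochs.transpose(1, 0, 2), stage_labels=labels[:n_ep],
    )


def bandpass(rec: EpochedRecording, low: float = 0.5, high: float = 32.0,
             order: int = 4) -> EpochedRecording:
    """Zero-phase Butterworth band-pass, applied per epoch and channel."""
    if not 0 < low < high < rec.fs / 2:
        raise ValueError("require 0 < low < high < fs/2")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=rec.fs,
                        output="sos")
    # constant-extension padding keeps the steep 0.5 Hz high-pass from
    # ringing at the epoch edges
    filtered = signal.sosfiltfilt(sos, rec.epochs, axis=-1,
                                  padtype="constant")
    return replace(rec, epochs=filtered)


def reject_artifact_epochs(rec: EpochedRecording,
                           threshold: float = 300.0) -> EpochedRecording:
    """Drop epochs where any channel exceeds ``threshold`` uV in magnitude.

    A deterministic surrogate for visual artifact screening; epoch order
    is preserved.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    peak = np.abs(rec.epochs).max(axis=(1, 2))
    keep = peak <= threshold
    if not keep.any():
        raise ValueError("all epochs rejected")
    return rec.select_epochs(keep)


def equate_epoch_counts(rec_a: EpochedRecording, rec_b: EpochedRecording,
                        stage: str, seed: int
                        ) -> tuple[EpochedRecording, EpochedRecording]:
    """Random-subsample the given stage so both recordings match counts.

    Epochs of the named stage in the larger recording are subsampled
    without replacement down to min(n_a, n_b); other stages are left
    untouched.  The selection is reproducible from ``seed``.
    """
    rng = np.random.default_rng(seed)
    out = []
    n_target = min(int(rec_a.stage_mask(stage).sum()),
                   int(rec_b.stage_mask(stage).sum()))
    if n_target < 1:
        raise ValueError(f"no {stage} epochs to equate")
    for rec in (rec_a, rec_b):
        idx_stage = np.flatnonzero(rec.stage_mask(stage))
        if len(idx_stage) == n_target:
            out.append(rec)
            continue
        chosen = rng.choice(idx_stage, size=n_target, replace=False)
        keep = np.ones(rec.n_epochs, dtype=bool)
        keep[idx_stage] = False
        keep[chosen] = True
        out.append(rec.select_epochs(keep))
    return out[0], out[1]
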