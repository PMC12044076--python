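"""Feature assembly, subject averaging and the within-subject z-transform."""

import numpy as np
import pandas as pd
import pytest

from sleepcrit import feature_table as ft
from sleepcrit.io_preprocess import EpochedRecording


def _recording(n_epochs=3, n_ch=2, fs=64.0, seed=0):
    rng = np.random.default_rng(seed)
    epochs = rng.normal(0, 20, size=(n_epochs, n_ch, int(fs * 20)))
    return EpochedRecording(
        subject_id=f"S{seed:03d}", condition="placebo", age_group="young",
        channel_names=[f"C{i}" for i in range(n_ch)], fs=fs,
        epochs=epochs, stage_labels=np.array(["NREM"] * n_epochs))


def _toy_tables():
    """Hand-built epoch and subject tables with two subjects/conditions."""
    rng = np.random.default_rng(0)
    rows = []
    for subj, scale in (("A", 1.0), ("B", 10.0)):
        for cond, shift in (("placebo", 0.0), ("caffeine", 0.5)):
            for ch in ("C0", "C1"):
                for ep in range(20):
                    rows.append({
                        "subject_id": subj, "condition": cond,
                        "age_group": "young", "stage": "NREM",
                        "channel": ch, "epoch_index": ep,
                        "feat": scale * (rng.normal() + shift),
                    })
    epoch = pd.DataFrame(rows)
    subject = ft.average_by_subject(epoch)
    return epoch, subject


class TestExtractFeatures:
    def test_canonical_columns_and_shape(self, tiny_study):
        recs, _ = tiny_study
        table = ft.extract_features(recs[0], "NREM")
        for col in ft.CANONICAL_FEATURES:
            assert col in table.columns
        assert len(table) == 6 * 3  # NREM epochs x channels

    def test_degenerate_epoch_flagged_without_failing(self):
        """A constant epoch yields flagged (NaN) metric cells; the healthy
        epoch's cells are unaffected."""
        rec = _recording(n_epochs=2)
        rec.epochs[1] = 5.0
        table = ft.extract_features(rec, "NREM")
        bad = table[table.epoch_index == 1]
        good = table[table.epoch_index == 0]
        for col in ("sampen", "lzc", "dfa"):
            assert bad[col].isna().all()
            assert np.isfinite(good[col]).all()

    def test_identical_epochs_give_identical_rows(self):
        rec = _recording(n_epochs=2)
        rec.epochs[1] = rec.epochs[0]
        table = ft.extract_features(rec, "NREM")
        a = table[table.epoch_index == 0][ft.CANONICAL_FEATURES].reset_index(
            drop=True)
        b = table[table.epoch_index == 1][ft.CANONICAL_FEATURES].reset_index(
            drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_missing_stage_raises(self):
        with pytest.raises(ValueError):
            ft.extract_features(_recording(), "REM")


class TestAverageBySubject:
    def test_mean_of_two_values(self):
        epoch = pd.DataFrame({
            "subject_id": ["A"] * 2, "condition": ["placebo"] * 2,
            "age_group": ["young"] * 2, "stage": ["NREM"] * 2,
            "channel": ["C0"] * 2, "epoch_index": [0, 1],
            "feat": [1.0, 3.0],
        })
        out = ft.average_by_subject(epoch)
        assert out["feat"].iloc[0] == 2.0

    def test_flagged_epochs_excluded_from_mean(self):
        epoch = pd.DataFrame({
            "subject_id": ["A"] * 5, "condition": ["placebo"] * 5,
            "age_group": ["young"] * 5, "stage": ["NREM"] * 5,
            "channel": ["C0"] * 5, "epoch_index": range(5),
            "feat": [1.0, 2.0, np.inf, 3.0, 2.0],
        })
        out = ft.average_by_subject(epoch)
        assert out["feat"].iloc[0] == 2.0

    def test_all_flagged_cell_raises(self):
        epoch = pd.DataFrame({
            "subject_id": ["A"], "condition": ["placebo"],
            "age_group": ["young"], "stage": ["NREM"],
            "channel": ["C0"], "epoch_index": [0], "feat": [np.nan],
        })
        with pytest.raises(ValueError, match="zero valid epochs"):
            ft.average_by_subject(epoch)


class TestZTransform:
    def test_subject_means_near_zero(self):
        epoch, subject = _toy_tables()
        z = ft.z_transform(subject, epoch)
        n_epochs = 40  # per (subject, channel): 20 per condition x 2
        for subj in ("A", "B"):
            vals = z[z.subject_id == subj]["feat"]
            assert np.all(np.abs(vals.mean()) < 3 / np.sqrt(n_epochs) + 0.5)

    def test_constant_shift_cancels(self):
        epoch, subject = _toy_tables()
        z0 = ft.z_transform(subject, epoch)
        epoch2 = epoch.copy()
        subject2 = subject.copy()
        sel = epoch2.subject_id == "A"
        epoch2.loc[sel, "feat"] += 42.0
        subject2.loc[subject2.subject_id == "A", "feat"] += 42.0
        z1 = ft.z_transform(subject2, epoch2)
        pd.testing.assert_frame_equal(z0, z1)

    def test_strictly_within_subject(self):
        """Perturbing one subject's data never changes another's z-scores."""
        epoch, subject = _toy_tables()
        z0 = ft.z_transform(subject, epoch)
        epoch2 = epoch.copy()
        sel = epoch2.subject_id == "A"
        epoch2.loc[sel, "feat"] = epoch2.loc[sel, "feat"] * 3.0 + 100.0
        z1 = ft.z_transform(subject, epoch2)
        pd.testing.assert_frame_equal(
            z0[z0.subject_id == "B"].reset_index(drop=True),
            z1[z1.subject_id == "B"].reset_index(drop=True))

    def test_ordering_preserved_within_subject(self):
        epoch, subject = _toy_tables()
        z = ft.z_transform(subject, epoch)
        for subj in ("A", "B"):
            raw = subject[(subject.subject_id == subj)
                          & (subject.condition == "placebo")]["feat"].values
            zs = z[(z.subject_id == subj)
                   & (z.condition == "placebo")]["feat"].values
            assert list(np.argsort(raw)) == list(np.argsort(zs))

    def test_zero_sd_raises(self):
        epoch = pd.DataFrame({
            "subject_id": ["A"] * 4, "condition": ["placebo"] * 4,
            "age_group": ["young"] * 4, "stage": ["NREM"] * 4,
            "channel": ["C0"] * 4, "epoch_index": range(4),
            "feat": [2.0] * 4,
        })
        subject = ft.average_by_subject(epoch)
        with pytest.raises(ValueError, match="SD"):
            ft.z_transform(subject, epoch)


class TestToMatrix:
    def test_design_matrix_shape_and_groups(self, tiny_study):
        recs, _ = tiny_study
        tables = [ft.extract_features(r, "NREM") for r in recs[:4]]
        epoch = pd.concat(tables, ignore_index=True)
        subject = ft.average_by_subject(epoch)
        X, y, groups, names = ft.to_matrix(subject)
        assert X.shape == (4, 11 * 3)  # 2 subjects x 2 conditions
        assert len(names) == 33
        assert set(y) == {"caffeine", "placebo"}
        assert all((groups == g).sum() == 2 for g in np.unique(groups))
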