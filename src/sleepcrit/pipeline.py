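"""End-to-end orchestration: simulate/load -> preprocess -> features ->
inference -> decoding, with a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, decoding, feature_table, stats_inference
from .io_preprocess import (EpochedRecording, bandpass, read_recording,
                            reject_artifact_epochs)
from .synthetic_data import SyntheticStudyConfig, generate_study
from .topography import report_topography_values

log = logging.getLogger("sleepcrit")


@dataclass
class PipelineConfig:
    """Knobs of a full run; defaults mirror the standard analysis."""

    out_dir: str = "results"
    data_dir: str | None = None          # real-data mode: metadata.csv inside
    synthetic: SyntheticStudyConfig = field(default_factory=SyntheticStudyConfig)
    stages: tuple[str, ...] = ("NREM", "REM")
    artifact_threshold: float = 300.0
    band_low: float = 0.5
    band_high: float = 32.0
    n_perm: int = 10_000
    alpha_levels: tuple[float, float] = (0.05, 0.01)
    decode_model: str = "svm_rbf"
    n_label_perm: int = 1000
    run_decoding: bool = True
    run_rf: bool = False
    n_rf_repeats: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        for a in self.alpha_levels:
            if not 0 < a < 1:
                raise ValueError("alpha levels must be in (0, 1)")


def _config_hash(config: PipelineConfig) -> str:
    def default(o):
        if hasattr(o, "__dict__"):
            return o.__dict__
        if isinstance(o, tuple):
            return list(o)
        return str(o)
    blob = json.dumps(asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_recordings(config: PipelineConfig) -> list[EpochedRecording]:
    """Recordings from the metadata CSV (real-data mode) or the generator."""
    if config.data_dir is not None:
        meta = pd.read_csv(Path(config.data_dir) / "metadata.csv")
        recs = []
        for _, row in meta.iterrows():
            recs.append(read_recording(
                Path(config.data_dir) / row["edf_path"],
                Path(config.data_dir) / row["hypnogram_path"],
                subject_id=row["subject_id"], condition=row["condition"],
                age_group=row["age_group"],
            ))
        return recs
    recordings, _ = generate_study(config.synthetic)
    return recordings


def significance_markers(p: np.ndarray,
                         levels: tuple[float, float]) -> list[str]:
    """'**' below the stricter level, '*' below the looser one, '' else."""
    loose, strict = max(levels), min(levels)
    return ["**" if v < strict else ("*" if v < loose else "") for v in p]


def run_pipeline(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Run the full analysis; writes TSVs plus a manifest and returns the
    result tables keyed by name."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results: dict[str, pd.DataFrame] = {}

    recs = load_recordings(config)
    processed = []
    for rec in recs:
        rec = bandpass(rec, config.band_low, config.band_high)
        rec = reject_artifact_epochs(rec, config.artifact_threshold)
        processed.append(rec)

    for stage in config.stages:
        epoch_tables = [feature_table.extract_features(r, stage)
                        for r in processed]
        epoch_table = pd.concat(epoch_tables, ignore_index=True)
        subj_table = feature_table.average_by_subject(epoch_table)
        z_table = feature_table.z_transform(subj_table, epoch_table)
        results[f"features_{stage}_epoch"] = epoch_table
        results[f"features_{stage}_subject"] = z_table

        channels = sorted(z_table["channel"].unique())
        stats_rows = []
        for feat in feature_table.CANONICAL_FEATURES:
            caff = z_table[z_table["condition"] == "caffeine"].pivot_table(
                index="subject_id", columns="channel", values=feat,
                sort=True)[channels].to_numpy()
            plac = z_table[z_table["condition"] == "placebo"].pivot_table(
                index="subject_id", columns="channel", values=feat,
                sort=True)[channels].to_numpy()
            res = stats_inference.paired_perm_pseudo_t(
                caff, plac, n_perm=config.n_perm, seed=config.seed)
            marks = significance_markers(res.p_corrected, config.alpha_levels)
            for i, ch in enumerate(channels):
                stats_rows.append({
                    "stage": stage, "feature": feat, "channel": ch,
                    "pseudo_t": res.pseudo_t[i],
                    "p_corrected": res.p_corrected[i],
                    "cohens_d": res.cohens_d[i], "significance": marks[i],
                })
        stats_table = pd.DataFrame(stats_rows)
        results[f"stats_{stage}"] = stats_table

        if config.run_decoding:
            dec_rows = []
            for feat in feature_table.CANONICAL_FEATURES:
                X, y, groups, names = feature_table.to_matrix(
                    z_table, features=[feat])
                cfg = decoding.DecodeConfig(
                    model=config.decode_model,
                    n_folds=min(10, len(np.unique(groups))),
                    n_label_perm=config.n_label_perm, seed=config.seed)
                dres = decoding.decode_single_feature(X, y, groups, cfg)
                for i, name in enumerate(names):
                    dec_rows.append({
                        "stage": stage, "feature": feat,
                        "channel": name.split(":", 1)[1],
                        "accuracy": dres.scores[i],
                        "p_corrected": dres.p_corrected[i],
                    })
            results[f"decoding_{stage}"] = pd.DataFrame(dec_rows)

        if config.run_rf:
            X, y, groups, names = feature_table.to_matrix(z_table)
            cfg = decoding.DecodeConfig(
                model="random_forest", n_rf_repeats=config.n_rf_repeats,
                inner_folds=min(7, len(np.unique(groups)) - 1),
                seed=config.seed)
            imp = decoding.rf_multifeature(X, y, groups, names, cfg)
            results[f"importance_{stage}"] = pd.DataFrame({
                "name": imp.feature_names,
                "importance_mean": imp.importance_mean,
                "importance_sd": imp.importance_sd,
            }).sort_values("importance_mean", ascending=False,
                           ignore_index=True)

        topo = report_topography_values(
            stats_table[stats_table["feature"] == "slope"][
                ["channel", "pseudo_t", "p_corrected"]].reset_index(drop=True))
        results[f"topography_{stage}"] = topo

    for name, table in results.items():
        table.to_csv(out_dir / f"{name}.tsv", sep="\t", index=False)
    manifest = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "version": __version__,
        "outputs": sorted(results),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log.info("pipeline complete: %d tables in %s", len(results), out_dir)
    return results
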