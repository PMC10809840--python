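"""End-to-end orchestration: synth -> extract -> stats/classify.

These functions back the command-line interface but are equally usable from
Python.  All stages are deterministic for a fixed config and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import evaluate, make_observations
from .errors import ConfigError, DataError
from .features import ALL_FEATURES, EpochGrid, SharpnessParams, extract_features
from .io import AnnotationSet, Recording, read_annotation_csv, read_edf
from .preprocess import PreprocessConfig, preprocess
from .segmentation import build_segments, label_epochs
from .stats import repeated_anova, topography
from .synth import SynthConfig, generate_study, write_dataset

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "attach_labels", "run_synth", "run_extract",
           "run_report"]


@dataclass
class PipelineConfig:
    """Single document controlling every stage (YAML-loadable)."""

    data_dir: str = "data"
    out_dir: str = "out"
    seed: int = 0
    n_subjects: int = 20
    synth: SynthConfig = field(default_factory=SynthConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    epoch_len: float = 1.0
    sharpness: SharpnessParams = field(default_factory=SharpnessParams)
    features: tuple[str, ...] = ALL_FEATURES
    channels: tuple[str, ...] | None = None  # None = all channels
    fusion_levels: tuple[int, ...] = (1, 2, 3)
    classifiers: tuple[str, ...] = ("svm", "knn", "lr", "nb")
    schemes: tuple[int, ...] = (1, 2, 3)
    classify_fusion: int = 3        # consensus of all raters
    classify_contact: str | None = "C4-P4"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        try:
            with open(path) as fh:
                doc = yaml.safe_load(fh) or {}
        except FileNotFoundError as exc:
            raise ConfigError(f"config file not found: {path}") from exc
        except yaml.YAMLError as exc:
            raise ConfigError(f"invalid YAML in {path}: {exc}") from exc
        cfg = cls()
        from .synth import BackgroundModel, RaterNoise

        builders = {"synth": SynthConfig, "preprocess": PreprocessConfig,
                    "sharpness": SharpnessParams}
        for key, val in doc.items():
            if not hasattr(cfg, key):
                raise ConfigError(f"unknown config key {key!r}")
            if key in builders and isinstance(val, dict):
                sub = dict(val)
                if key == "synth":
                    if isinstance(sub.get("rater_noise"), dict):
                        sub["rater_noise"] = RaterNoise(**sub["rater_noise"])
                    if isinstance(sub.get("background"), dict):
                        sub["background"] = BackgroundModel(**sub["background"])
                    if "seizure_intervals" in sub:
                        sub["seizure_intervals"] = tuple(
                            tuple(iv) for iv in sub["seizure_intervals"])
                try:
                    setattr(cfg, key, builders[key](**sub))
                except TypeError as exc:
                    raise ConfigError(f"bad {key} block: {exc}") from exc
            else:
                if isinstance(val, list):
                    val = tuple(val)
                setattr(cfg, key, val)
        return cfg


def attach_labels(features: pd.DataFrame, ann: AnnotationSet,
                  grid: EpochGrid, fusion_level: int,
                  subject: str) -> pd.DataFrame:
    """Join per-epoch segment labels (one fusion level) onto a feature table."""
    spec = build_segments(ann, fusion_level)
    labels = label_epochs(grid, spec)
    out = features.copy()
    out["subject"] = subject
    out["fusion"] = fusion_level
    epoch_idx = out["epoch"].to_numpy()
    valid = epoch_idx < len(labels)
    out = out[valid].copy()
    out["label"] = labels[out["epoch"].to_numpy()]
    out["period"] = np.where(out["label"] == "nonseizure",
                             "nonseizure", "seizure")
    return out


def run_synth(cfg: PipelineConfig, force: bool = False) -> list[dict]:
    """Generate the synthetic study and write EDF + annotation CSV files."""
    outdir = Path(cfg.data_dir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise DataError(f"output directory {outdir} is not empty "
                        "(use --force to overwrite)")
    study = generate_study(cfg.n_subjects, cfg.synth, seed=cfg.seed)
    manifest = write_dataset(study, outdir)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump({"seed": cfg.seed, "recordings": manifest}, fh, indent=2)
    log.info("wrote %d subjects to %s", len(manifest), outdir)
    return manifest


def _load_subject(edf_path: Path) -> tuple[str, Recording, AnnotationSet]:
    subject = edf_path.stem
    ann_path = edf_path.with_name(f"{subject}_annotations.csv")
    if not ann_path.exists():
        raise DataError(f"missing annotation file for subject {subject}: "
                        f"{ann_path}")
    rec = read_edf(edf_path)
    from .io import fuse_annotations

    ann = fuse_annotations(read_annotation_csv(ann_path))
    return subject, rec, ann


def run_extract(cfg: PipelineConfig) -> pd.DataFrame:
    """Read recordings, preprocess, extract features, attach labels.

    Writes ``features.csv`` (long format: subject, channel, epoch, feature,
    value, fusion, label, period) under the output directory and returns the
    frame.
    """
    data_dir = Path(cfg.data_dir)
    edfs = sorted(data_dir.glob("*.edf"))
    if not edfs:
        raise DataError(f"no EDF files found in {data_dir}")
    grid = EpochGrid(cfg.epoch_len)
    frames = []
    for edf_path in edfs:
        subject, rec, ann = _load_subject(edf_path)
        from .io import MontageMap, normalize_label, to_bipolar

        montage = MontageMap()
        have = {normalize_label(l).casefold() for l in rec.channel_labels}
        needed = {e.casefold() for pair in montage.pairs for e in pair}
        if needed <= have:
            rec = to_bipolar(rec, montage)  # referential input
        rec = preprocess(rec, cfg.preprocess)
        channels = list(cfg.channels) if cfg.channels else None
        feats = extract_features(rec, grid, cfg.sharpness,
                                 features=cfg.features, channels=channels)
        for k in cfg.fusion_levels:
            frames.append(attach_labels(feats, ann, grid, k, subject))
    table = pd.concat(frames, ignore_index=True)
    outdir = Path(cfg.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    table.to_csv(outdir / "features.csv", index=False)
    log.info("feature table: %d rows -> %s", len(table),
             outdir / "features.csv")
    return table


def run_report(cfg: PipelineConfig,
               table: pd.DataFrame | None = None) -> dict:
    """ANOVA tables, topography maps, and classifier reports from features.

    Reads ``features.csv`` when no table is passed.  Writes ``anova_*.csv``,
    ``topography.csv``, and ``classification.json`` under the output
    directory.  Schemes with an empty class are skipped with a logged
    reason.
    """
    outdir = Path(cfg.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    if table is None:
        path = outdir / "features.csv"
        if not path.exists():
            raise DataError(f"feature table not found: {path}")
        table = pd.read_csv(path)

    report: dict = {"seed": cfg.seed, "anova": {}, "classification": {}}

    core = [f for f in ("envelope", "sharpness", "don")
            if f in set(table["feature"])]
    for feat in core:
        sub = table[(table["feature"] == feat)
                    & (table["fusion"] == cfg.classify_fusion)]
        try:
            res = repeated_anova(sub, factors=("period", "channel"))
        except DataError as exc:
            log.warning("ANOVA skipped for %s: %s", feat, exc)
            continue
        res.table.to_csv(outdir / f"anova_{feat}.csv", index=False)
        report["anova"][feat] = res.table.to_dict(orient="records")

    topo_rows = []
    for feat in core:
        for k in cfg.fusion_levels:
            sub = table[(table["feature"] == feat) & (table["fusion"] == k)]
            if sub.empty:
                continue
            for stage in (None, "S1", "S2", "S3"):
                tm = topography(sub, feat, stage=stage)
                tm["feature"] = feat
                tm["fusion"] = k
                tm["stage"] = stage or "S"
                topo_rows.append(tm)
    if topo_rows:
        pd.concat(topo_rows, ignore_index=True).to_csv(
            outdir / "topography.csv", index=False)

    fused = table[table["fusion"] == cfg.classify_fusion]
    for scheme in cfg.schemes:
        for feat in core:
            try:
                obs = make_observations(fused, feat, scheme,
                                        channel=cfg.classify_contact)
            except DataError as exc:
                log.warning("scheme %d / %s skipped: %s", scheme, feat, exc)
                continue
            for clf in cfg.classifiers:
                try:
                    rep = evaluate(obs, classifier=clf, seed=cfg.seed)
                except DataError as exc:
                    log.warning("scheme %d / %s / %s skipped: %s",
                                scheme, feat, clf, exc)
                    continue
                report["classification"][f"scheme{scheme}/{feat}/{clf}"] = \
                    rep.to_dict()

    with open(outdir / "classification.json", "w") as fh:
        json.dump(report["classification"], fh, indent=2)
    with open(outdir / "report.json", "w") as fh:
        json.dump({k: v for k, v in report.items() if k != "classification"},
                  fh, indent=2, default=str)
    return report
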