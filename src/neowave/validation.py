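"""Study-level evaluation experiments run entirely on synthetic cohorts.

Three reusable experiments summarize what the pipeline recovers from its own
generative model:

* :func:`pattern_summary` - group-median feature contrasts (seizure vs
  nonseizure, stage progression) and single-feature SVM AUCs for the three
  classification schemes, pooled over independent study replicates.
* :func:`null_type_one_error` - empirical size of the repeated-ANOVA period
  test when the generator injects no seizure effect.
* :func:`power_envelope_gain` - empirical power of the same test when the
  seizure delta amplitude is a multiple of the background RMS.

All experiments derive every random stream from a single integer seed.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .classify import evaluate, make_observations
from .errors import DataError
from .features import EpochGrid, SharpnessParams, extract_features
from .pipeline import attach_labels
from .preprocess import PreprocessConfig, preprocess
from .stats import repeated_anova
from .synth import RaterNoise, SynthConfig, generate_study

__all__ = ["study_feature_table", "pattern_summary", "null_type_one_error",
           "power_envelope_gain"]

CORE = ("envelope", "sharpness", "don")


def study_feature_table(n_subjects: int, cfg: SynthConfig, seed: int,
                        channels: tuple[str, ...] = ("C4-P4",),
                        fusion: int = 3,
                        preprocess_cfg: PreprocessConfig | None = None,
                        features: tuple[str, ...] = CORE) -> pd.DataFrame:
    """Generate a cohort and return its labeled per-epoch feature table."""
    grid = EpochGrid(1.0)
    params = SharpnessParams()
    frames = []
    for subject, rec, ann in generate_study(n_subjects, cfg, seed=seed):
        rec = preprocess(rec, preprocess_cfg or PreprocessConfig())
        feats = extract_features(rec, grid, params, features=features,
                                 channels=list(channels))
        frames.append(attach_labels(feats, ann, grid, fusion, subject))
    return pd.concat(frames, ignore_index=True)


def pattern_summary(n_seeds: int = 20, n_subjects: int = 20, seed: int = 0,
                    cfg: SynthConfig | None = None,
                    channel: str = "C4-P4") -> dict:
    """Pooled feature contrasts and per-scheme SVM AUCs over study replicates.

    Returns a dict with, per core feature, the pooled epoch medians for the
    seizure and nonseizure periods and the three stages, plus the mean
    held-out SVM AUC per (scheme, feature).
    """
    cfg = cfg or SynthConfig()
    pooled: dict[str, dict[str, list]] = {
        f: {"seizure": [], "nonseizure": [], "S1": [], "S2": [], "S3": []}
        for f in CORE}
    aucs: dict[tuple[int, str], list[float]] = {
        (s, f): [] for s in (1, 2, 3) for f in CORE}
    rng = np.random.default_rng(seed)
    for i in range(n_seeds):
        rep_seed = int(rng.integers(0, 2 ** 31 - 1))
        table = study_feature_table(n_subjects, cfg, rep_seed,
                                    channels=(channel,))
        for f in CORE:
            sub = table[(table["feature"] == f)].dropna(subset=["value"])
            pooled[f]["seizure"].extend(
                sub.loc[sub["period"] == "seizure", "value"])
            pooled[f]["nonseizure"].extend(
                sub.loc[sub["period"] == "nonseizure", "value"])
            for s in ("S1", "S2", "S3"):
                pooled[f][s].extend(sub.loc[sub["label"] == s, "value"])
        for scheme in (1, 2, 3):
            for f in CORE:
                try:
                    obs = make_observations(table, f, scheme, channel=channel)
                    rep = evaluate(obs, classifier="svm", seed=rep_seed)
                except DataError:
                    continue
                aucs[(scheme, f)].append(rep.auc)
    out: dict = {"medians": {}, "auc": {}}
    for f in CORE:
        out["medians"][f] = {k: float(np.median(v)) if v else float("nan")
                             for k, v in pooled[f].items()}
    for (scheme, f), vals in aucs.items():
        out["auc"][f"scheme{scheme}/{f}"] = (float(np.mean(vals))
                                             if vals else float("nan"))
    return out


def _anova_period_p(cfg: SynthConfig, n_subjects: int, seed: int) -> float:
    table = study_feature_table(
        n_subjects, cfg, seed, channels=("CH01", "CH02"),
        preprocess_cfg=PreprocessConfig(pca_enabled=False),
        features=("envelope",))
    res = repeated_anova(table, factors=("period", "channel"))
    return res.p_value("period")


def _small_cfg(**overrides) -> SynthConfig:
    base = dict(
        n_channels=2, duration=40.0,
        seizure_intervals=((10.0, 20.0), (25.0, 35.0)),
        rater_noise=RaterNoise(jitter_s=0.0, miss_prob=0.0))
    base.update(overrides)
    return SynthConfig(**base)


def null_type_one_error(n_sims: int = 500, n_subjects: int = 8,
                        seed: int = 0, alpha: float = 0.05) -> float:
    """Empirical false-positive rate of the period test under a true null.

    Seizure intervals are annotated but carry no injected oscillation
    (amplitude 0), so period labels are exchangeable with background.
    """
    cfg = _small_cfg(seizure_amplitude=0.0, sharpness_shape=0.0,
                     nonlinearity_eps=(0.0, 0.0, 0.0))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_sims):
        p = _anova_period_p(cfg, n_subjects, int(rng.integers(0, 2 ** 31 - 1)))
        hits += p < alpha
    return hits / n_sims


def power_envelope_gain(gain: float = 3.0, n_sims: int = 100,
                        n_subjects: int = 20, seed: int = 0,
                        alpha: float = 0.05) -> float:
    """Empirical power of the period test for a uniform seizure gain.

    The seizure delta amplitude is ``gain`` times the background RMS in all
    three stages.
    """
    base = _small_cfg()
    cfg = replace(base, envelope_gain_profile=(1.0, 1.0, 1.0),
                  seizure_amplitude=gain * base.background.rms_uv)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_sims):
        p = _anova_period_p(cfg, n_subjects, int(rng.integers(0, 2 ** 31 - 1)))
        hits += p < alpha
    return hits / n_sims
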