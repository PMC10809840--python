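"""Synthetic multichannel EEG with staged seizures and multi-rater annotations.

The generator emulates the structure of neonatal cot-side EEG studies: 18
bipolar channels at 256 Hz, per-second seizure masks from three raters, and
seizure events whose three equal thirds (start / middle / end) carry distinct
amplitude, waveform peakedness, and intrawave frequency modulation.

Generative model
----------------
Background, per channel, is a dominant slow delta rhythm with a slowly
wandering instantaneous frequency and amplitude (never near zero, so its
Hilbert phase is well behaved) plus a low-weight band-limited 1/f^alpha
Gaussian noise floor.  Inside each annotated seizure interval a coherent
delta oscillation is added whose phase is intrawave-modulated,

    theta_m(t) = omega t + eps_k * sin(omega t),

with modulation depth ``eps_k`` per third, whose half-waves are raised to a
power (peakedness) and decorated with a peak-locked ~10 ms transient
(spike-and-wave morphology) scaled by ``sharpness_shape``, and whose
amplitude is ``seizure_amplitude * g_k`` per third.  Raters annotate the
ground-truth seizure seconds with Gaussian boundary jitter and a per-event
miss probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.signal import lfilter

from .errors import ConfigError
from .io import (AnnotationSet, MontageMap, Recording, fuse_annotations,
                 write_annotation_csv, write_edf)

__all__ = [
    "RaterNoise",
    "BackgroundModel",
    "SynthConfig",
    "generate_pure_tone",
    "generate_recording",
    "generate_study",
    "write_dataset",
]


@dataclass(frozen=True)
class RaterNoise:
    """Annotation corruption: boundary jitter (seconds, sd) and event misses."""

    jitter_s: float = 1.0
    miss_prob: float = 0.1


@dataclass(frozen=True)
class BackgroundModel:
    """Background EEG model: slow rhythm plus 1/f^alpha noise floor.

    ``noise_weight`` is the RMS of the noise floor relative to the rhythm;
    kept low because broadband noise dominates Hilbert-phase instantaneous
    frequency through phase slips.
    """

    exponent: float = 1.0                 # 1/f^alpha
    band: tuple[float, float] = (0.5, 60.0)
    noise_weight: float = 0.05
    rhythm_freq: float = 2.2              # Hz, neonatal delta
    rhythm_wander: float = 0.15           # relative sd of the frequency walk
    rhythm_amp_mod: float = 0.25          # slow amplitude modulation depth
    rms_uv: float = 15.0                  # overall background RMS in microvolts


@dataclass(frozen=True)
class SynthConfig:
    """Full description of one synthetic recording."""

    n_channels: int = 18
    fs: float = 256.0
    duration: float = 120.0
    seizure_intervals: tuple[tuple[float, float], ...] = ((30.0, 60.0), (75.0, 105.0))
    envelope_gain_profile: tuple[float, float, float] = (1.7, 2.2, 1.55)
    sharpness_shape: float = 0.5
    nonlinearity_eps: tuple[float, float, float] = (0.02, 0.15, 0.45)
    seizure_freq: float = 2.5
    seizure_amplitude: float = 37.5       # microvolts, before per-third gain
    rater_noise: RaterNoise = field(default_factory=RaterNoise)
    background: BackgroundModel = field(default_factory=BackgroundModel)
    n_raters: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.n_channels < 1:
            raise ConfigError("n_channels must be >= 1")
        if not 0.0 <= self.sharpness_shape <= 1.0:
            raise ConfigError("sharpness_shape must lie in [0, 1]")
        if any(not 0.0 <= e < 1.0 for e in self.nonlinearity_eps):
            raise ConfigError("modulation depths must satisfy 0 <= eps < 1")
        if any(g <= 0 for g in self.envelope_gain_profile):
            raise ConfigError("envelope gains must be positive")
        ivs = sorted(self.seizure_intervals)
        for (a, b) in ivs:
            if not (0 <= a < b <= self.duration):
                raise ConfigError(f"seizure interval ({a}, {b}) outside recording")
            if b - a < 3:
                raise ConfigError("seizure intervals must be at least 3 s long")
        for (_, b0), (a1, _) in zip(ivs, ivs[1:]):
            if a1 < b0:
                raise ConfigError("seizure intervals must be disjoint")
        f_top = max(self.background.band[1], self.seizure_freq)
        if self.fs <= 2 * f_top:
            raise ConfigError(
                f"fs={self.fs} must exceed twice the highest generated "
                f"frequency ({f_top} Hz)")


def generate_pure_tone(freq: float, amplitude: float, fs: float,
                       duration: float, eps: float = 0.0) -> Recording:
    """Single-channel intrawave-modulated tone x(t) = A cos(2 pi f t + eps sin(2 pi f t)).

    With ``eps = 0`` this is a pure sinusoid; for small ``eps`` the
    instantaneous frequency is f (1 + eps cos(2 pi f t)), so the degree of
    nonlinearity of the tone is eps / sqrt(2).
    """
    if not 0.0 <= eps < 1.0:
        raise ConfigError("eps must satisfy 0 <= eps < 1")
    if freq >= fs / 2:
        raise ConfigError("tone frequency must be below Nyquist")
    t = np.arange(int(round(duration * fs))) / fs
    theta = 2 * np.pi * freq * t
    x = amplitude * np.cos(theta + eps * np.sin(theta))
    return Recording(x[None, :], fs, ["tone"],
                     meta={"freq": freq, "eps": eps})


def _background_channel(rng: np.random.Generator, n: int, fs: float,
                        bg: BackgroundModel) -> np.ndarray:
    """One channel of rhythm-plus-noise background with unit RMS."""
    dt = 1.0 / fs
    # frequency of the rhythm follows an AR(1) (Ornstein-Uhlenbeck) walk
    tau = 3.0
    a = 1.0 - dt / tau
    innov = (bg.rhythm_wander * bg.rhythm_freq * np.sqrt(2 * dt / tau)
             * rng.standard_normal(n))
    f_inst = bg.rhythm_freq + lfilter([1.0], [1.0, -a], innov)
    f_inst = np.clip(f_inst, 0.3, 3.0 * bg.rhythm_freq)
    phase = 2 * np.pi * np.cumsum(f_inst) * dt + rng.uniform(0, 2 * np.pi)
    amp = 1.0 + bg.rhythm_amp_mod * np.sin(
        2 * np.pi * 0.1 * np.arange(n) * dt + rng.uniform(0, 2 * np.pi))
    rhythm = amp * np.cos(phase)
    rhythm /= max(np.std(rhythm), 1e-12)

    freqs = np.fft.rfftfreq(n, dt)
    shape = np.zeros_like(freqs)
    lo, hi = bg.band
    m = (freqs >= lo) & (freqs <= hi)
    shape[m] = freqs[m] ** (-bg.exponent / 2.0)
    spec = shape * np.exp(2j * np.pi * rng.random(len(freqs)))
    noise = np.fft.irfft(spec, n)
    noise /= max(np.std(noise), 1e-12)

    x = rhythm + bg.noise_weight * noise
    return x / np.std(x)


# waveform-family constants: half-wave power span, peak-locked transient
# gain and temporal half-width (seconds)
_PEAK_POWER_SPAN = 2.0
_SPIKE_GAIN = 1.0
_SPIKE_WIDTH_S = 0.010


def _seizure_wave(t_rel: np.ndarray, freq: float, shape: float,
                  eps: float) -> np.ndarray:
    """Unit-scale seizure waveform: peaked, spike-decorated, FM-modulated.

    The intrawave modulation uses a cosine phase term, theta + eps cos(theta),
    so the instantaneous-frequency spread is eps/sqrt(2) (as for the sine
    variant) while the phase rate at the extrema stays ~1: modulation depth
    then controls nonlinearity without narrowing the peaks, keeping the
    sharpness and nonlinearity knobs independent.
    """
    theta = 2 * np.pi * freq * t_rel
    theta_m = theta + eps * np.cos(theta)
    u = np.cos(theta_m)
    p = 1.0 + _PEAK_POWER_SPAN * shape
    base = np.sign(u) * np.abs(u) ** p
    # Gaussian transient locked to each positive peak (theta_m = 0 mod 2 pi)
    ph = np.mod(theta_m + np.pi, 2 * np.pi) - np.pi
    spike = np.exp(-0.5 * (ph / (2 * np.pi * freq * _SPIKE_WIDTH_S)) ** 2)
    return base + _SPIKE_GAIN * shape * spike


def _stage_bounds(start_s: float, end_s: float) -> list[tuple[float, float]]:
    n = end_s - start_s
    b1, b2 = round(n / 3), round(2 * n / 3)
    return [(start_s, start_s + b1), (start_s + b1, start_s + b2),
            (start_s + b2, end_s)]


def _rater_mask(truth_events: list[tuple[int, int]], n_seconds: int,
                noise: RaterNoise, rng: np.random.Generator) -> np.ndarray:
    mask = np.zeros(n_seconds, dtype=int)
    for (a, b) in truth_events:
        if noise.miss_prob > 0 and rng.random() < noise.miss_prob:
            continue
        if noise.jitter_s > 0:
            a = a + int(round(rng.normal(0, noise.jitter_s)))
            b = b + int(round(rng.normal(0, noise.jitter_s)))
        a, b = max(a, 0), min(b, n_seconds)
        if b > a:
            mask[a:b] = 1
    return mask


def generate_recording(cfg: SynthConfig,
                       rng: np.random.Generator | None = None
                       ) -> tuple[Recording, AnnotationSet]:
    """Generate one recording and its three-rater annotation set.

    The seizure oscillation is coherent across channels (uniform spatial
    gain); background noise is independent per channel.  Identical seeds
    produce bit-identical output.
    """
    cfg.validate()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    fs = cfg.fs
    n = int(round(cfg.duration * fs))
    n_seconds = int(np.ceil(cfg.duration))
    t = np.arange(n) / fs

    x = np.vstack([_background_channel(rng, n, fs, cfg.background)
                   for _ in range(cfg.n_channels)])

    truth_events: list[tuple[int, int]] = []
    for (a, b) in sorted(cfg.seizure_intervals):
        truth_events.append((int(round(a)), int(round(b))))
        wave = np.zeros(n)
        for k, (s0, s1) in enumerate(_stage_bounds(a, b)):
            sl = slice(int(round(s0 * fs)), int(round(s1 * fs)))
            gain = cfg.envelope_gain_profile[k] * cfg.seizure_amplitude
            wave[sl] = (gain / cfg.background.rms_uv) * _seizure_wave(
                t[sl] - a, cfg.seizure_freq, cfg.sharpness_shape,
                cfg.nonlinearity_eps[k])
        # short cosine ramps remove on/offset discontinuities
        ramp = int(round(0.25 * fs))
        i0, i1 = int(round(a * fs)), int(round(b * fs))
        env = np.ones(i1 - i0)
        if ramp > 0 and len(env) > 2 * ramp:
            r = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
            env[:ramp] = r
            env[-ramp:] = r[::-1]
        x[:, i0:i1] += wave[i0:i1] * env

    x *= cfg.background.rms_uv

    truth = np.zeros(n_seconds, dtype=int)
    for (a, b) in truth_events:
        truth[a:b] = 1
    if cfg.rater_noise.jitter_s == 0 and cfg.rater_noise.miss_prob == 0:
        masks = np.tile(truth, (cfg.n_raters, 1))
    else:
        masks = np.vstack([
            _rater_mask(truth_events, n_seconds, cfg.rater_noise, rng)
            for _ in range(cfg.n_raters)])

    if cfg.n_channels == len(LONGITUDINAL_BIPOLAR_LABELS):
        labels = list(LONGITUDINAL_BIPOLAR_LABELS)
    else:
        labels = [f"CH{i + 1:02d}" for i in range(cfg.n_channels)]
    rec = Recording(x, fs, labels, meta={"synthetic": True, "seed": cfg.seed,
                                         "truth_mask": truth})
    return rec, fuse_annotations(masks)


LONGITUDINAL_BIPOLAR_LABELS = MontageMap().labels


def _lognormal_factor(rng: np.random.Generator, cv: float,
                      size: int | None = None):
    """Mean-one lognormal multiplier(s) with coefficient of variation ``cv``."""
    if cv <= 0:
        return 1.0 if size is None else np.ones(size)
    sigma = np.sqrt(np.log(1 + cv ** 2))
    return np.exp(rng.normal(-sigma ** 2 / 2, sigma, size))


def generate_study(n_subjects: int, cfg: SynthConfig | None = None,
                   seed: int = 0, between_subject_cv: float = 0.2,
                   stage_jitter_cv: float = 0.15,
                   eps_jitter_cv: float = 0.10
                   ) -> list[tuple[str, Recording, AnnotationSet]]:
    """Generate a cohort with lognormal between-subject variation.

    Each subject gets an independent substream of ``seed``.  The overall
    seizure amplitude and background RMS vary with coefficient of variation
    ``between_subject_cv``; in addition the per-stage envelope gains and
    modulation depths are jittered per subject (``stage_jitter_cv``,
    ``eps_jitter_cv``), reflecting that seizure progression differs between
    neonates.
    """
    cfg = cfg or SynthConfig()
    ss = np.random.SeedSequence(seed)
    out = []
    for i, child in enumerate(ss.spawn(n_subjects)):
        rng = np.random.default_rng(child)
        amp_f = float(_lognormal_factor(rng, between_subject_cv))
        bg_f = float(_lognormal_factor(rng, between_subject_cv))
        g_f = _lognormal_factor(rng, stage_jitter_cv, 3)
        e_f = _lognormal_factor(rng, eps_jitter_cv, 3)
        gains = tuple(g * f for g, f in zip(cfg.envelope_gain_profile, g_f))
        eps = tuple(min(e * f, 0.95)
                    for e, f in zip(cfg.nonlinearity_eps, e_f))
        sub_cfg = replace(
            cfg,
            seizure_amplitude=cfg.seizure_amplitude * amp_f,
            envelope_gain_profile=gains,
            nonlinearity_eps=eps,
            background=replace(cfg.background,
                               rms_uv=cfg.background.rms_uv * bg_f),
        )
        rec, ann = generate_recording(sub_cfg, rng)
        out.append((f"subj{i + 1:03d}", rec, ann))
    return out


def write_dataset(study: list[tuple[str, Recording, AnnotationSet]],
                  outdir: str | Path) -> list[dict]:
    """Write a study as per-subject EDF + annotation CSV; returns a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for subject_id, rec, ann in study:
        edf_path = outdir / f"{subject_id}.edf"
        csv_path = outdir / f"{subject_id}_annotations.csv"
        write_edf(rec, edf_path)
        write_annotation_csv(ann.rater_masks, csv_path)
        manifest.append({"subject": subject_id, "edf": edf_path.name,
                         "annotations": csv_path.name,
                         "fs": rec.fs, "n_channels": rec.n_channels,
                         "duration_s": rec.duration})
    return manifest
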