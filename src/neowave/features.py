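"""Waveform features on nonoverlapping epochs.

Three core measures quantify seizure morphology:

* **complex envelope** - per-epoch median of the analytic-signal magnitude
  (Hilbert transform); tracks oscillation amplitude robustly.
* **epileptic sharpness** - median over detected extrema of the mean
  absolute voltage drop from each extremum to the signal 7 ms on either
  side.  Extrema come from an order-statistic (weighted-median) filter with
  a sliding Tukey window, making detection amplitude-scale free.
* **degree of nonlinearity (DoN)** - standard deviation of the Hilbert
  instantaneous frequency normalized by the segment's zero-crossing
  frequency; quantifies intrawave frequency modulation, i.e. departure of
  the waveform from a sinusoid.  For a tone cos(wt + eps sin wt) the DoN is
  eps / sqrt(2).

Comparator features: five-band Hamming periodogram powers, the high/low
energy ratio (beta+gamma)/(theta+alpha), and RMS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import hilbert, periodogram
from scipy.signal.windows import tukey

from .errors import DataError
from .io import Recording

__all__ = [
    "EpochGrid",
    "SharpnessParams",
    "complex_envelope",
    "detect_extrema",
    "sharpness",
    "peak_sharpness",
    "degree_of_nonlinearity",
    "band_powers",
    "energy_ratio",
    "rms",
    "extract_features",
    "BANDS",
]

#: Canonical EEG frequency bands in Hz (gamma extends to Nyquist).
BANDS: tuple[tuple[str, float, float], ...] = (
    ("delta", 1.0, 4.0),
    ("theta", 4.0, 9.0),
    ("alpha", 9.0, 13.0),
    ("beta", 13.0, 30.0),
    ("gamma", 30.0, np.inf),
)


@dataclass(frozen=True)
class EpochGrid:
    """Nonoverlapping epochs aligned to sample 0; a final partial epoch is dropped."""

    epoch_len: float = 1.0  # seconds

    def n_epochs(self, duration: float) -> int:
        return int(np.floor(duration / self.epoch_len + 1e-9))

    def slices(self, n_samples: int, fs: float) -> list[slice]:
        step = int(round(self.epoch_len * fs))
        return [slice(i * step, (i + 1) * step)
                for i in range(n_samples // step)]


@dataclass(frozen=True)
class SharpnessParams:
    window_len: int = 64        # sliding-window samples (0.25 s at 256 Hz)
    tukey_taper: float = 0.5
    flank_ms: float = 7.0
    both_polarities: bool = True
    interp_flanks: bool = True  # linear interpolation at exactly +/- flank_ms

    def __post_init__(self) -> None:
        if self.window_len < 8:
            raise DataError("window_len must be >= 8 samples")
        if not 0 <= self.tukey_taper <= 1:
            raise DataError("tukey_taper must lie in [0, 1]")
        if self.flank_ms <= 0:
            raise DataError("flank_ms must be positive")


def complex_envelope(x: np.ndarray) -> float:
    """Median magnitude of the analytic signal over one epoch."""
    x = np.asarray(x, dtype=float)
    if not x.any():
        return 0.0
    return float(np.median(np.abs(hilbert(x))))


def _weighted_median_track(x: np.ndarray, window_len: int,
                           taper: float) -> np.ndarray:
    """Order-statistic filter track: Tukey-weighted median of the trailing window.

    Realizations advance one sample at a time; ``track[n]`` summarizes the
    window ending at ``n``, so the track lags the signal and intersects it
    only around turning points.  The left edge is padded with the first
    sample so the track covers the whole input.
    """
    w = tukey(window_len, taper)
    if w.sum() == 0:  # degenerate taper, fall back to flat weights
        w = np.ones(window_len)
    xp = np.pad(x, (window_len - 1, 0), mode="edge")
    windows = sliding_window_view(xp, window_len)
    order = np.argsort(windows, axis=1)
    sorted_vals = np.take_along_axis(windows, order, axis=1)
    cum_w = np.cumsum(w[order], axis=1)
    k = np.argmax(cum_w >= 0.5 * w.sum(), axis=1)
    return sorted_vals[np.arange(len(x)), k]


def _excursion_maxima(x: np.ndarray, track: np.ndarray) -> np.ndarray:
    """Maxima of excursions of ``x`` above ``track`` bracketed by crossings."""
    above = x > track
    d = np.diff(above.astype(np.int8))
    starts = np.where(d == 1)[0] + 1
    ends = np.where(d == -1)[0] + 1
    # pair each start-crossing with the next end-crossing; excursions touching
    # a record edge have no bracketing intersection and are dropped
    peaks = []
    j = 0
    for s in starts:
        while j < len(ends) and ends[j] <= s:
            j += 1
        if j == len(ends):
            break
        e = ends[j]
        peaks.append(s + int(np.argmax(x[s:e])))
    return np.asarray(peaks, dtype=int)


def detect_extrema(x: np.ndarray, params: SharpnessParams | None = None
                   ) -> np.ndarray:
    """Adaptive extrema detection via the order-statistic filter.

    The Tukey-weighted sliding median forms an adaptive threshold track;
    peaks are the maxima of excursions of the signal above the track (and,
    with ``both_polarities``, minima via the negated signal).  Detection is
    invariant to positive rescaling and additive offsets.
    """
    params = params or SharpnessParams()
    x = np.asarray(x, dtype=float)
    if len(x) <= params.window_len:
        raise DataError("signal shorter than the order-statistic window")
    track = _weighted_median_track(x, params.window_len, params.tukey_taper)
    peaks = _excursion_maxima(x, track)
    if params.both_polarities:
        neg = _excursion_maxima(-x, -track)
        peaks = np.unique(np.concatenate([peaks, neg]))
    return np.sort(peaks)


def peak_sharpness(x: np.ndarray, peaks: np.ndarray, fs: float,
                   flank_ms: float = 7.0, interp: bool = True
                   ) -> np.ndarray:
    """Per-extremum sharpness: mean absolute drop to the flanks at +/- flank_ms.

    Extrema whose flanks fall outside the segment are dropped.  Flank values
    are linearly interpolated at exactly +/- flank_ms (the default keeps the
    measure sampling-rate independent); with ``interp=False`` the nearest
    sample is used.
    """
    x = np.asarray(x, dtype=float)
    k = flank_ms * fs / 1000.0
    peaks = np.asarray(peaks, dtype=float)
    ok = (peaks - k >= 0) & (peaks + k <= len(x) - 1)
    peaks = peaks[ok]
    if len(peaks) == 0:
        return np.empty(0)
    idx = np.arange(len(x))
    if interp:
        lo = np.interp(peaks - k, idx, x)
        hi = np.interp(peaks + k, idx, x)
    else:
        lo = x[np.clip(np.round(peaks - k).astype(int), 0, len(x) - 1)]
        hi = x[np.clip(np.round(peaks + k).astype(int), 0, len(x) - 1)]
    center = x[peaks.astype(int)]
    return (np.abs(center - lo) + np.abs(center - hi)) / 2.0


def sharpness(x: np.ndarray, fs: float,
              params: SharpnessParams | None = None) -> float:
    """Epileptic sharpness: median of per-extremum flank drops.

    Returns NaN (missing-value flag) when no usable extremum exists.
    """
    params = params or SharpnessParams()
    peaks = detect_extrema(x, params)
    vals = peak_sharpness(x, peaks, fs, params.flank_ms, params.interp_flanks)
    if len(vals) == 0:
        return float("nan")
    return float(np.median(vals))


def degree_of_nonlinearity(x: np.ndarray, fs: float, edge_s: float = 0.1,
                           return_quality: bool = False):
    """DoN: std of (IF - IF_z) / IF_z over the segment interior.

    IF is the derivative of the unwrapped Hilbert phase (central
    differences); IF_z is the scalar zero-crossing frequency of the segment,
    zero-crossing count / (2 x duration).  The first and last ``edge_s``
    seconds are excluded from the std to suppress Hilbert edge effects.
    Negative IF samples (phase slips) are retained but their fraction is
    reported as a quality metric; above 20% a warning is issued.

    Returns NaN when the segment has no zero crossings.
    """
    x = np.asarray(x, dtype=float)
    zc = int(np.sum(np.diff(np.signbit(x)) != 0))
    duration = len(x) / fs
    if_z = zc / (2.0 * duration)
    if if_z == 0:
        return (float("nan"), float("nan")) if return_quality else float("nan")
    phase = np.unwrap(np.angle(hilbert(x)))
    inst_freq = np.gradient(phase) * fs / (2 * np.pi)
    edge = int(round(edge_s * fs))
    core = inst_freq[edge:len(x) - edge] if edge > 0 and len(x) > 2 * edge \
        else inst_freq
    neg_frac = float(np.mean(core < 0))
    if neg_frac > 0.20:
        warnings.warn(
            f"{neg_frac:.0%} of instantaneous-frequency samples are negative "
            "(phase slips); DoN estimate may be unstable", stacklevel=2)
    value = float(np.std((core - if_z) / if_z))
    return (value, neg_frac) if return_quality else value


def band_powers(x: np.ndarray, fs: float) -> np.ndarray:
    """Hamming-windowed periodogram power in the five canonical bands."""
    x = np.asarray(x, dtype=float)
    freqs, pxx = periodogram(x, fs=fs, window="hamming")
    out = np.empty(len(BANDS))
    for i, (_, lo, hi) in enumerate(BANDS):
        m = (freqs >= lo) & (freqs < hi)
        out[i] = pxx[m].sum()
    return out


def energy_ratio(bp: np.ndarray) -> float:
    """(beta + gamma) / (theta + alpha); delta excluded from both sides."""
    bp = np.asarray(bp, dtype=float)
    denom = bp[1] + bp[2]
    if denom == 0:
        return float("nan")
    return float((bp[3] + bp[4]) / denom)


def rms(x: np.ndarray) -> float:
    """Root-mean-square amplitude."""
    x = np.asarray(x, dtype=float)
    if len(x) == 0:
        raise DataError("rms of an empty segment is undefined")
    return float(np.sqrt(np.mean(x ** 2)))


CORE_FEATURES = ("envelope", "sharpness", "don")
BAND_FEATURES = tuple(name for name, _, _ in BANDS)
ALL_FEATURES = CORE_FEATURES + BAND_FEATURES + ("er", "rms")


def extract_features(rec: Recording, grid: EpochGrid | None = None,
                     params: SharpnessParams | None = None,
                     features: tuple[str, ...] = ALL_FEATURES,
                     channels: list[str] | None = None) -> pd.DataFrame:
    """Per-channel, per-epoch feature table (tidy long format).

    Returns a DataFrame with columns ``channel, epoch, feature, value``.
    ``channels`` restricts extraction to a subset of channel labels.
    """
    grid = grid or EpochGrid()
    params = params or SharpnessParams()
    labels = channels if channels is not None else rec.channel_labels
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # per-epoch quality warnings -> table
        for label in labels:
            x = rec.channel(label)
            for ep, sl in enumerate(grid.slices(len(x), rec.fs)):
                seg = x[sl]
                vals: dict[str, float] = {}
                if "envelope" in features:
                    vals["envelope"] = complex_envelope(seg)
                if "sharpness" in features:
                    vals["sharpness"] = sharpness(seg, rec.fs, params)
                if "don" in features:
                    vals["don"] = degree_of_nonlinearity(seg, rec.fs)
                need_bands = any(f in features for f in BAND_FEATURES + ("er",))
                if need_bands:
                    bp = band_powers(seg, rec.fs)
                    for i, name in enumerate(BAND_FEATURES):
                        if name in features:
                            vals[name] = bp[i]
                    if "er" in features:
                        vals["er"] = energy_ratio(bp)
                if "rms" in features:
                    vals["rms"] = rms(seg)
                rows.extend({"channel": label, "epoch": ep,
                             "feature": f, "value": v}
                            for f, v in vals.items())
    return pd.DataFrame(rows, columns=["channel", "epoch", "feature", "value"])
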