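"""Recording and annotation containers, EDF and CSV I/O, bipolar montage.

EEG recordings are held as a plain ``channels x samples`` float array in
microvolts.  Seizure annotations are per-second binary masks, one per rater;
fusing them at level ``k`` marks a second as seizure when at least ``k``
raters agree.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DataError

__all__ = [
    "Recording",
    "AnnotationSet",
    "MontageMap",
    "LONGITUDINAL_BIPOLAR_PAIRS",
    "read_edf",
    "write_edf",
    "to_bipolar",
    "fuse_annotations",
    "read_annotation_csv",
    "write_annotation_csv",
    "normalize_label",
]

#: The standard 18-contact longitudinal ("double banana") bipolar layout.
LONGITUDINAL_BIPOLAR_PAIRS: tuple[tuple[str, str], ...] = (
    ("Fp1", "F3"), ("F3", "C3"), ("C3", "P3"), ("P3", "O1"),
    ("Fp2", "F4"), ("F4", "C4"), ("C4", "P4"), ("P4", "O2"),
    ("Fp1", "F7"), ("F7", "T3"), ("T3", "T5"), ("T5", "O1"),
    ("Fp2", "F8"), ("F8", "T4"), ("T4", "T6"), ("T6", "O2"),
    ("Fz", "Cz"), ("Cz", "Pz"),
)

_LABEL_PREFIXES = ("EEG ", "EEG-", "EEG_")
_LABEL_SUFFIXES = ("-REF", "-LE", "-AVG", "-A1", "-A2", "-M1", "-M2")


def normalize_label(label: str) -> str:
    """Strip common EDF channel-label decorations (``EEG Fp1-REF`` -> ``Fp1``)."""
    out = label.strip()
    for pre in _LABEL_PREFIXES:
        if out.upper().startswith(pre.upper()):
            out = out[len(pre):]
            break
    for suf in _LABEL_SUFFIXES:
        if out.upper().endswith(suf):
            out = out[: -len(suf)]
            break
    return out.strip()


@dataclass
class Recording:
    """Uniformly sampled multichannel signal in microvolts."""

    samples: np.ndarray          # (n_channels, n_samples), float
    fs: float                    # Hz
    channel_labels: list[str]
    start_time: object | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise DataError("samples must be a 2-D channels x time array")
        if self.fs <= 0:
            raise DataError("sampling rate must be positive")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise DataError("one label per channel required")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise DataError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        """Return one channel's samples by (case-insensitive) label."""
        want = normalize_label(label).casefold()
        for i, lab in enumerate(self.channel_labels):
            if normalize_label(lab).casefold() == want:
                return self.samples[i]
        raise DataError(f"channel {label!r} not found")

    def copy_with(self, samples: np.ndarray, **meta) -> "Recording":
        new_meta = dict(self.meta)
        new_meta.update(meta)
        return Recording(samples, self.fs, list(self.channel_labels),
                         self.start_time, new_meta)


@dataclass
class AnnotationSet:
    """Per-rater binary seizure masks at 1-second resolution plus fusions.

    ``fused[k][t]`` is 1 when at least ``k`` raters marked second ``t`` as
    seizure, so the fused masks are nested: fused[3] <= fused[2] <= fused[1].
    """

    rater_masks: np.ndarray      # (n_raters, n_seconds) of 0/1
    fused: dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rater_masks = np.asarray(self.rater_masks, dtype=int)
        if self.rater_masks.ndim != 2:
            raise DataError("rater_masks must be raters x seconds")
        if not np.isin(self.rater_masks, (0, 1)).all():
            raise DataError("annotation masks must be binary")
        if not self.fused:
            counts = self.rater_masks.sum(axis=0)
            self.fused = {
                k: (counts >= k).astype(int)
                for k in range(1, self.n_raters + 1)
            }

    @property
    def n_raters(self) -> int:
        return self.rater_masks.shape[0]

    @property
    def n_seconds(self) -> int:
        return self.rater_masks.shape[1]


@dataclass
class MontageMap:
    """Ordered anode/cathode electrode pairs defining a bipolar derivation."""

    pairs: tuple[tuple[str, str], ...] = LONGITUDINAL_BIPOLAR_PAIRS

    @property
    def labels(self) -> list[str]:
        return [f"{a}-{b}" for a, b in self.pairs]


def fuse_annotations(masks: np.ndarray) -> AnnotationSet:
    """Fuse per-rater binary masks at every agreement level.

    Parameters
    ----------
    masks : array, shape (n_raters, n_seconds)
        0/1 seizure annotation per rater per second.
    """
    masks = np.asarray(masks)
    if not np.isin(masks, (0, 1)).all():
        raise DataError("annotation masks must contain only 0 and 1")
    return AnnotationSet(rater_masks=masks.astype(int))


def to_bipolar(rec: Recording, montage: MontageMap | None = None) -> Recording:
    """Derive a bipolar recording (anode minus cathode per pair).

    Referential-offset free by construction: adding any common signal to all
    referential channels leaves the output unchanged.
    """
    montage = montage or MontageMap()
    have = {normalize_label(l).casefold(): i for i, l in enumerate(rec.channel_labels)}
    missing = [f"{a}-{b}" for a, b in montage.pairs
               if a.casefold() not in have or b.casefold() not in have]
    if missing:
        raise DataError(f"electrodes missing for bipolar pairs: {', '.join(missing)}")
    rows = [rec.samples[have[a.casefold()]] - rec.samples[have[b.casefold()]]
            for a, b in montage.pairs]
    return Recording(np.vstack(rows), rec.fs, montage.labels, rec.start_time,
                     dict(rec.meta, montage="longitudinal-bipolar"))


# ---------------------------------------------------------------------------
# EDF I/O.  Reading goes through MNE; writing uses a minimal EDF encoder
# (16-bit, 1-second data records) sufficient for round-tripping synthetic
# recordings through any standard EDF reader.
# ---------------------------------------------------------------------------

def read_edf(path: str | Path) -> Recording:
    """Read an EDF/EDF+ file into a :class:`Recording` (samples in microvolts)."""
    import mne

    path = Path(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = mne.io.read_raw_edf(path, preload=True, verbose="ERROR")
    except Exception as exc:  # noqa: BLE001 - normalize reader failures
        raise DataError(f"cannot read EDF file {path}: {exc}") from exc
    data = raw.get_data() * 1e6  # MNE holds EEG in volts
    labels = [normalize_label(name) for name in raw.ch_names]
    return Recording(data, float(raw.info["sfreq"]), labels,
                     raw.info.get("meas_date"), {"source": str(path)})


def _edf_field(value, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        s = f"{float(value):.{max(width - 6, 1)}g}"[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: Recording, path: str | Path) -> None:
    """Write a recording as EDF with 16-bit samples and 1-second records.

    The sampling rate must be a positive integer and the duration is padded
    to a whole number of seconds (with edge values) as EDF requires complete
    data records.
    """
    path = Path(path)
    fs = int(round(rec.fs))
    if abs(fs - rec.fs) > 1e-9 or fs <= 0:
        raise DataError("EDF writer requires an integer sampling rate")
    n_rec = math.ceil(rec.n_samples / fs)
    n_ch = rec.n_channels
    data = rec.samples
    if n_rec * fs != rec.n_samples:
        pad = n_rec * fs - rec.n_samples
        data = np.pad(data, ((0, 0), (0, pad)), mode="edge")

    phys_max = np.maximum(np.abs(data).max(axis=1), 1.0)
    dig_min, dig_max = -32768, 32767
    scale = (dig_max - dig_min) / (2 * phys_max)
    digital = np.clip(np.round((data + phys_max[:, None]) * scale[:, None]
                               + dig_min), dig_min, dig_max).astype("<i2")

    header = b"".join([
        _edf_field("0", 8),
        _edf_field("X X X X", 80),
        _edf_field("Startdate X X X X", 80),
        _edf_field("01.01.00", 8),
        _edf_field("00.00.00", 8),
        _edf_field(256 * (n_ch + 1), 8),
        _edf_field("", 44),
        _edf_field(n_rec, 8),
        _edf_field(1, 8),
        _edf_field(n_ch, 4),
    ])
    sig = b"".join([
        b"".join(_edf_field(lab[:16], 16) for lab in rec.channel_labels),
        b"".join(_edf_field("", 80) for _ in range(n_ch)),
        b"".join(_edf_field("uV", 8) for _ in range(n_ch)),
        b"".join(_edf_field(f"{-m:.6g}"[:8], 8) for m in phys_max),
        b"".join(_edf_field(f"{m:.6g}"[:8], 8) for m in phys_max),
        b"".join(_edf_field(dig_min, 8) for _ in range(n_ch)),
        b"".join(_edf_field(dig_max, 8) for _ in range(n_ch)),
        b"".join(_edf_field("", 80) for _ in range(n_ch)),
        b"".join(_edf_field(fs, 8) for _ in range(n_ch)),
        b"".join(_edf_field("", 32) for _ in range(n_ch)),
    ])
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        # data records: per record, each channel's fs samples contiguously
        recs = digital.reshape(n_ch, n_rec, fs)
        fh.write(np.ascontiguousarray(recs.transpose(1, 0, 2)).tobytes())


# ---------------------------------------------------------------------------
# Annotation CSV: one row per second, one column per rater, 0/1.  A single
# non-numeric first row is tolerated as a header.
# ---------------------------------------------------------------------------

def read_annotation_csv(path: str | Path) -> np.ndarray:
    """Read per-rater masks from CSV, returning a (n_raters, n_seconds) array."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"annotation file not found: {path}")
    rows: list[list[str]] = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if row and any(cell.strip() for cell in row):
                rows.append([cell.strip() for cell in row])
    if not rows:
        raise DataError(f"annotation file is empty: {path}")

    def _numeric(row: list[str]) -> bool:
        try:
            [float(c) for c in row]
            return True
        except ValueError:
            return False

    if not _numeric(rows[0]):
        rows = rows[1:]
    if not rows:
        raise DataError(f"annotation file has a header but no data: {path}")
    try:
        arr = np.array([[float(c) for c in row] for row in rows])
    except ValueError as exc:
        raise DataError(f"non-numeric annotation values in {path}") from exc
    if not np.isin(arr, (0, 1)).all():
        raise DataError(f"annotation values must be 0/1 in {path}")
    return arr.astype(int).T  # file rows are seconds, columns raters


def write_annotation_csv(masks: np.ndarray, path: str | Path,
                         header: bool = True) -> None:
    """Write per-rater masks as seconds x raters CSV."""
    masks = np.asarray(masks, dtype=int)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        if header:
            writer.writerow([f"rater{r + 1}" for r in range(masks.shape[0])])
        writer.writerows(masks.T.tolist())
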