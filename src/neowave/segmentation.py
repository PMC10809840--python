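"""Map fused annotations to analysis segments.

Seconds marked seizure (at a given rater-agreement level k) form events;
each event at least 3 s long is split into three equal-length stages S1/S2/S3
(start / middle / end, boundaries at rounded thirds).  Epochs are labeled
nonseizure or S1/S2/S3 by majority overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import DataError
from .features import EpochGrid
from .io import AnnotationSet

__all__ = ["SegmentSpec", "mask_to_events", "split_stages",
           "build_segments", "label_epochs"]

log = logging.getLogger(__name__)

STAGE_LABELS = ("S1", "S2", "S3")


def mask_to_events(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of 1s as half-open [start, end) second intervals."""
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise DataError("mask must be binary")
    padded = np.r_[0, mask, 0]
    d = np.diff(padded)
    starts = np.where(d == 1)[0]
    ends = np.where(d == -1)[0]
    return list(zip(starts.tolist(), ends.tolist()))


def split_stages(event: tuple[int, int]) -> tuple[tuple[int, int], ...]:
    """Split an event into start/middle/end stages at rounded thirds.

    Events shorter than 3 s cannot be staged and raise :class:`DataError`
    (callers exclude and log them).
    """
    a, b = event
    n = b - a
    if n < 3:
        raise DataError(f"event of {n} s is too short to stage")
    b1, b2 = round(n / 3), round(2 * n / 3)
    return ((a, a + b1), (a + b1, a + b2), (a + b2, b))


@dataclass
class SegmentSpec:
    """Seizure/nonseizure intervals and per-event stages at one fusion level."""

    fusion_level: int
    n_seconds: int
    events: list[tuple[int, int]]
    stages: list[tuple[tuple[int, int], ...]] = field(default_factory=list)
    excluded_events: list[tuple[int, int]] = field(default_factory=list)

    @property
    def nonseizure(self) -> list[tuple[int, int]]:
        """Complement of the events within the recording."""
        out, cursor = [], 0
        for a, b in self.events:
            if a > cursor:
                out.append((cursor, a))
            cursor = b
        if cursor < self.n_seconds:
            out.append((cursor, self.n_seconds))
        return out

    def second_labels(self) -> np.ndarray:
        """Per-second label array: 'nonseizure', 'seizure', or S1/S2/S3."""
        labels = np.array(["nonseizure"] * self.n_seconds, dtype=object)
        for a, b in self.excluded_events:
            labels[a:b] = "seizure"  # too short to stage, still seizure
        for stages in self.stages:
            for name, (a, b) in zip(STAGE_LABELS, stages):
                labels[a:b] = name
        return labels


def build_segments(ann: AnnotationSet, fusion_level: int) -> SegmentSpec:
    """Construct the segment spec for one rater-agreement level."""
    if fusion_level not in ann.fused:
        raise DataError(f"fusion level {fusion_level} not available")
    mask = ann.fused[fusion_level]
    events = mask_to_events(mask)
    spec = SegmentSpec(fusion_level=fusion_level, n_seconds=len(mask),
                       events=events)
    for ev in events:
        try:
            spec.stages.append(split_stages(ev))
        except DataError:
            spec.excluded_events.append(ev)
            log.info("event %s shorter than 3 s excluded from stage analysis", ev)
    return spec


def label_epochs(grid: EpochGrid, spec: SegmentSpec) -> np.ndarray:
    """Label each epoch by the segment covering more than half of it."""
    sec_labels = spec.second_labels()
    n_ep = grid.n_epochs(spec.n_seconds)
    out = np.empty(n_ep, dtype=object)
    for i in range(n_ep):
        t0, t1 = i * grid.epoch_len, (i + 1) * grid.epoch_len
        # overlap of the epoch with each covered second
        counts: dict[str, float] = {}
        for s in range(int(np.floor(t0)), int(np.ceil(t1))):
            if s >= len(sec_labels):
                break
            ov = min(t1, s + 1) - max(t0, s)
            if ov > 0:
                counts[sec_labels[s]] = counts.get(sec_labels[s], 0.0) + ov
        out[i] = max(counts.items(), key=lambda kv: kv[1])[0]
    return out
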