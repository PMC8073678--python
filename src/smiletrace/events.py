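"""Smoothing, activation-run segmentation and smile classification.

A smile event is a maximal run of frames where the *smoothed* AU12 intensity
stays at or above an activation threshold (default 0.5 on the 0-5 scale) on
valid frames, lasting at least one second.  Each AU12 event is classified:

* **Social Smile (SO)** -- AU06 (cheek raiser) is co-active on at least half
  of the event's frames, the Duchenne-marker reading of "both active";
* **Simple Smile (SI)** -- AU12 only.

Smoothing is a width-4 boxcar (window ``{t-2, t-1, t, t+1}``, edges
renormalized over in-bounds frames); an even kernel has no center so the
alignment is a fixed convention, documented here for reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ParameterError
from .openface import AUFrameSeries

DEFAULT_SMOOTH_WIDTH = 4
DEFAULT_TAU = 0.5
DEFAULT_MIN_EVENT_S = 1.0
DEFAULT_SOCIAL_OVERLAP = 0.5

SOCIAL = "SO"
SIMPLE = "SI"


@dataclass(frozen=True)
class ActivationInterval:
    """Maximal supra-threshold run, frame indices inclusive on both ends."""

    start_idx: int
    end_idx: int
    au: str = "AU12"

    def __post_init__(self) -> None:
        if not 0 <= self.start_idx <= self.end_idx:
            raise ParameterError("interval indices out of order")

    @property
    def n_frames(self) -> int:
        return self.end_idx - self.start_idx + 1


@dataclass
class SmileEvent:
    """One detected AU12 activation episode with its summary features."""

    subject_id: str
    segment_id: int
    smile_type: str  # SOCIAL or SIMPLE
    start_idx: int
    end_idx: int
    onset_s: float
    offset_s: float
    duration_s: float
    mean_au12: float
    mean_au06: float
    au06_overlap_frac: float


def smooth_boxcar(signal: np.ndarray, width_frames: int = DEFAULT_SMOOTH_WIDTH) -> np.ndarray:
    """Windowed mean over ``{t - w//2, ..., t + w - w//2 - 1}``.

    Edge windows renormalize over in-bounds frames, so output length equals
    input length and constant signals are fixed points.
    """
    if width_frames < 1:
        raise ParameterError("width_frames must be >= 1")
    x = np.asarray(signal, dtype=float)
    n = x.size
    if n == 0:
        raise ParameterError("signal must have length >= 1")
    left = width_frames // 2
    right = width_frames - left - 1
    t = np.arange(n)
    lo = np.maximum(0, t - left)
    hi = np.minimum(n, t + right + 1)
    csum = np.concatenate(([0.0], np.cumsum(x)))
    return (csum[hi] - csum[lo]) / (hi - lo)


def detect_active_intervals(
    signal: np.ndarray,
    valid_mask: np.ndarray,
    tau: float = DEFAULT_TAU,
    au: str = "AU12",
) -> list[ActivationInterval]:
    """Maximal runs with ``signal >= tau`` on valid frames (boundary included)."""
    signal = np.asarray(signal, dtype=float)
    valid_mask = np.asarray(valid_mask, dtype=bool)
    if signal.size != valid_mask.size:
        raise ParameterError("signal and valid_mask lengths differ")
    active = (signal >= tau) & valid_mask
    edges = np.diff(np.r_[False, active, False].astype(np.int8))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1) - 1
    return [ActivationInterval(int(s), int(e), au) for s, e in zip(starts, ends)]


def filter_min_duration(
    intervals: list[ActivationInterval], fps: float, min_s: float = DEFAULT_MIN_EVENT_S
) -> list[ActivationInterval]:
    """Drop runs strictly shorter than ``min_s`` (duration = frames / fps)."""
    if min_s < 0:
        raise ParameterError("min_s must be non-negative")
    if not fps > 0:
        raise ParameterError("fps must be positive")
    return [iv for iv in intervals if iv.n_frames / fps >= min_s]


def event_features(
    start_idx: int,
    end_idx: int,
    au12_smooth: np.ndarray,
    au06_smooth: np.ndarray,
    fps: float,
) -> tuple[float, float, float]:
    """(mean AU12, mean AU06, duration) of the smoothed signals over an event."""
    if end_idx < start_idx:
        raise ParameterError("empty event frame range")
    sl = slice(start_idx, end_idx + 1)
    duration = (end_idx - start_idx + 1) / fps
    return (
        float(np.mean(au12_smooth[sl])),
        float(np.mean(au06_smooth[sl])),
        float(duration),
    )


def classify_smiles(
    au12_intervals: list[ActivationInterval],
    au06_intervals: list[ActivationInterval],
    fps: float,
    social_overlap_threshold: float = DEFAULT_SOCIAL_OVERLAP,
    *,
    au12_smooth: np.ndarray,
    au06_smooth: np.ndarray,
    timestamps: np.ndarray,
    subject_id: str = "",
    segment_id: int = 0,
) -> list[SmileEvent]:
    """One :class:`SmileEvent` per (duration-filtered) AU12 interval.

    ``au06_overlap_frac`` is the fraction of event frames covered by any
    AU06 interval; the event is Social iff that fraction reaches the
    threshold.  AU06 intervals never generate events on their own.
    """
    if not 0.0 < social_overlap_threshold <= 1.0:
        raise ParameterError("social_overlap_threshold must be in (0, 1]")
    n = len(timestamps)
    au06_active = np.zeros(n, dtype=bool)
    for iv in au06_intervals:
        au06_active[iv.start_idx:iv.end_idx + 1] = True

    events: list[SmileEvent] = []
    for iv in au12_intervals:
        covered = int(au06_active[iv.start_idx:iv.end_idx + 1].sum())
        frac = covered / iv.n_frames
        mean12, mean06, dur = event_features(
            iv.start_idx, iv.end_idx, au12_smooth, au06_smooth, fps
        )
        events.append(SmileEvent(
            subject_id=subject_id,
            segment_id=segment_id,
            smile_type=SOCIAL if frac >= social_overlap_threshold else SIMPLE,
            start_idx=iv.start_idx,
            end_idx=iv.end_idx,
            onset_s=float(timestamps[iv.start_idx]),
            offset_s=float(timestamps[iv.end_idx]),
            duration_s=dur,
            mean_au12=mean12,
            mean_au06=mean06,
            au06_overlap_frac=frac,
        ))
    return events


def detect_smile_events(
    segment: AUFrameSeries,
    *,
    smooth_width_frames: int = DEFAULT_SMOOTH_WIDTH,
    tau: float = DEFAULT_TAU,
    min_event_s: float = DEFAULT_MIN_EVENT_S,
    social_overlap_threshold: float = DEFAULT_SOCIAL_OVERLAP,
) -> list[SmileEvent]:
    """Full per-segment chain: smooth -> detect -> duration-filter -> classify."""
    s12 = smooth_boxcar(segment.au12, smooth_width_frames)
    s06 = smooth_boxcar(segment.au06, smooth_width_frames)
    iv12 = detect_active_intervals(s12, segment.valid_mask, tau, au="AU12")
    iv12 = filter_min_duration(iv12, segment.fps, min_event_s)
    iv06 = detect_active_intervals(s06, segment.valid_mask, tau, au="AU06")
    return classify_smiles(
        iv12, iv06, segment.fps, social_overlap_threshold,
        au12_smooth=s12, au06_smooth=s06, timestamps=segment.timestamps,
        subject_id=segment.subject_id, segment_id=segment.segment_id,
    )


def events_to_records(events: list[SmileEvent]) -> list[dict]:
    """Plain-dict rows for the events CSV."""
    return [
        {
            "subject_id": e.subject_id,
            "segment_id": e.segment_id,
            "smile_type": e.smile_type,
            "onset_s": e.onset_s,
            "offset_s": e.offset_s,
            "duration_s": e.duration_s,
            "mean_au12": e.mean_au12,
            "mean_au06": e.mean_au06,
            "au06_overlap_frac": e.au06_overlap_frac,
        }
        for e in events
    ]
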