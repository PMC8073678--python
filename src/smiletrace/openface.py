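"""Reading OpenFace AU output, confidence gating and dropout segmentation.

The pipeline consumes the CSV dialect written by OpenFace's feature
extraction tools: one row per video frame with a ``frame`` index, a
``timestamp`` in seconds, a per-frame tracking ``confidence`` in [0, 1] and
action-unit intensity columns ``AUxx_r`` on a 0-5 scale.  Only AU12
(lip-corner puller) and AU06 (cheek raiser) are used; all other columns are
tolerated and ignored.

Frames whose confidence does not exceed the gate (default C > 0.75, strict)
are *masked*, never deleted, so the time accounting and gap lengths stay
exact.  Long masked runs split a recording into segments; short runs are
bridged by linear interpolation of the AU signals (see
:func:`split_at_dropouts`).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import EmptyInputError, FormatError, ParameterError

logger = logging.getLogger(__name__)

#: Columns a readable OpenFace CSV must contain (case/whitespace tolerant).
REQUIRED_COLUMNS = ("frame", "timestamp", "confidence", "AU06_r", "AU12_r")

#: OpenFace AU intensities live on this scale.
INTENSITY_RANGE = (0.0, 5.0)

DEFAULT_CONFIDENCE_THRESHOLD = 0.75
DEFAULT_MAX_GAP_S = 0.5


@dataclass
class AUFrameSeries:
    """Per-frame AU06/AU12 intensities and tracking confidence for one segment.

    Arrays are aligned per frame.  ``valid_mask`` is True for frames whose
    confidence strictly exceeds ``gate_threshold`` (all-True until a gate is
    applied).
    """

    subject_id: str
    segment_id: int
    timestamps: np.ndarray
    fps: float
    confidence: np.ndarray
    au12: np.ndarray
    au06: np.ndarray
    valid_mask: np.ndarray = None  # type: ignore[assignment]
    gate_threshold: float | None = None

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.confidence = np.asarray(self.confidence, dtype=float)
        self.au12 = np.asarray(self.au12, dtype=float)
        self.au06 = np.asarray(self.au06, dtype=float)
        n = self.timestamps.size
        if n < 1:
            raise ParameterError("AUFrameSeries requires at least one frame")
        if self.valid_mask is None:
            self.valid_mask = np.ones(n, dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        for name in ("confidence", "au12", "au06", "valid_mask"):
            if getattr(self, name).size != n:
                raise ParameterError(f"array length mismatch for '{name}'")
        if not self.fps > 0:
            raise ParameterError("fps must be positive")
        if n > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise FormatError("timestamps must be strictly increasing")
        lo, hi = INTENSITY_RANGE
        for name in ("au12", "au06"):
            arr = getattr(self, name)
            if arr.min(initial=lo) < lo or arr.max(initial=hi) > hi:
                raise ParameterError(f"{name} intensities outside [{lo}, {hi}]")
        if self.confidence.min(initial=0.0) < 0.0 or self.confidence.max(initial=1.0) > 1.0:
            raise ParameterError("confidence outside [0, 1]")

    @property
    def n_frames(self) -> int:
        return self.timestamps.size

    @property
    def duration_s(self) -> float:
        """Recording span in seconds, counting each frame as 1/fps."""
        return self.n_frames / self.fps


@dataclass
class RecordingSet:
    """One subject's recording split into gate-clean segments.

    ``usable_seconds`` sums segment durations (bridged short gaps included);
    confidence statistics are computed over *all* original frames.
    """

    subject_id: str
    segments: list[AUFrameSeries]
    usable_seconds: float
    confidence_mean: float
    confidence_pct: float
    gate_threshold: float | None = None

    @property
    def n_segments(self) -> int:
        return len(self.segments)


def _normalize_header(columns) -> dict[str, str]:
    return {str(c).strip().lower(): c for c in columns}


def read_openface_csv(path: str | Path, subject_id: str) -> AUFrameSeries:
    """Read one OpenFace-dialect CSV into an :class:`AUFrameSeries`.

    Rows with non-finite values in a required column are dropped (count
    logged); AU intensities are clipped into [0, 5] (count logged).  The
    frame rate is inferred as ``1 / median(Δtimestamp)`` so isolated dropped
    video frames do not distort it.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    lookup = _normalize_header(df.columns)
    missing = [c for c in REQUIRED_COLUMNS if c.lower() not in lookup]
    if missing:
        raise FormatError(
            f"{path.name}: missing required column(s) {', '.join(repr(c) for c in missing)}"
        )
    cols = {c: pd.to_numeric(df[lookup[c.lower()]], errors="coerce").to_numpy(dtype=float)
            for c in REQUIRED_COLUMNS}
    finite = np.ones(len(df), dtype=bool)
    for arr in cols.values():
        finite &= np.isfinite(arr)
    n_dropped = int((~finite).sum())
    if n_dropped:
        logger.info("%s: dropped %d rows with non-finite required values", path.name, n_dropped)
    if not finite.any():
        raise EmptyInputError(f"{path.name}: no usable rows after cleaning")

    ts = cols["timestamp"][finite]
    conf = np.clip(cols["confidence"][finite], 0.0, 1.0)
    lo, hi = INTENSITY_RANGE
    au12_raw = cols["AU12_r"][finite]
    au06_raw = cols["AU06_r"][finite]
    n_clipped = int(((au12_raw < lo) | (au12_raw > hi)).sum()
                    + ((au06_raw < lo) | (au06_raw > hi)).sum())
    if n_clipped:
        logger.info("%s: clipped %d AU intensity values into [0, 5]", path.name, n_clipped)
    au12 = np.clip(au12_raw, lo, hi)
    au06 = np.clip(au06_raw, lo, hi)

    if ts.size > 1 and not np.all(np.diff(ts) > 0):
        raise FormatError(f"{path.name}: timestamps not strictly increasing after cleaning")
    if ts.size < 2:
        raise FormatError(f"{path.name}: need at least 2 frames to infer fps")
    fps = 1.0 / float(np.median(np.diff(ts)))
    return AUFrameSeries(
        subject_id=subject_id, segment_id=0, timestamps=ts, fps=fps,
        confidence=conf, au12=au12, au06=au06,
    )


def write_openface_csv(series: AUFrameSeries, path: str | Path) -> None:
    """Write a series back out in the OpenFace input dialect (round-trippable)."""
    df = pd.DataFrame({
        "frame": np.arange(series.n_frames),
        "timestamp": series.timestamps,
        "confidence": series.confidence,
        "success": np.ones(series.n_frames, dtype=int),
        "AU06_r": series.au06,
        "AU12_r": series.au12,
    })
    df.to_csv(path, index=False, float_format="%.17g")  # round-trip exact


def write_segment_csv(series: AUFrameSeries, path: str | Path) -> None:
    """Normalized per-segment CSV for inspection."""
    pd.DataFrame({
        "subject_id": series.subject_id,
        "segment_id": series.segment_id,
        "timestamp": series.timestamps,
        "confidence": series.confidence,
        "au12": series.au12,
        "au06": series.au06,
        "valid": series.valid_mask.astype(int),
    }).to_csv(path, index=False)


def apply_confidence_gate(
    series: AUFrameSeries, threshold: float = DEFAULT_CONFIDENCE_THRESHOLD
) -> AUFrameSeries:
    """Mask frames whose confidence is not *strictly* above ``threshold``.

    Frames are retained (masked, not deleted) so gap lengths stay computable.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ParameterError(f"confidence threshold {threshold!r} outside [0, 1]")
    return replace(series, valid_mask=series.confidence > threshold, gate_threshold=threshold)


def _runs(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Start (inclusive) and end (exclusive) indices of maximal True runs."""
    padded = np.diff(np.r_[False, mask, False].astype(np.int8))
    return np.flatnonzero(padded == 1), np.flatnonzero(padded == -1)


def split_at_dropouts(
    series: AUFrameSeries, max_gap_s: float = DEFAULT_MAX_GAP_S
) -> RecordingSet:
    """Split a gated recording at long low-confidence runs.

    Invalid runs longer than ``max_gap_s`` (frame count / fps, strict) break
    the recording into segments and are excluded from usable time.  Shorter
    interior runs are bridged: their AU values are linearly interpolated from
    the flanking valid frames and the frames count as valid downstream.
    Leading/trailing invalid frames of a segment cannot be interpolated and
    are trimmed.  Confidence statistics are computed over all original
    frames.
    """
    if max_gap_s < 0:
        raise ParameterError("max_gap_s must be non-negative")
    valid = series.valid_mask
    n = series.n_frames
    conf_mean = float(series.confidence.mean())
    conf_pct = 100.0 * float(valid.mean())

    starts, ends = _runs(~valid)
    breakers = [(s, e) for s, e in zip(starts, ends) if (e - s) / series.fps > max_gap_s]

    segments: list[AUFrameSeries] = []
    cursor = 0
    chunks = []
    for s, e in breakers:
        if s > cursor:
            chunks.append((cursor, s))
        cursor = e
    if cursor < n:
        chunks.append((cursor, n))

    for lo, hi in chunks:
        v = valid[lo:hi]
        idx = np.flatnonzero(v)
        if idx.size == 0:
            continue
        a, b = lo + idx[0], lo + idx[-1] + 1  # trim untrimmable edges
        ts = series.timestamps[a:b]
        v = valid[a:b]
        au12 = series.au12[a:b].copy()
        au06 = series.au06[a:b].copy()
        if not v.all():  # bridge short interior gaps
            au12[~v] = np.interp(ts[~v], ts[v], au12[v])
            au06[~v] = np.interp(ts[~v], ts[v], au06[v])
        segments.append(AUFrameSeries(
            subject_id=series.subject_id,
            segment_id=len(segments),
            timestamps=ts,
            fps=series.fps,
            confidence=series.confidence[a:b],
            au12=au12,
            au06=au06,
            valid_mask=np.ones(b - a, dtype=bool),
            gate_threshold=series.gate_threshold,
        ))

    usable = sum(seg.n_frames for seg in segments) / series.fps
    return RecordingSet(
        subject_id=series.subject_id,
        segments=segments,
        usable_seconds=float(usable),
        confidence_mean=conf_mean,
        confidence_pct=conf_pct,
        gate_threshold=series.gate_threshold,
    )
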