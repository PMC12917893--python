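"""R-peak annotation ingest, noise handling, RR computation and windowing.

Single-lead wearable ECG devices for ambulatory atrial-fibrillation
monitoring emit R-peak timestamps plus intervals they label as noise
(motion artifact, lead-off). This module turns those annotation streams
into quality-gated, fixed-grid 30-minute RR-interval windows.

Conventions
-----------
* Timestamps are integer milliseconds from recording start.
* Noise intervals and analysis windows are half-open ``[start, end)``:
  a peak exactly at an interval's end is *kept*, one at its start removed.
* Window membership is decided by the interval's onset (its first peak),
  so windows partition the interval set exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InputFormatError, InsufficientDataError

__all__ = [
    "RPeakAnnotation",
    "RRSeries",
    "QualityReport",
    "Window",
    "remove_noise_peaks",
    "compute_rr",
    "filter_implausible_rr",
    "quality_gate",
    "segment_windows",
    "merge_intervals",
    "DEFAULT_RR_BOUNDS_MS",
]

#: Physiological plausibility bounds for the ventricular response in AF.
DEFAULT_RR_BOUNDS_MS = (300.0, 2000.0)

MS_PER_HOUR = 3_600_000.0


def merge_intervals(intervals: np.ndarray) -> np.ndarray:
    """Merge overlapping/touching half-open intervals; returns (k, 2) int64."""
    iv = np.asarray(intervals, dtype=np.int64).reshape(-1, 2)
    if iv.shape[0] == 0:
        return iv
    iv = iv[np.argsort(iv[:, 0], kind="stable")]
    merged = [iv[0].copy()]
    for start, end in iv[1:]:
        if start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append(np.array([start, end], dtype=np.int64))
    return np.array(merged, dtype=np.int64)


@dataclass(frozen=True)
class RPeakAnnotation:
    """Per-recording R-peak timestamps plus noise-labelled intervals."""

    recording_id: str
    peak_times_ms: np.ndarray
    noise_intervals: np.ndarray
    recording_span_ms: int

    def __post_init__(self) -> None:
        peaks = np.asarray(self.peak_times_ms, dtype=np.int64)
        if peaks.ndim != 1:
            raise InputFormatError("peak_times_ms must be one-dimensional")
        if peaks.size > 1 and not np.all(np.diff(peaks) > 0):
            raise InputFormatError(
                f"{self.recording_id}: R-peak timestamps must be strictly increasing"
            )
        noise = merge_intervals(self.noise_intervals)
        if noise.size:
            if np.any(noise[:, 1] <= noise[:, 0]):
                raise InputFormatError("noise intervals must have end > start")
            noise = np.clip(noise, 0, int(self.recording_span_ms))
            noise = noise[noise[:, 1] > noise[:, 0]]
        object.__setattr__(self, "peak_times_ms", peaks)
        object.__setattr__(self, "noise_intervals", noise)
        object.__setattr__(self, "recording_span_ms", int(self.recording_span_ms))


@dataclass(frozen=True)
class RRSeries:
    """RR intervals with the timestamp of each interval's first peak."""

    onsets_ms: np.ndarray
    rr_ms: np.ndarray

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets_ms, dtype=np.float64)
        rr = np.asarray(self.rr_ms, dtype=np.float64)
        if onsets.shape != rr.shape or onsets.ndim != 1:
            raise InputFormatError("onsets_ms and rr_ms must be equal-length 1-d arrays")
        if rr.size and np.any(rr <= 0):
            raise InputFormatError("RR intervals must be positive")
        object.__setattr__(self, "onsets_ms", onsets)
        object.__setattr__(self, "rr_ms", rr)

    def __len__(self) -> int:
        return int(self.rr_ms.size)

    @property
    def is_empty(self) -> bool:
        return self.rr_ms.size == 0


@dataclass(frozen=True)
class QualityReport:
    """Outcome of the recording-level usability gate."""

    recording_id: str
    noise_fraction: float
    analyzable_hours: float
    usable: bool
    reasons: tuple[str, ...] = field(default_factory=tuple)


@dataclass(frozen=True)
class Window:
    """One fixed-grid analysis window of a recording."""

    index: int
    start_ms: int
    end_ms: int
    partial: bool
    rr: RRSeries


def remove_noise_peaks(ann: RPeakAnnotation) -> RPeakAnnotation:
    """Drop every R-peak lying inside a noise-marked ``[start, end)`` interval.

    Noise intervals are retained on the returned annotation for downstream
    quality accounting. Idempotent.
    """
    peaks = ann.peak_times_ms
    noise = ann.noise_intervals
    if noise.shape[0] == 0 or peaks.size == 0:
        return ann
    idx = np.searchsorted(noise[:, 0], peaks, side="right") - 1
    inside = (idx >= 0) & (peaks < noise[np.clip(idx, 0, None), 1])
    return replace(ann, peak_times_ms=peaks[~inside])


def compute_rr(ann: RPeakAnnotation) -> RRSeries:
    """Successive R-peak differences; onset = first peak of each pair.

    Fewer than two peaks yields an empty series (sentinel logic downstream
    handles degenerate windows — this is not an error).
    """
    peaks = ann.peak_times_ms
    if peaks.size < 2:
        return RRSeries(np.empty(0), np.empty(0))
    return RRSeries(onsets_ms=peaks[:-1].astype(np.float64), rr_ms=np.diff(peaks).astype(np.float64))


def filter_implausible_rr(
    rr: RRSeries,
    lo_ms: float = DEFAULT_RR_BOUNDS_MS[0],
    hi_ms: float = DEFAULT_RR_BOUNDS_MS[1],
) -> RRSeries:
    """Drop intervals outside ``[lo_ms, hi_ms]``; gaps are not re-bridged."""
    if lo_ms >= hi_ms:
        raise InputFormatError("lo_ms must be < hi_ms")
    keep = (rr.rr_ms >= lo_ms) & (rr.rr_ms <= hi_ms)
    return RRSeries(rr.onsets_ms[keep], rr.rr_ms[keep])


def quality_gate(
    ann: RPeakAnnotation,
    max_noise_fraction: float = 0.20,
    min_analyzable_hours: float = 48.0,
) -> QualityReport:
    """Recording-level usability: noise coverage and analyzable duration.

    The defaults are the study's enrolment gates: recordings with more than
    20% noise-labelled signal or under 48 h of analyzable (non-noise) ECG
    are unusable. ``analyzable = span - merged noise length``.
    """
    span = float(ann.recording_span_ms)
    if span <= 0:
        raise InsufficientDataError("recording span must be positive")
    noise = ann.noise_intervals
    noise_ms = float(np.sum(noise[:, 1] - noise[:, 0])) if noise.size else 0.0
    noise_fraction = noise_ms / span
    analyzable_hours = (span - noise_ms) / MS_PER_HOUR
    reasons: list[str] = []
    if noise_fraction > max_noise_fraction:
        reasons.append("noise_fraction")
    if analyzable_hours < min_analyzable_hours:
        reasons.append("analyzable_hours")
    return QualityReport(
        recording_id=ann.recording_id,
        noise_fraction=noise_fraction,
        analyzable_hours=analyzable_hours,
        usable=not reasons,
        reasons=tuple(reasons),
    )


def segment_windows(
    rr: RRSeries,
    window_min: float = 30.0,
    span_ms: int | None = None,
) -> list[Window]:
    """Cut an RR series into contiguous fixed-grid windows.

    Windows are ``[k*W, (k+1)*W)`` anchored at recording start; an interval
    belongs to the window containing its onset. The trailing partial window
    is retained and flagged. Windows with <2 intervals are still returned
    (possibly empty) so the -1 sentinel logic can apply.

    ``span_ms`` defaults to the end of the last interval; it must be given
    for an empty series.
    """
    if window_min <= 0:
        raise InputFormatError("window_min must be positive")
    w_ms = window_min * 60_000.0
    if span_ms is None:
        if rr.is_empty:
            raise InsufficientDataError("span_ms required for an empty RR series")
        span_ms = int(rr.onsets_ms[-1] + rr.rr_ms[-1])
    n_windows = max(1, math.ceil(span_ms / w_ms))
    assignment = np.floor_divide(rr.onsets_ms, w_ms).astype(np.int64) if len(rr) else np.empty(0, np.int64)
    windows: list[Window] = []
    for k in range(n_windows):
        sel = assignment == k
        start = int(k * w_ms)
        end = int((k + 1) * w_ms)
        windows.append(
            Window(
                index=k,
                start_ms=start,
                end_ms=end,
                partial=end > span_ms,
                rr=RRSeries(rr.onsets_ms[sel], rr.rr_ms[sel]),
            )
        )
    return windows
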