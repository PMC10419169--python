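"""Spike-wave discharge detection by the amplitude/duration criterion.

A discharge is a repetitive train of large-amplitude spikes and waves lasting
at least one second with amplitude at least two-fold the baseline EEG.  The
implementation operationalizes this as follows:

1. *Envelope*: the rectified trace smoothed over 50 ms — long enough to
   bridge the zero crossings inside a 7-8 Hz cycle, short enough to keep
   event edges sharp.
2. *Baseline*: the median over 1 s windows of the window-wise envelope peak.
   The median makes the estimate robust: discharges occupying a minority of
   the recording barely move it.
3. *Thresholding*: maximal intervals where the envelope exceeds
   ``threshold_factor`` (default 2) times the baseline, after closing gaps up
   to ``merge_gap`` (default 0.5 s, so one train is not split at its wave
   troughs) and discarding intervals shorter than ``min_duration`` (1 s).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

from .types import (
    EEGRecording,
    ParameterError,
    SessionSummary,
    SWDAnnotation,
    SWDEvent,
)

__all__ = [
    "DetectionConfig",
    "BaselineEstimate",
    "envelope",
    "estimate_baseline_amplitude",
    "merge_intervals",
    "detect_swds",
    "summarize",
    "DetectionScore",
    "score_against_truth",
]


@dataclass(frozen=True)
class DetectionConfig:
    """Detector parameters (defaults follow the 2x / >=1 s criterion)."""

    threshold_factor: float = 2.0
    min_duration: float = 1.0
    merge_gap: float = 0.5
    baseline_window: float = 1.0
    smoothing: float = 0.05
    channel: str | None = None

    def __post_init__(self) -> None:
        if not self.threshold_factor > 1.0:
            raise ParameterError("threshold_factor must exceed 1")
        if not self.min_duration > 0:
            raise ParameterError("min_duration must be positive")
        if self.merge_gap < 0:
            raise ParameterError("merge_gap must be non-negative")
        if not self.baseline_window > 0 or not self.smoothing > 0:
            raise ParameterError("baseline_window and smoothing must be positive")


@dataclass(frozen=True)
class BaselineEstimate:
    """Robust amplitude scale of the non-event EEG (µV)."""

    value: float
    degenerate: bool = False


def envelope(x: np.ndarray, sampling_rate: float, smoothing: float = 0.05) -> np.ndarray:
    """Rectified signal smoothed with a moving average of ``smoothing`` seconds."""
    size = max(int(round(smoothing * sampling_rate)), 1)
    return uniform_filter1d(np.abs(np.asarray(x, dtype=float)), size=size, mode="nearest")


def estimate_baseline_amplitude(
    recording: EEGRecording, config: DetectionConfig | None = None
) -> BaselineEstimate:
    """Median over sliding windows of the window-wise envelope peak.

    Insensitive to discharges occupying a minority of the recording (they
    inflate only the upper tail of the window-peak distribution).  An
    all-constant trace yields a zero baseline flagged as degenerate.
    """
    config = config or DetectionConfig()
    fs = recording.sampling_rate
    x = recording.channel(config.channel)
    win = int(round(config.baseline_window * fs))
    if x.size <= win:
        raise ParameterError("recording shorter than baseline_window")
    env = envelope(x - np.median(x), fs, config.smoothing)
    n_win = x.size // win
    peaks = env[: n_win * win].reshape(n_win, win).max(axis=1)
    value = float(np.median(peaks))
    return BaselineEstimate(value=value, degenerate=value == 0.0)


def merge_intervals(
    intervals: list[tuple[int, int]], gap_samples: int
) -> list[tuple[int, int]]:
    """Close gaps of at most ``gap_samples`` between consecutive intervals.

    Idempotent: merging an already-merged list is a no-op.
    """
    if not intervals:
        return []
    merged = [intervals[0]]
    for start, stop in intervals[1:]:
        last_start, last_stop = merged[-1]
        if start - last_stop <= gap_samples:
            merged[-1] = (last_start, max(last_stop, stop))
        else:
            merged.append((start, stop))
    return merged


def _threshold_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open sample intervals."""
    if mask.size == 0:
        return []
    edges = np.flatnonzero(np.diff(mask.astype(np.int8)))
    starts = list(edges[mask[edges + 1]] + 1)
    stops = list(edges[~mask[edges + 1]] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(mask.size)
    return list(zip(starts, stops))


def detect_swds(
    recording: EEGRecording, config: DetectionConfig | None = None
) -> list[SWDEvent]:
    """Detect discharges: envelope above threshold, gaps closed, short runs dropped.

    Returns events sorted and non-overlapping, in seconds with the half-open
    ``[onset, offset)`` convention.  A degenerate (flat) recording yields an
    empty list.
    """
    config = config or DetectionConfig()
    if recording.n_samples == 0:
        raise ParameterError("empty recording")
    fs = recording.sampling_rate
    baseline = estimate_baseline_amplitude(recording, config)
    if baseline.degenerate:
        return []
    x = recording.channel(config.channel)
    env = envelope(x - np.median(x), fs, config.smoothing)
    mask = env > config.threshold_factor * baseline.value
    runs = _threshold_runs(mask)
    runs = merge_intervals(runs, int(round(config.merge_gap * fs)))
    min_len = int(round(config.min_duration * fs))
    label = config.channel or recording.channel_labels[0]
    return [
        SWDEvent(start / fs, stop / fs, label)
        for start, stop in runs
        if stop - start >= min_len
    ]


def summarize(events: list[SWDEvent]) -> SessionSummary:
    """Seizure burden: event count, total duration, and their ratio (mean)."""
    n = len(events)
    total = float(sum(e.duration for e in events))
    mean = total / n if n else None
    return SessionSummary(n_events=n, total_duration=total, mean_duration=mean)


@dataclass(frozen=True)
class DetectionScore:
    """Agreement between detected events and ground truth."""

    n_detected: int
    n_true: int
    n_matched: int
    precision: float
    recall: float
    onset_errors: tuple[float, ...]
    offset_errors: tuple[float, ...]

    @property
    def mean_onset_error(self) -> float | None:
        return float(np.mean(self.onset_errors)) if self.onset_errors else None

    @property
    def mean_offset_error(self) -> float | None:
        return float(np.mean(self.offset_errors)) if self.offset_errors else None


def score_against_truth(
    events: list[SWDEvent],
    truth: list[SWDAnnotation],
    tol: float = 0.0,
) -> DetectionScore:
    """Greedy one-to-one interval matching by overlap.

    A detected/true pair is matchable when their intervals (each dilated by
    ``tol`` seconds) overlap; pairs are matched greedily by decreasing
    overlap.  Precision = matched/detected, recall = matched/true; onset and
    offset errors are absolute differences over matched pairs.
    """
    if tol < 0:
        raise ParameterError("tol must be non-negative")
    pairs = []
    for i, ev in enumerate(events):
        for j, tr in enumerate(truth):
            ov = min(ev.offset + tol, tr.offset + tol) - max(ev.onset - tol, tr.onset - tol)
            if ov > 0:
                pairs.append((ov, i, j))
    pairs.sort(key=lambda p: (-p[0], p[1], p[2]))
    used_det: set[int] = set()
    used_true: set[int] = set()
    onset_err, offset_err = [], []
    for _, i, j in pairs:
        if i in used_det or j in used_true:
            continue
        used_det.add(i)
        used_true.add(j)
        onset_err.append(abs(events[i].onset - truth[j].onset))
        offset_err.append(abs(events[i].offset - truth[j].offset))
    n_matched = len(used_det)
    precision = n_matched / len(events) if events else 1.0
    recall = n_matched / len(truth) if truth else 1.0
    return DetectionScore(
        n_detected=len(events),
        n_true=len(truth),
        n_matched=n_matched,
        precision=precision,
        recall=recall,
        onset_errors=tuple(onset_err),
        offset_errors=tuple(offset_err),
    )
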