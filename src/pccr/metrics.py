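"""Offline evaluation: precision, accuracy, epoching and saccade metrics.

Precision is reported two ways: the RMS of inter-sample angular distances
(sample-to-sample noise) and the plain standard deviation of the samples
(dispersion).  For white noise the two are tied by RMS ~ sqrt(2) * SD.
Traces are split into non-overlapping one-second epochs; per-epoch values
are averaged.  A plain velocity-threshold event detector (central
differences, no smoothing filters) provides saccade/microsaccade intervals
for the event metrics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "EventMetrics",
    "AccuracyResult",
    "precision_rms",
    "precision_sd",
    "precision_epoched",
    "accuracy",
    "epoch_split",
    "radial_velocity",
    "detect_events_velocity",
    "event_metrics",
]


def _valid_pair_diffs(x: np.ndarray) -> np.ndarray:
    """Differences between consecutive samples where both are valid; pairs
    straddling an invalid (NaN) sample are excluded."""
    d = np.diff(x)
    return d[np.isfinite(d)]


def precision_rms(samples) -> float:
    """RMS of inter-sample distances along one axis (degrees).

    ``sqrt(mean(theta_i^2))`` with ``theta_i`` the differences between
    consecutive valid samples.  Returns NaN when fewer than two valid
    consecutive samples exist.
    """
    x = np.asarray(samples, dtype=float)
    d = _valid_pair_diffs(x)
    if d.size == 0:
        return float("nan")
    return float(np.sqrt(np.mean(d ** 2)))


def precision_sd(samples) -> float:
    """Sample standard deviation of the valid samples along one axis."""
    x = np.asarray(samples, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        return float("nan")
    return float(np.std(x, ddof=1))


def epoch_split(trace, frame_rate: float, epoch_s: float = 1.0) -> list[np.ndarray]:
    """Split a trace into consecutive non-overlapping epochs of
    ``round(epoch_s * frame_rate)`` samples; the trailing partial epoch is
    dropped."""
    arr = np.asarray(trace)
    n_per = int(round(epoch_s * frame_rate))
    n_epochs = len(arr) // n_per
    return [arr[i * n_per:(i + 1) * n_per] for i in range(n_epochs)]


def precision_epoched(samples, frame_rate: float, epoch_s: float = 1.0,
                      kind: str = "rms") -> float:
    """Mean per-epoch precision (RMS or SD) over one-second epochs."""
    fn = {"rms": precision_rms, "sd": precision_sd}[kind]
    vals = [fn(e) for e in epoch_split(samples, frame_rate, epoch_s)]
    vals = [v for v in vals if np.isfinite(v)]
    return float(np.mean(vals)) if vals else float("nan")


@dataclass
class AccuracyResult:
    mean_offset_deg: float            # mean Euclidean offset from target
    mean_dx_deg: float
    mean_dy_deg: float
    n: int


def accuracy(samples, target_position) -> AccuracyResult:
    """Mean difference between the measured gaze samples and the true
    stimulus position; the caller supplies a fixation interval free of
    saccades and blinks."""
    xy = np.atleast_2d(np.asarray(samples, dtype=float))
    tgt = np.asarray(target_position, dtype=float)
    keep = np.all(np.isfinite(xy), axis=1)
    xy = xy[keep]
    if xy.shape[0] == 0:
        return AccuracyResult(float("nan"), float("nan"), float("nan"), 0)
    d = xy - tgt
    return AccuracyResult(
        mean_offset_deg=float(np.mean(np.linalg.norm(d, axis=1))),
        mean_dx_deg=float(np.mean(d[:, 0])),
        mean_dy_deg=float(np.mean(d[:, 1])),
        n=int(xy.shape[0]),
    )


def radial_velocity(trace, frame_rate: float) -> np.ndarray:
    """Radial gaze velocity (deg/s) by central differences, unsmoothed.

    End samples use one-sided differences.  ``trace`` is (n, 2) or (n,).
    """
    xy = np.asarray(trace, dtype=float)
    if xy.ndim == 1:
        xy = xy[:, None]
    v = np.empty_like(xy)
    v[1:-1] = (xy[2:] - xy[:-2]) * (frame_rate / 2.0)
    v[0] = (xy[1] - xy[0]) * frame_rate
    v[-1] = (xy[-1] - xy[-2]) * frame_rate
    return np.linalg.norm(v, axis=1)


def detect_events_velocity(trace, frame_rate: float,
                           velocity_threshold: float = 30.0,
                           min_duration_s: float = 0.006,
                           merge_gap: int = 2) -> list[tuple[int, int]]:
    """Velocity-threshold saccade detector (plumbing, not a contribution).

    Returns [onset, offset] index pairs (inclusive) where the unsmoothed
    radial velocity exceeds ``velocity_threshold`` for at least
    ``min_duration_s``; intervals separated by fewer than ``merge_gap``
    samples are merged first.  Blinks must be excluded upstream.
    """
    speed = radial_velocity(trace, frame_rate)
    above = speed > velocity_threshold
    above &= np.isfinite(speed)
    if not above.any():
        return []
    # run-length extraction
    edges = np.diff(above.astype(int))
    onsets = list(np.where(edges == 1)[0] + 1)
    offsets = list(np.where(edges == -1)[0])
    if above[0]:
        onsets.insert(0, 0)
    if above[-1]:
        offsets.append(len(above) - 1)
    intervals = list(zip(onsets, offsets))
    merged: list[list[int]] = []
    for on, off in intervals:
        if merged and on - merged[-1][1] < merge_gap:
            merged[-1][1] = off
        else:
            merged.append([on, off])
    n_min = max(1, int(round(min_duration_s * frame_rate)))
    return [(on, off) for on, off in merged if off - on + 1 >= n_min]


@dataclass
class EventMetrics:
    """Metrics of one saccadic event."""

    onset: int
    offset: int
    latency_ms: Optional[float]       # onset re stimulus appearance
    duration_ms: float
    amplitude_deg: float              # Euclidean start-to-end distance
    peak_velocity_deg_s: float        # max radial velocity inside the event
    at_boundary: bool = False

    def __post_init__(self) -> None:
        if self.offset <= self.onset:
            raise ValueError("offset must exceed onset")


def event_metrics(trace, interval: tuple[int, int], frame_rate: float,
                  stimulus_onset: int | None = None) -> EventMetrics:
    """Compute latency, duration, amplitude and peak velocity for one
    detected event interval (inclusive indices)."""
    xy = np.atleast_2d(np.asarray(trace, dtype=float))
    if xy.shape[0] == 1:
        xy = xy.T
    on, off = int(interval[0]), int(interval[1])
    if not (0 <= on < off < xy.shape[0]):
        raise ValueError(f"interval {interval} outside trace of {xy.shape[0]} samples")
    speed = radial_velocity(xy, frame_rate)
    latency = None
    if stimulus_onset is not None:
        latency = (on - stimulus_onset) / frame_rate * 1000.0
    return EventMetrics(
        onset=on,
        offset=off,
        latency_ms=latency,
        duration_ms=(off - on) / frame_rate * 1000.0,
        amplitude_deg=float(np.linalg.norm(xy[off] - xy[on])),
        peak_velocity_deg_s=float(np.max(speed[on:off + 1])),
        at_boundary=(on == 0 or off == xy.shape[0] - 1),
    )
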