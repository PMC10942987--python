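"""The oscillation index: baseline smooth, event detection, index triplet.

The statistic quantifies spontaneous vasomotion (or smooth-muscle calcium
oscillation) from a scalar trace in three numbers:

frequency
    supra-threshold events per second of recording,
amplitude
    mean event amplitude relative to the running baseline
    (``(peak - baseline) / baseline``), reported in percent,
peak-interval SD
    sample standard deviation of the intervals between consecutive event
    peaks, a measure of rhythm regularity.

The running baseline ("baseline smooth", F0/D0/R0) is the sixth smallest
value in a trailing 20-sample window, and an event is a maximal run of
samples strictly exceeding the baseline plus twice the residual SD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import OutOfBoundsError, TraceTooShortError
from .images import FrameStack
from .traces import TraceSeries

__all__ = [
    "VasomotionEvent",
    "EventSet",
    "OscillationIndex",
    "sliding_baseline",
    "detect_events",
    "compute_index",
    "mean_roi_trace",
]


@dataclass(frozen=True)
class VasomotionEvent:
    """One supra-threshold event."""

    peak_time_s: float
    peak_value: float
    baseline_at_peak: float
    amplitude_frac: float


@dataclass
class EventSet:
    """Detected events plus the threshold series that defined them."""

    events: list
    threshold: np.ndarray
    sigma: float
    flat_residual: bool = False

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def peak_times_s(self) -> np.ndarray:
        return np.array([e.peak_time_s for e in self.events], dtype=float)

    @property
    def amplitudes_frac(self) -> np.ndarray:
        return np.array([e.amplitude_frac for e in self.events], dtype=float)


@dataclass
class OscillationIndex:
    """The frequency / amplitude / peak-interval-SD triplet.

    ``peak_interval_sd_s`` is ``None`` (undefined, not zero) when fewer
    than three events were detected.
    """

    frequency_hz: float
    amplitude_pct: float
    peak_interval_sd_s: float | None
    n_events: int
    duration_s: float


def sliding_baseline(trace: TraceSeries, window: int = 20, order: int = 6) -> np.ndarray:
    """Order-statistic running baseline.

    ``baseline[t]`` is the ``order``-th smallest value in the window of
    ``window`` samples ending at ``t`` (trailing/causal alignment).  For
    the start-up samples ``t < window - 1`` the statistic of the first
    full window is reused.

    Returns an array the same length as the trace.
    """
    x = trace.values
    n = x.size
    window = int(window)
    order = int(order)
    if not 1 <= order <= window:
        raise ValueError(f"order must be in [1, window], got {order} / {window}")
    if n < window:
        raise TraceTooShortError(f"trace has {n} samples, needs >= {window}")
    windows = sliding_window_view(x, window)
    stats = np.partition(windows, order - 1, axis=1)[:, order - 1]
    out = np.empty(n, dtype=float)
    out[window - 1 :] = stats
    out[: window - 1] = stats[0]
    return out


def _runs(mask: np.ndarray) -> list:
    """Start/stop (half-open) index pairs of maximal True runs."""
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def detect_events(
    trace: TraceSeries, baseline: np.ndarray, k: float = 2.0
) -> EventSet:
    """Find maximal runs of samples strictly above ``baseline + k * sigma``.

    ``sigma`` is the sample SD (n-1 denominator) of the residual
    ``trace - baseline`` over the whole record — the "double SD of the
    baseline" criterion with ``k = 2``.  The event peak is the run
    maximum (earliest index on ties); its amplitude is
    ``(peak - baseline_at_peak) / baseline_at_peak``.
    """
    x = trace.values
    baseline = np.asarray(baseline, dtype=float)
    if baseline.shape != x.shape:
        raise ValueError("baseline must have the same length as the trace")
    residual = x - baseline
    sigma = float(np.std(residual, ddof=1))
    threshold = baseline + k * sigma
    if sigma == 0.0:
        return EventSet(events=[], threshold=threshold, sigma=0.0, flat_residual=True)
    above = x > threshold  # strict inequality: at-threshold samples do not count
    events = []
    dt = trace.sampling_interval_s
    for start, stop in _runs(above):
        seg = x[start:stop]
        peak_idx = start + int(np.argmax(seg))  # argmax -> earliest tie
        b = baseline[peak_idx]
        events.append(
            VasomotionEvent(
                peak_time_s=peak_idx * dt,
                peak_value=float(x[peak_idx]),
                baseline_at_peak=float(b),
                amplitude_frac=float((x[peak_idx] - b) / b),
            )
        )
    return EventSet(events=events, threshold=threshold, sigma=sigma)


def compute_index(
    trace: TraceSeries,
    window: int = 20,
    order: int = 6,
    k: float = 2.0,
) -> OscillationIndex:
    """Run baseline + event detection and reduce to the index triplet.

    Frequency is events per second of recording; amplitude is the mean
    event amplitude in percent (0 with no events); the peak-interval SD
    is the sample SD of consecutive peak-time differences, defined only
    when at least three events (two intervals) exist.
    """
    baseline = sliding_baseline(trace, window=window, order=order)
    evset = detect_events(trace, baseline, k=k)
    duration = trace.duration_s
    n = evset.n_events
    frequency = n / duration
    amplitude_pct = float(np.mean(evset.amplitudes_frac) * 100.0) if n else 0.0
    if n >= 3:
        intervals = np.diff(evset.peak_times_s)
        interval_sd: float | None = float(np.std(intervals, ddof=1))
    else:
        interval_sd = None
    return OscillationIndex(
        frequency_hz=float(frequency),
        amplitude_pct=amplitude_pct,
        peak_interval_sd_s=interval_sd,
        n_events=n,
        duration_s=float(duration),
    )


def mean_roi_trace(stack: FrameStack, roi: np.ndarray) -> TraceSeries:
    """Mean intensity over an ROI mask per frame, as a calcium trace."""
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != stack.data.shape[1:]:
        raise OutOfBoundsError(
            f"ROI shape {roi.shape} does not match frame shape {stack.data.shape[1:]}"
        )
    if not roi.any():
        raise ValueError("ROI mask is empty")
    values = stack.data[:, roi].mean(axis=1)
    return TraceSeries(values=values, sampling_interval_s=stack.frame_interval_s, kind="calcium")
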