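"""Uniformly sampled scalar time series (radius, diameter, fluorescence)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

TRACE_KINDS = ("radius", "diameter", "calcium")


@dataclass
class TraceSeries:
    """A uniformly sampled scalar trace.

    Parameters
    ----------
    values
        Sample values, micrometres for radius/diameter traces or arbitrary
        fluorescence units for calcium traces.
    sampling_interval_s
        Time between consecutive samples, seconds.
    kind
        One of ``radius``, ``diameter``, ``calcium``.
    flags
        Per-sample boolean quality flags; ``True`` marks a sample that was
        interpolated or otherwise suspect.
    """

    values: np.ndarray
    sampling_interval_s: float
    kind: str = "radius"
    flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("trace must be a 1-D array with at least 2 samples")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace values must be finite")
        self.sampling_interval_s = float(self.sampling_interval_s)
        if not self.sampling_interval_s > 0:
            raise ValueError("sampling_interval_s must be positive")
        if self.kind not in TRACE_KINDS:
            raise ValueError(f"kind must be one of {TRACE_KINDS}, got {self.kind!r}")
        if self.flags is None:
            self.flags = np.zeros(self.values.size, dtype=bool)
        else:
            self.flags = np.asarray(self.flags, dtype=bool)
            if self.flags.shape != self.values.shape:
                raise ValueError("flags must match values in shape")

    def __len__(self) -> int:
        return self.values.size

    @property
    def times_s(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.values.size) * self.sampling_interval_s

    @property
    def duration_s(self) -> float:
        """Total record duration (number of samples times the interval)."""
        return self.values.size * self.sampling_interval_s
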