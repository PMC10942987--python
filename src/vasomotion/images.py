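"""Image containers: movie stacks and kymographs with physical calibration."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _check_positive(name: str, value: float) -> float:
    value = float(value)
    if not value > 0:
        raise ValueError(f"{name} must be positive, got {value}")
    return value


@dataclass
class FrameStack:
    """A T x H x W grayscale movie with frame interval and pixel size."""

    data: np.ndarray
    frame_interval_s: float
    pixel_size_um: float
    ground_truth: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[0] < 1:
            raise ValueError("stack must be a T x H x W array with T >= 1")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("stack intensities must be finite")
        self.frame_interval_s = _check_positive("frame_interval_s", self.frame_interval_s)
        self.pixel_size_um = _check_positive("pixel_size_um", self.pixel_size_um)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple:
        return self.data.shape


@dataclass
class ReslicedKymograph:
    """Time x position intensity array from reslicing a movie along a path."""

    data: np.ndarray
    frame_interval_s: float
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("kymograph must be a T x P array")
        self.frame_interval_s = _check_positive("frame_interval_s", self.frame_interval_s)
        self.pixel_size_um = _check_positive("pixel_size_um", self.pixel_size_um)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def path_length_px(self) -> int:
        return self.data.shape[1]


@dataclass
class LineScanKymograph:
    """Line-scan image: scan lines (time) by pixels along the vessel axis.

    ``polarity`` declares whether moving blood cells appear as bright or
    dark streaks against the background.
    """

    data: np.ndarray
    line_period_s: float
    pixel_size_um: float
    polarity: str = "dark"
    ground_truth: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] < 2 or self.data.shape[1] < 2:
            raise ValueError("line scan must be an L x P array with L, P >= 2")
        self.line_period_s = _check_positive("line_period_s", self.line_period_s)
        self.pixel_size_um = _check_positive("pixel_size_um", self.pixel_size_um)
        if self.polarity not in ("bright", "dark"):
            raise ValueError("polarity must be 'bright' or 'dark'")

    @property
    def n_lines(self) -> int:
        return self.data.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.data.shape[1]

    @property
    def total_time_s(self) -> float:
        return self.n_lines * self.line_period_s
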