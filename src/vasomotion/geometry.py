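"""Vessel geometry: reslicing, FWHM diameter, midline-anchored radius.

The vessel lumen appears as a bright band in a dye-filled two-photon
frame.  Its width per frame is read off an intensity profile sampled
along a line orthogonal to the vessel: the diameter is the full width at
half maximum of the profile, with crossings located by linear
interpolation; the radius uses a fixed midline as one boundary and the
half-height crossing on one chosen side as the other.

Half height is referenced to ``(max + min) / 2`` of the (optionally
smoothed) profile — background fluorescence is nonzero in vivo, so a
baseline-relative half height is the conventional reading.  From the
global peak we walk outward on each side to the *first* crossing below
half height, which is robust to background structures beyond the vessel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates, uniform_filter1d

from .errors import (
    NoPeakError,
    OutOfBoundsError,
    TraceRejectedError,
    UnboundedProfileError,
)
from .images import FrameStack, ReslicedKymograph
from .traces import TraceSeries

__all__ = [
    "WidthMeasurement",
    "reslice",
    "profile_fwhm",
    "profile_half_radius",
    "extract_trace",
    "default_midline",
]


@dataclass(frozen=True)
class WidthMeasurement:
    """One width (or radius) measurement on a single profile.

    ``left_crossing_px``/``right_crossing_px`` are sub-pixel positions;
    for a radius measurement one of them is the fixed midline.  ``ok``
    is the quality flag (False never escapes: failing measurements raise
    instead, and callers that tolerate failures record the flag).
    """

    width_um: float
    left_crossing_px: float
    right_crossing_px: float
    ok: bool = True


def reslice(stack: FrameStack, path: np.ndarray) -> ReslicedKymograph:
    """Sample every frame along a path by bilinear interpolation.

    ``path`` is an (M, 2) array of (row, col) coordinates, sub-pixel
    allowed, M >= 3.  Row ``t`` of the output is frame ``t`` sampled
    along the path.
    """
    path = np.asarray(path, dtype=float)
    if path.ndim != 2 or path.shape[1] != 2 or path.shape[0] < 3:
        raise ValueError("path must be an (M, 2) array of (row, col) with M >= 3")
    T, H, W = stack.data.shape
    bad = (
        (path[:, 0] < 0) | (path[:, 0] > H - 1) | (path[:, 1] < 0) | (path[:, 1] > W - 1)
    )
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise OutOfBoundsError(
            f"path point {i} = ({path[i, 0]}, {path[i, 1]}) is outside the "
            f"{H} x {W} image"
        )
    coords = path.T  # (2, M)
    out = np.empty((T, path.shape[0]), dtype=float)
    for t in range(T):
        out[t] = map_coordinates(stack.data[t], coords, order=1, mode="nearest")
    return ReslicedKymograph(
        data=out,
        frame_interval_s=stack.frame_interval_s,
        pixel_size_um=stack.pixel_size_um,
    )


def _smooth(values: np.ndarray, smooth_px: int) -> np.ndarray:
    if smooth_px is None or smooth_px <= 1:
        return values
    return uniform_filter1d(values, size=int(smooth_px), mode="nearest")


def _peak_index(values: np.ndarray) -> int:
    """Global maximum; ties broken toward the profile center, then left."""
    peaks = np.flatnonzero(values == values.max())
    center = (values.size - 1) / 2.0
    return int(peaks[np.argmin(np.abs(peaks - center))])


def _cross_left(values: np.ndarray, peak: int, half: float) -> float:
    """First sub-half crossing walking left from the peak (sub-pixel)."""
    for i in range(peak - 1, -1, -1):
        if values[i] < half:
            # half lies between values[i] (below) and values[i + 1] (>= half)
            return i + (half - values[i]) / (values[i + 1] - values[i])
    raise UnboundedProfileError("no half-height crossing left of the peak")


def _cross_right(values: np.ndarray, peak: int, half: float) -> float:
    for i in range(peak + 1, values.size):
        if values[i] < half:
            return i - (half - values[i]) / (values[i - 1] - values[i])
    raise UnboundedProfileError("no half-height crossing right of the peak")


def profile_fwhm(
    profile: np.ndarray, pixel_size_um: float = 1.0, smooth_px: int = 3
) -> WidthMeasurement:
    """Full width at half maximum of a line profile.

    Half height is ``(max + min) / 2`` after moving-average smoothing
    (``smooth_px`` samples; <= 1 disables).  Crossings are found by
    walking outward from the global peak and linearly interpolating
    between the bracketing samples.
    """
    values = np.asarray(profile, dtype=float)
    if values.ndim != 1 or values.size < 3:
        raise ValueError("profile must be 1-D with at least 3 samples")
    if not np.all(np.isfinite(values)):
        raise ValueError("profile values must be finite")
    values = _smooth(values, smooth_px)
    vmin, vmax = float(values.min()), float(values.max())
    if vmax == vmin:
        raise NoPeakError("flat profile: max equals min")
    half = 0.5 * (vmax + vmin)
    peak = _peak_index(values)
    left = _cross_left(values, peak, half)
    right = _cross_right(values, peak, half)
    return WidthMeasurement(
        width_um=float((right - left) * pixel_size_um),
        left_crossing_px=float(left),
        right_crossing_px=float(right),
    )


def profile_half_radius(
    profile: np.ndarray,
    midline_px: float,
    side: str = "right",
    pixel_size_um: float = 1.0,
    smooth_px: int = 3,
) -> WidthMeasurement:
    """Radius from a fixed midline to the half-height crossing on one side.

    The midline is supplied by the caller once per vessel and held
    constant across frames; only the crossing on the requested side
    moves with the wall.
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    values = np.asarray(profile, dtype=float)
    if values.ndim != 1 or values.size < 3:
        raise ValueError("profile must be 1-D with at least 3 samples")
    if not 0 <= midline_px <= values.size - 1:
        raise OutOfBoundsError(f"midline {midline_px} outside profile of {values.size} px")
    values = _smooth(values, smooth_px)
    vmin, vmax = float(values.min()), float(values.max())
    if vmax == vmin:
        raise NoPeakError("flat profile: max equals min")
    half = 0.5 * (vmax + vmin)
    peak = _peak_index(values)
    if side == "right":
        crossing = _cross_right(values, peak, half)
        left, right = float(midline_px), crossing
    else:
        crossing = _cross_left(values, peak, half)
        left, right = crossing, float(midline_px)
    return WidthMeasurement(
        width_um=float(abs(crossing - midline_px) * pixel_size_um),
        left_crossing_px=float(left),
        right_crossing_px=float(right),
    )


def default_midline(kymo: ReslicedKymograph) -> float:
    """Default midline: intensity centroid of the time-averaged profile.

    The midline was fixed by eye in the original workflow; the centroid
    of the mean profile (above its minimum) is a deterministic surrogate.
    """
    mean_profile = kymo.data.mean(axis=0)
    weights = mean_profile - mean_profile.min()
    total = weights.sum()
    if total == 0:
        return (mean_profile.size - 1) / 2.0
    return float(np.arange(mean_profile.size) @ weights / total)


def extract_trace(
    kymo: ReslicedKymograph,
    mode: str = "diameter",
    midline_px: float | None = None,
    side: str = "right",
    smooth_px: int = 3,
    max_failed_frac: float = 0.2,
) -> TraceSeries:
    """Per-frame width/radius trace from a resliced kymograph.

    Frames whose profile fails measurement (flat, or unbounded at the
    edge) are flagged and linearly interpolated from neighbouring good
    frames; if more than ``max_failed_frac`` of the frames fail the whole
    trace is rejected.
    """
    if mode not in ("diameter", "radius"):
        raise ValueError("mode must be 'diameter' or 'radius'")
    if mode == "radius" and midline_px is None:
        midline_px = default_midline(kymo)
    T = kymo.n_frames
    values = np.full(T, np.nan)
    flags = np.zeros(T, dtype=bool)
    for t in range(T):
        profile = kymo.data[t]
        try:
            if mode == "diameter":
                m = profile_fwhm(profile, kymo.pixel_size_um, smooth_px)
            else:
                m = profile_half_radius(
                    profile, midline_px, side, kymo.pixel_size_um, smooth_px
                )
            values[t] = m.width_um
        except (NoPeakError, UnboundedProfileError):
            flags[t] = True
    n_failed = int(flags.sum())
    if n_failed > max_failed_frac * T:
        raise TraceRejectedError(
            f"{n_failed}/{T} frames failed width measurement "
            f"(> {max_failed_frac:.0%} allowed)"
        )
    if n_failed:
        good = np.flatnonzero(~flags)
        values[flags] = np.interp(np.flatnonzero(flags), good, values[good])
    return TraceSeries(
        values=values,
        sampling_interval_s=kymo.frame_interval_s,
        kind=mode,
        flags=flags,
    )
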