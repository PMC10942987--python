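"""Line-scan velocimetry, blood-cell flux, and capillary stall detection.

A line scan repeatedly samples intensity along a line placed inside a
vessel lumen; a moving blood cell traces a slanted streak in the
resulting lines x pixels kymograph.  The streak slope (pixels per line)
times the pixel size over the line period gives the cell velocity, and
the streak count over the scan time gives the flux.  A capillary is
*stalled* when no cell moves for at least ``stall_min_frames``
consecutive frames (10 frames ~ 10.8 s in a standard 200-frame record).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.ndimage import map_coordinates
from scipy.optimize import minimize_scalar

from .errors import DegenerateStreakError, LengthMismatchError, TraceTooShortError
from .images import LineScanKymograph
from .traces import TraceSeries

__all__ = [
    "FlowMeasurement",
    "StallReport",
    "streak_velocity",
    "auto_streak_velocity",
    "flux",
    "flowing_indicator",
    "stall_classify",
    "stall_rate",
]


@dataclass
class FlowMeasurement:
    """Signed velocity and/or flux for one vessel.

    ``velocity_mm_s`` is ``None`` when no flow could be measured (e.g. a
    streak-free kymograph in automatic mode).  The sign convention is
    +1 = the declared baseline flow direction.
    """

    velocity_mm_s: float | None = None
    flux_cells_per_s: float | None = None
    direction_sign_convention: int = 1
    n_streaks: int = 0


@dataclass
class StallReport:
    """Per-capillary stall classification."""

    flowing: np.ndarray  # per-frame boolean, length = record_frames
    stalled: bool
    longest_stall_frames: int


# --------------------------------------------------------------------------
# velocity


def streak_velocity(
    kymo: LineScanKymograph,
    streaks: list,
    positive_direction: int = 1,
) -> FlowMeasurement:
    """Velocity from manually annotated streak endpoints.

    ``streaks`` is a list of endpoint pairs ``((line0, px0), (line1, px1))``
    (sub-pixel allowed, distinct line indices).  Per streak the velocity
    is ``(dpx * pixel_size_um) / (dline * line_period_s)``; the vessel
    velocity is the mean over streaks, in mm/s, signed so that motion in
    the declared positive direction is positive.
    """
    if not streaks:
        raise ValueError("need at least one streak annotation")
    velocities = []
    for (l0, p0), (l1, p1) in streaks:
        dline = l1 - l0
        if dline == 0:
            raise DegenerateStreakError("streak endpoints on the same scan line")
        slope = (p1 - p0) / dline  # px per line
        velocities.append(slope * kymo.pixel_size_um / kymo.line_period_s)
    v_um_s = float(np.mean(velocities)) * positive_direction
    return FlowMeasurement(
        velocity_mm_s=v_um_s / 1000.0,
        direction_sign_convention=positive_direction,
        n_streaks=len(streaks),
    )


def _shear_projection_score(block: np.ndarray, theta_deg: float) -> float:
    """Variance of the shear projection of ``block`` at angle ``theta_deg``.

    theta is the streak angle from vertical: tan(theta) = pixels per line.
    Each line is shifted so that streaks at that angle become vertical,
    then lines are averaged; aligned streaks give a high-contrast profile
    (large variance), misaligned ones blur out.  For slopes steeper than
    one pixel per line the same projection is evaluated on the
    transposed block (slope 1/s), keeping the shear within the field.
    """
    slope = math.tan(math.radians(theta_deg))
    if abs(slope) > 1.0:
        block = block.T
        slope = 1.0 / slope
    n, p = block.shape
    rows = np.arange(n, dtype=float)
    cols = np.arange(p, dtype=float)
    shift = slope * (rows - (n - 1) / 2.0)
    rr = np.repeat(rows, p)
    cc = (cols[None, :] + shift[:, None]).ravel()
    vals = map_coordinates(block, [rr, cc], order=1, mode="constant", cval=np.nan)
    vals = vals.reshape(n, p)
    counts = np.sum(~np.isnan(vals), axis=0)
    valid = counts >= max(2, int(0.7 * n))
    if valid.sum() < 5:
        return -np.inf
    with np.errstate(invalid="ignore"):
        proj = np.nanmean(vals[:, valid], axis=0)
    return float(np.var(proj))


def auto_streak_velocity(
    kymo: LineScanKymograph,
    block_lines: int | None = None,
    angle_step_deg: float = 1.0,
    angle_max_deg: float = 89.0,
    variance_floor: float = 2.0,
    positive_direction: int = 1,
) -> FlowMeasurement:
    """Automatic velocity from the dominant streak orientation.

    The kymograph is cut into blocks of ``block_lines`` lines.  Per
    block, candidate streak angles on a coarse grid (1 degree default,
    excluding exactly horizontal) are scored by the variance of the
    shear projection; the grid maximum is refined by a bounded
    continuous search within +-1 grid step.  A block whose best score
    does not exceed ``variance_floor`` times the median score is treated
    as streak-free and skipped.  The reported velocity is the median
    over blocks; if every block is skipped the result is a no-flow
    measurement (velocity ``None``).
    """
    L, P = kymo.data.shape
    if block_lines is None:
        block_lines = min(L, 128)
    if L < block_lines:
        raise ValueError(f"kymograph has {L} lines, needs >= {block_lines}")
    thetas = np.arange(-angle_max_deg, angle_max_deg + 1e-9, angle_step_deg)
    block_velocities = []
    n_blocks = L // block_lines
    for b in range(n_blocks):
        block = kymo.data[b * block_lines : (b + 1) * block_lines].astype(float)
        block = block - block.mean()
        scores = np.array([_shear_projection_score(block, th) for th in thetas])
        if not np.isfinite(scores).any():
            continue
        finite = scores[np.isfinite(scores)]
        best_i = int(np.nanargmax(np.where(np.isfinite(scores), scores, -np.inf)))
        if scores[best_i] < variance_floor * np.median(finite):
            continue  # no dominant orientation: streak-free block
        lo = max(-angle_max_deg, thetas[best_i] - angle_step_deg)
        hi = min(angle_max_deg, thetas[best_i] + angle_step_deg)
        def neg_score(th):
            s = _shear_projection_score(block, th)
            return -s if np.isfinite(s) else 1e300

        res = minimize_scalar(
            neg_score, bounds=(lo, hi), method="bounded", options={"xatol": 1e-3}
        )
        theta = float(res.x) if np.isfinite(res.fun) else float(thetas[best_i])
        slope = math.tan(math.radians(theta))  # px per line
        block_velocities.append(slope * kymo.pixel_size_um / kymo.line_period_s)
    if not block_velocities:
        return FlowMeasurement(
            velocity_mm_s=None, direction_sign_convention=positive_direction
        )
    v_um_s = float(np.median(block_velocities)) * positive_direction
    return FlowMeasurement(
        velocity_mm_s=v_um_s / 1000.0,
        direction_sign_convention=positive_direction,
        n_streaks=len(block_velocities),
    )


# --------------------------------------------------------------------------
# flux


def flux(kymo: LineScanKymograph, streak_count: int) -> FlowMeasurement:
    """Cell flux: streak count divided by the total scan time."""
    if streak_count < 0:
        raise ValueError("streak_count must be >= 0")
    return FlowMeasurement(
        flux_cells_per_s=streak_count / kymo.total_time_s,
        n_streaks=int(streak_count),
    )


# --------------------------------------------------------------------------
# stalls


def flowing_indicator(
    roi_trace: TraceSeries,
    window_frames: int = 3,
    k_sigma: float = 2.0,
    quiet_quantile: float = 0.04,
    contrast_min: float = 3.0,
) -> np.ndarray:
    """Per-frame flowing/quiet indicator from local intensity dispersion.

    Blood-cell transit makes the ROI intensity fluctuate frame to frame;
    during a stall only sensor noise remains.  The statistic is the
    sample SD over sliding windows of ``window_frames``; a frame counts
    as non-flowing when *some* window containing it is quiet, so a stall
    of exactly ``n`` frames maps to exactly ``n`` non-flowing frames in
    the noiseless limit.

    The quiet threshold is ``k_sigma`` times an estimate of the sensor
    noise SD, built in two stages: (1) a noise floor from the mean of
    the lowest ``quiet_quantile`` of windowed SDs (4% by default — the
    fraction of windows a minimal 10-frame stall contributes to a
    200-frame record); (2) a refinement that pools the frame values
    lying under provisionally quiet windows (SD below half the median
    level) and takes their within-run SD, which is unbiased where the
    small-window SDs are not.  When the
    record shows no quiet cluster — the median windowed SD is below
    ``contrast_min`` times the noise floor — every frame is reported
    flowing; a perfectly constant record is all non-flowing.
    """
    x = roi_trace.values
    n = x.size
    w = int(window_frames)
    if n < w:
        raise TraceTooShortError(f"trace has {n} samples, needs >= {w}")
    sds = np.std(sliding_window_view(x, w), axis=1, ddof=1)
    scale = float(np.median(sds))
    if scale == 0.0:
        return np.zeros(n, dtype=bool)  # constant record: nothing moves
    k = max(3, int(np.ceil(quiet_quantile * sds.size)))
    floor = float(np.mean(np.sort(sds)[:k]))
    if floor > 0 and scale < contrast_min * floor:
        return np.ones(n, dtype=bool)  # no quiet cluster: flowing throughout
    # provisional quiet windows: well below the flowing dispersion level
    split = 0.5 * scale
    quiet_win = sds <= split
    # refine the noise SD from frames lying only under quiet windows
    interior = np.ones(n, dtype=bool)
    for j in np.flatnonzero(~quiet_win):
        interior[j : j + w] = False
    sigma_n = floor
    if interior.any():
        resid2, dof = 0.0, 0
        for start, stop in _bool_runs(interior):
            seg = x[start:stop]
            if seg.size >= 2:
                resid2 += float(np.sum((seg - seg.mean()) ** 2))
                dof += seg.size - 1
        if dof > 0:
            sigma_n = math.sqrt(resid2 / dof)
    thr = k_sigma * sigma_n
    nonflowing = np.zeros(n, dtype=bool)
    for j in np.flatnonzero(sds <= thr):
        nonflowing[j : j + w] = True
    return ~nonflowing


def _bool_runs(mask: np.ndarray) -> list:
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def _longest_false_run(flowing) -> int:
    longest = 0
    current = 0
    for f in flowing:
        if f:
            if current > longest:
                longest = current
            current = 0
        else:
            current += 1
    return max(longest, current)


def stall_classify(
    flowing,
    stall_min_frames: int = 10,
    record_frames: int = 200,
) -> StallReport:
    """Stalled iff some run of >= ``stall_min_frames`` non-flowing frames.

    ``flowing`` is the per-frame boolean indicator and must have exactly
    ``record_frames`` entries.  Runs are not merged across intervening
    flowing frames.
    """
    flowing = np.asarray(flowing, dtype=bool)
    if flowing.size != record_frames:
        raise LengthMismatchError(
            f"indicator has {flowing.size} frames, expected {record_frames}"
        )
    longest = _longest_false_run(flowing.tolist())
    return StallReport(
        flowing=flowing,
        stalled=longest >= stall_min_frames,
        longest_stall_frames=longest,
    )


def stall_rate(reports: list) -> float:
    """Percentage of stalled capillaries in a set of reports."""
    if not reports:
        raise ValueError("need at least one capillary report")
    return 100.0 * sum(r.stalled for r in reports) / len(reports)
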