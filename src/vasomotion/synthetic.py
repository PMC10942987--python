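"""Synthetic movies, kymographs, and traces with known ground truth.

Every generator emulates one acquisition mode of the two-photon stroke
imaging workflow — dye-filled vessel lumen movies whose radius
oscillates sinusoidally (~0.1 Hz, a few percent), smooth-muscle calcium
traces with supra-baseline transients, line-scan kymographs with
blood-cell streaks of known signed velocity, and capillary records with
inserted flow-free (stall) intervals — and attaches the generating
parameters as ground truth so every analysis operation can be tested
for parameter recovery.

All randomness flows from the explicit ``seed`` in each spec; identical
spec + seed gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import erf

from .cooperation import DEFAULT_OFFSETS_UM, PositionalTraceSet
from .errors import InvalidSpecError
from .images import FrameStack, LineScanKymograph
from .traces import TraceSeries

__all__ = [
    "FRAME_INTERVAL_BOUNDS_S",
    "OscillationSpec",
    "VesselMovieSpec",
    "FlowSpec",
    "StallSpec",
    "make_radius_trace",
    "make_calcium_trace",
    "make_vessel_movie",
    "make_linescan_kymograph",
    "make_capillary_movie",
    "make_coupled_trace_set",
]

# frame-scan interval range of the acquisition regime (0.625-0.926 Hz)
FRAME_INTERVAL_BOUNDS_S = (1.0 / 0.926, 1.0 / 0.625)

_MIN_SAMPLES = 20
_CALCIUM_KERNEL_HALF = 3  # half-sine event: 3-sample rise, 3-sample fall


@dataclass(frozen=True)
class OscillationSpec:
    """Parameters of a sinusoidally oscillating scalar trace.

    ``amplitude_frac`` is the peak deviation over the base level, so
    0.03 means a 3% oscillation.  ``frame_interval_s`` must lie within
    ``frame_interval_bounds`` (the frame-scan range of the acquisition;
    pass ``None`` to lift the restriction).
    """

    base_level: float
    frequency_hz: float = 0.1
    amplitude_frac: float = 0.03
    phase_rad: float = 0.0
    noise_sd: float = 0.0
    drift_per_s: float = 0.0
    duration_s: float = 300.0
    frame_interval_s: float = 1.0 / 0.926
    seed: int = 0
    frame_interval_bounds: tuple | None = FRAME_INTERVAL_BOUNDS_S

    def __post_init__(self) -> None:
        if not self.base_level > 0:
            raise InvalidSpecError("base_level must be positive")
        if self.frequency_hz < 0 or self.amplitude_frac < 0 or self.noise_sd < 0:
            raise InvalidSpecError("frequency, amplitude and noise must be >= 0")
        if not self.duration_s > 0 or not self.frame_interval_s > 0:
            raise InvalidSpecError("duration and frame interval must be positive")
        if self.frame_interval_bounds is not None:
            lo, hi = self.frame_interval_bounds
            if not lo - 1e-9 <= self.frame_interval_s <= hi + 1e-9:
                raise InvalidSpecError(
                    f"frame_interval_s {self.frame_interval_s:.4f} outside "
                    f"[{lo:.4f}, {hi:.4f}] s"
                )
        if self.n_samples < _MIN_SAMPLES:
            raise InvalidSpecError(
                f"duration/interval gives {self.n_samples} samples, "
                f"need >= {_MIN_SAMPLES}"
            )

    @property
    def n_samples(self) -> int:
        return int(self.duration_s / self.frame_interval_s)


@dataclass(frozen=True)
class VesselMovieSpec:
    """A movie of a horizontal vessel whose radius follows an oscillation."""

    oscillation: OscillationSpec
    image_shape: tuple = (64, 64)
    pixel_size_um: float = 0.994
    vessel_axis_row: float | None = None  # default: image center row
    lumen_intensity: float = 200.0
    background_intensity: float = 20.0
    edge_softness_px: float = 1.0
    pixel_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        H, W = self.image_shape
        if H < 3 or W < 3:
            raise InvalidSpecError("image must be at least 3 x 3")
        if not self.lumen_intensity > self.background_intensity:
            raise InvalidSpecError("lumen must be brighter than background")
        if self.edge_softness_px < 0 or self.pixel_noise_sd < 0:
            raise InvalidSpecError("edge softness and noise must be >= 0")
        osc = self.oscillation
        max_radius_um = osc.base_level * (1 + osc.amplitude_frac) + max(
            0.0, osc.drift_per_s * osc.duration_s
        )
        # profile is measured across rows: the whole lumen must fit in H
        if 2 * max_radius_um / self.pixel_size_um >= H:
            raise InvalidSpecError(
                f"vessel diameter up to {2 * max_radius_um:.1f} um does not fit "
                f"in {H} rows at {self.pixel_size_um} um/px"
            )


@dataclass(frozen=True)
class FlowSpec:
    """A line-scan kymograph with blood-cell streaks of known velocity."""

    velocity_mm_s: float = 1.0
    cell_rate_hz: float = 20.0
    line_period_s: float = 0.002
    pixels: int = 200
    pixel_size_um: float = 2.0
    n_lines: int = 512
    streak_polarity: str = "dark"
    background_intensity: float = 100.0
    streak_contrast: float = 60.0
    streak_sigma_px: float = 0.8
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixels < 2 or self.n_lines < 2:
            raise InvalidSpecError("need at least 2 pixels and 2 lines")
        if self.streak_polarity not in ("bright", "dark"):
            raise InvalidSpecError("streak_polarity must be 'bright' or 'dark'")
        if self.cell_rate_hz < 0 or self.noise_sd < 0:
            raise InvalidSpecError("cell rate and noise must be >= 0")
        if not self.line_period_s > 0 or not self.pixel_size_um > 0:
            raise InvalidSpecError("line period and pixel size must be positive")
        slope = abs(self.velocity_mm_s) * 1000.0 * self.line_period_s / self.pixel_size_um
        if slope >= self.pixels:
            raise InvalidSpecError(
                "velocity too high: a streak crosses the scan window in < 2 lines"
            )

    @property
    def slope_px_per_line(self) -> float:
        """Signed streak slope: pixels advanced per scan line."""
        return self.velocity_mm_s * 1000.0 * self.line_period_s / self.pixel_size_um


@dataclass(frozen=True)
class StallSpec:
    """A capillary ROI record with optional flow-free intervals.

    While flowing, blood-cell transit modulates the ROI intensity with
    SD ``transit_signal_sd``; inside a stall only sensor noise
    (``noise_sd``) remains.  The default 200 frames at 1.0841 s span
    ~216.8 s, the standard stall-counting record.
    """

    n_frames: int = 200
    frame_interval_s: float = 1.0841
    stall_intervals: tuple = ()
    transit_signal_sd: float = 10.0
    noise_sd: float = 2.0
    base_intensity: float = 100.0
    roi_shape: tuple = (8, 8)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise InvalidSpecError("need at least 2 frames")
        if not self.transit_signal_sd > self.noise_sd:
            raise InvalidSpecError("transit_signal_sd must exceed noise_sd")
        covered = np.zeros(self.n_frames, dtype=bool)
        for start, length in self.stall_intervals:
            if start < 0 or length < 1 or start + length > self.n_frames:
                raise InvalidSpecError(
                    f"stall interval ({start}, {length}) outside [0, {self.n_frames})"
                )
            if covered[start : start + length].any():
                raise InvalidSpecError("stall intervals overlap")
            covered[start : start + length] = True

    def stall_mask(self) -> np.ndarray:
        mask = np.zeros(self.n_frames, dtype=bool)
        for start, length in self.stall_intervals:
            mask[start : start + length] = True
        return mask


# --------------------------------------------------------------------------
# generators


def make_radius_trace(spec: OscillationSpec) -> TraceSeries:
    """Sinusoidal radius trace with optional linear drift and noise.

    ``x[t] = base * (1 + a * sin(2 pi f t + phi)) + drift * t + N(0, sd^2)``.
    """
    rng = np.random.default_rng(spec.seed)
    t = np.arange(spec.n_samples) * spec.frame_interval_s
    values = spec.base_level * (
        1.0 + spec.amplitude_frac * np.sin(2 * np.pi * spec.frequency_hz * t + spec.phase_rad)
    )
    values = values + spec.drift_per_s * t
    if spec.noise_sd > 0:
        values = values + rng.normal(0.0, spec.noise_sd, values.size)
    return TraceSeries(values=values, sampling_interval_s=spec.frame_interval_s, kind="radius")


def make_calcium_trace(spec: OscillationSpec):
    """Noisy baseline plus half-sine transient events.

    Events arrive as a Poisson process at mean rate ``frequency_hz``
    (thinned so events never overlap); each is a half-sine bump with a
    3-sample rise and fall peaking at ``amplitude_frac * base_level``
    above baseline.  Returns ``(trace, event_peak_times_s)`` with the
    ground-truth event times in seconds.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    dt = spec.frame_interval_s
    values = np.full(n, float(spec.base_level))
    half = _CALCIUM_KERNEL_HALF
    kernel = np.sin(np.pi * np.arange(2 * half + 1) / (2 * half))
    peak_indices: list = []
    if spec.frequency_hz > 0:
        t = 0.0
        last_peak = -np.inf
        while True:
            t += rng.exponential(1.0 / spec.frequency_hz)
            idx = int(round(t / dt))
            if idx >= n - half:
                break
            if idx - last_peak < 2 * half + 1 or idx < half:
                continue
            peak_indices.append(idx)
            last_peak = idx
            amp = spec.amplitude_frac * spec.base_level
            values[idx - half : idx + half + 1] += amp * kernel
    if spec.noise_sd > 0:
        values = values + rng.normal(0.0, spec.noise_sd, n)
    trace = TraceSeries(values=values, sampling_interval_s=dt, kind="calcium")
    return trace, np.array(peak_indices, dtype=float) * dt


def _band_profile(rows, center, half_width_px, softness_px):
    if softness_px > 0:
        s = softness_px * np.sqrt(2.0)
        return 0.5 * (
            erf((rows - (center - half_width_px)) / s)
            - erf((rows - (center + half_width_px)) / s)
        )
    return ((rows >= center - half_width_px) & (rows <= center + half_width_px)).astype(float)


def make_vessel_movie(spec: VesselMovieSpec) -> FrameStack:
    """Movie of a bright horizontal band whose half-width tracks the radius.

    The ground-truth radius trace (um) is attached under
    ``ground_truth["radius_um"]``.
    """
    osc = spec.oscillation
    radius = make_radius_trace(osc)
    H, W = spec.image_shape
    center = (H - 1) / 2.0 if spec.vessel_axis_row is None else float(spec.vessel_axis_row)
    rng = np.random.default_rng(osc.seed + 1)
    rows = np.arange(H, dtype=float)
    frames = np.empty((len(radius), H, W), dtype=float)
    for t, r_um in enumerate(radius.values):
        half_px = r_um / spec.pixel_size_um
        profile = _band_profile(rows, center, half_px, spec.edge_softness_px)
        frame = spec.background_intensity + (
            spec.lumen_intensity - spec.background_intensity
        ) * profile
        frames[t] = frame[:, None]
    if spec.pixel_noise_sd > 0:
        frames = frames + rng.normal(0.0, spec.pixel_noise_sd, frames.shape)
    return FrameStack(
        data=frames,
        frame_interval_s=osc.frame_interval_s,
        pixel_size_um=spec.pixel_size_um,
        ground_truth={
            "radius_um": radius.values.copy(),
            "vessel_axis_row": center,
            "spec": asdict(spec),
        },
    )


def make_linescan_kymograph(spec: FlowSpec) -> LineScanKymograph:
    """Line-scan kymograph with Poisson-arriving streaks of fixed slope.

    Each blood-cell arrival draws one slanted streak of slope
    ``velocity * line_period / pixel_size`` pixels per line; negative
    velocity mirrors the slope.  Ground truth records the velocity,
    slope, and streak count.
    """
    rng = np.random.default_rng(spec.seed)
    L, P = spec.n_lines, spec.pixels
    img = np.full((L, P), float(spec.background_intensity))
    slope = spec.slope_px_per_line
    total_time = L * spec.line_period_s
    n_cells = rng.poisson(spec.cell_rate_hz * total_time)
    sign = 1.0 if spec.streak_polarity == "bright" else -1.0
    cols = np.arange(P, dtype=float)
    anchors = np.sort(rng.uniform(0, L, n_cells))
    entry = rng.uniform(0, P, n_cells)
    for t0, x0 in zip(anchors, entry):
        lines = np.arange(L)
        x = x0 + slope * (lines - t0)
        inside = (x > -3 * spec.streak_sigma_px) & (x < P - 1 + 3 * spec.streak_sigma_px)
        for li in lines[inside]:
            img[li] += (
                sign
                * spec.streak_contrast
                * np.exp(-0.5 * ((cols - (x0 + slope * (li - t0))) / spec.streak_sigma_px) ** 2)
            )
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    return LineScanKymograph(
        data=img,
        line_period_s=spec.line_period_s,
        pixel_size_um=spec.pixel_size_um,
        polarity=spec.streak_polarity,
        ground_truth={
            "velocity_mm_s": spec.velocity_mm_s,
            "slope_px_per_line": slope,
            "n_streaks": int(n_cells),
            "arrival_lines": anchors,
        },
    )


def make_capillary_movie(spec: StallSpec) -> FrameStack:
    """Capillary ROI movie with flow-free intervals of known position.

    While flowing, the frame intensity carries a sign-alternating
    random-depth transit modulation with SD ``transit_signal_sd``: at a
    ~1 s frame interval successive frames sample uncorrelated blood-cell
    occupancy, so every pair of neighbouring flowing frames differs
    visibly.  Stalled frames carry only sensor noise.  The ground-truth
    stall mask is attached.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_frames
    stall = spec.stall_mask()
    depth = 1.0 + 0.3 * rng.uniform(-1.0, 1.0, n)
    transit = spec.transit_signal_sd * depth * (-1.0) ** np.arange(n)
    transit[stall] = 0.0
    noise = rng.normal(0.0, spec.noise_sd, n) if spec.noise_sd > 0 else np.zeros(n)
    frame_value = spec.base_intensity + transit + noise
    H, W = spec.roi_shape
    frames = np.broadcast_to(frame_value[:, None, None], (n, H, W)).copy()
    return FrameStack(
        data=frames,
        frame_interval_s=spec.frame_interval_s,
        pixel_size_um=1.0,
        ground_truth={
            "stall_mask": stall,
            "stall_intervals": tuple(spec.stall_intervals),
            "spec": asdict(spec),
        },
    )


def make_coupled_trace_set(
    coupling_length_um: float,
    offsets_um: np.ndarray = DEFAULT_OFFSETS_UM,
    base_level: float = 20.0,
    amplitude_frac: float = 0.03,
    frequency_hz: float = 0.1,
    duration_s: float = 300.0,
    frame_interval_s: float = 1.0 / 0.926,
    seed: int = 0,
) -> PositionalTraceSet:
    """Positionally coupled radius traces with distance-decaying coherence.

    Every site mixes a shared sinusoid with independent Gaussian noise;
    the mixing weight decays as ``exp(-|offset| / coupling_length_um)``,
    so the expected Pearson r against the core site equals that weight
    and the cooperation extent grows with the coupling length.
    """
    if coupling_length_um <= 0:
        raise InvalidSpecError("coupling_length_um must be positive")
    rng = np.random.default_rng(seed)
    offsets_um = np.asarray(offsets_um, dtype=float)
    n = int(duration_s / frame_interval_s)
    t = np.arange(n) * frame_interval_s
    shared = np.sin(2 * np.pi * frequency_hz * t)
    shared = shared / shared.std()
    values = np.empty((offsets_um.size, n))
    for i, off in enumerate(offsets_um):
        c = np.exp(-abs(off) / coupling_length_um) if off != 0 else 1.0
        indep = rng.standard_normal(n)
        indep = (indep - indep.mean()) / indep.std()
        mix = c * shared + np.sqrt(max(0.0, 1.0 - c * c)) * indep
        values[i] = base_level * (1.0 + amplitude_frac * mix / np.sqrt(2.0))
    return PositionalTraceSet(
        offsets_um=offsets_um, values=values, sampling_interval_s=frame_interval_s
    )
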