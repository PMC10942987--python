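"""Spatial synchronization ("cooperation") of vasomotion along a vessel.

Smooth muscle cells along an arteriole contract collectively; the
cooperation index quantifies this by the Pearson correlation between the
radius dynamics at a core position and at offsets up to +-35 um along
the vessel (2.5 um steps, 29 sites).  The *extent* is the largest
distance out to which every site on both sides stays at or above the
correlation threshold (R >= 0.3 by default), scanning contiguously
outward from the core.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import OutOfBoundsError
from .geometry import extract_trace, reslice
from .images import FrameStack

__all__ = [
    "DEFAULT_OFFSETS_UM",
    "PositionalTraceSet",
    "positional_traces",
    "positional_traces_from_table",
    "cooperation_profile",
    "cooperation_extent",
    "cooperation_matrix",
    "CooperationProfile",
    "mean_profile",
]

DEFAULT_OFFSETS_UM = np.round(np.arange(-35.0, 35.0 + 1e-9, 2.5), 6)


@dataclass
class PositionalTraceSet:
    """One radius/diameter trace per position along the vessel.

    ``values`` is (n_sites, T); sites whose extraction failed are
    all-NaN rows and are excluded pairwise downstream.
    """

    offsets_um: np.ndarray
    values: np.ndarray
    sampling_interval_s: float

    def __post_init__(self) -> None:
        self.offsets_um = np.asarray(self.offsets_um, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.offsets_um.size:
            raise ValueError("values must be (n_sites, T) matching offsets")
        if not np.all(np.diff(self.offsets_um) > 0):
            raise ValueError("offsets must be strictly increasing")
        if not np.allclose(self.offsets_um, -self.offsets_um[::-1]):
            raise ValueError("offsets must be symmetric about 0")

    @property
    def core_index(self) -> int:
        return int(np.argmin(np.abs(self.offsets_um)))

    @property
    def n_sites(self) -> int:
        return self.offsets_um.size

    def usable(self) -> np.ndarray:
        return ~np.isnan(self.values).any(axis=1)


@dataclass
class CooperationProfile:
    """Pearson r versus offset from the core position."""

    offsets_um: np.ndarray
    r_values: np.ndarray  # NaN where undefined (zero variance / failed site)
    r_threshold: float = 0.3
    extent_um: float = field(default=np.nan)


def positional_traces(
    stack: FrameStack,
    core_col_px: float,
    offsets_um: np.ndarray = DEFAULT_OFFSETS_UM,
    mode: str = "radius",
    side: str = "right",
    smooth_px: int = 3,
    min_usable: int = 15,
) -> PositionalTraceSet:
    """Extract per-site radius traces from a movie of a horizontal vessel.

    Measurement sites are columns at ``core_col_px`` plus each offset
    (converted to pixels); each site's profile is the full image column,
    resliced per frame and reduced to a radius (or diameter) trace.
    Sites that fail extraction become NaN rows; fewer than ``min_usable``
    usable sites is an error.
    """
    offsets_um = np.asarray(offsets_um, dtype=float)
    T, H, W = stack.data.shape
    cols = core_col_px + offsets_um / stack.pixel_size_um
    if cols.min() < 0 or cols.max() > W - 1:
        raise OutOfBoundsError(
            f"measurement sites span columns {cols.min():.1f}..{cols.max():.1f}, "
            f"outside the {W}-px field of view"
        )
    rows = np.arange(H, dtype=float)
    values = np.full((offsets_um.size, T), np.nan)
    for i, c in enumerate(cols):
        path = np.column_stack((rows, np.full(H, c)))
        kymo = reslice(stack, path)
        try:
            tr = extract_trace(kymo, mode=mode, side=side, smooth_px=smooth_px)
        except Exception:
            continue
        values[i] = tr.values
    ts = PositionalTraceSet(
        offsets_um=offsets_um,
        values=values,
        sampling_interval_s=stack.frame_interval_s,
    )
    if int(ts.usable().sum()) < min_usable:
        raise ValueError(
            f"only {int(ts.usable().sum())} usable sites (< {min_usable})"
        )
    return ts


def positional_traces_from_table(
    table: pd.DataFrame, sampling_interval_s: float | None = None
) -> PositionalTraceSet:
    """Build a trace set from a wide table (identity pass-through).

    Columns named ``r_<offset>`` (e.g. ``r_-35.0`` .. ``r_+35.0``) hold
    one trace per offset; an optional ``time_s`` column supplies the
    sampling interval.
    """
    cols = [c for c in table.columns if c.startswith("r_")]
    if not cols:
        raise ValueError("table has no r_<offset> columns")
    offsets = np.array([float(c[2:]) for c in cols])
    order = np.argsort(offsets)
    values = table[np.array(cols)[order]].to_numpy(dtype=float).T
    if sampling_interval_s is None:
        if "time_s" not in table.columns:
            raise ValueError("need a time_s column or explicit sampling interval")
        sampling_interval_s = float(np.median(np.diff(table["time_s"].to_numpy())))
    return PositionalTraceSet(
        offsets_um=offsets[order],
        values=values,
        sampling_interval_s=sampling_interval_s,
    )


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        return np.nan
    return float((a @ b) / denom)


def cooperation_profile(
    traces: PositionalTraceSet, r_threshold: float = 0.3
) -> CooperationProfile:
    """Pearson r of every site against the core site.

    r at the core offset is 1 by definition; sites with zero variance or
    failed extraction are NaN (missing, not zero).  The profile's extent
    at the threshold is filled in via :func:`cooperation_extent`.
    """
    if traces.values.shape[1] < 3:
        raise ValueError("need at least 3 time points")
    core = traces.values[traces.core_index]
    if np.isnan(core).any() or np.std(core) == 0:
        raise ValueError("core trace is unusable (missing or zero variance)")
    r = np.full(traces.n_sites, np.nan)
    usable = traces.usable()
    for i in range(traces.n_sites):
        if usable[i]:
            r[i] = _pearson(traces.values[i], core)
    r[traces.core_index] = 1.0
    profile = CooperationProfile(
        offsets_um=traces.offsets_um, r_values=r, r_threshold=r_threshold
    )
    profile.extent_um = cooperation_extent(profile, r_threshold)
    return profile


def cooperation_extent(profile: CooperationProfile, r_threshold: float = 0.3) -> float:
    """Largest contiguous distance with r >= threshold on both sides.

    Scans outward from the core; a missing (NaN) r breaks contiguity.
    Returns 0 if the first neighbours already fail.
    """
    offsets = profile.offsets_um
    r = profile.r_values
    core = int(np.argmin(np.abs(offsets)))
    distances = np.unique(np.abs(offsets[np.abs(offsets) > 0]))
    extent = 0.0
    for d in np.sort(distances):
        sites = np.flatnonzero(np.isclose(np.abs(offsets), d))
        ok = all(np.isfinite(r[s]) and r[s] >= r_threshold for s in sites)
        if not ok:
            break
        extent = float(d)
    return extent


def cooperation_matrix(traces: PositionalTraceSet) -> np.ndarray:
    """All-pairs Pearson matrix over positions (symmetric, unit diagonal).

    Rows/columns of unusable or zero-variance sites are NaN.
    """
    if traces.values.shape[1] < 3:
        raise ValueError("need at least 3 time points")
    n = traces.n_sites
    mat = np.full((n, n), np.nan)
    usable = np.flatnonzero(traces.usable())
    sub = traces.values[usable]
    sd = sub.std(axis=1)
    good = usable[sd > 0]
    if good.size:
        block = np.corrcoef(traces.values[good])
        mat[np.ix_(good, good)] = block
    for i in usable:
        mat[i, i] = 1.0
    return mat


def mean_profile(profiles: list) -> CooperationProfile:
    """Unweighted mean r per offset across vessels (NaNs ignored)."""
    if not profiles:
        raise ValueError("no profiles to average")
    offsets = profiles[0].offsets_um
    for p in profiles[1:]:
        if not np.allclose(p.offsets_um, offsets):
            raise ValueError("profiles have mismatched offset grids")
    stacked = np.vstack([p.r_values for p in profiles])
    with np.errstate(invalid="ignore"):
        mean_r = np.nanmean(stacked, axis=0)
    out = CooperationProfile(
        offsets_um=offsets, r_values=mean_r, r_threshold=profiles[0].r_threshold
    )
    out.extent_um = cooperation_extent(out, out.r_threshold)
    return out
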