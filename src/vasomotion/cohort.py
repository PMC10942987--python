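"""Vessel-state classification and pre/post-ischemia normalization.

Two classifications of an oscillation index:

temporal
    an arteriole is *inert* when its vasomotion frequency falls below
    the venular reference frequency (0.0249 Hz by default; the figure
    legends of the source workflow round this to 0.026 Hz, and the
    cutoff is configurable);
spatial
    an arteriole is *aberrant* when its vasomotion amplitude is extreme
    — above 5% (``aberrant_high``) or below 1% (``aberrant_low``);
    boundary values count as normal.

Change rates express a post-ischemia value as a percentage of its
pre-ischemia baseline; the paired table joins strictly matched pre/post
measurements per vessel or cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .oscillation import OscillationIndex

__all__ = [
    "INERT_CUTOFF_HZ",
    "AMPLITUDE_HIGH_PCT",
    "AMPLITUDE_LOW_PCT",
    "ChangeRate",
    "classify_temporal",
    "classify_spatial",
    "change_rate",
    "paired_table",
    "label_counts",
]

INERT_CUTOFF_HZ = 0.0249
AMPLITUDE_HIGH_PCT = 5.0
AMPLITUDE_LOW_PCT = 1.0


@dataclass(frozen=True)
class ChangeRate:
    """Post/pre normalization: ``ratio_pct = 100 * post / pre``."""

    ratio_pct: float
    signed_pct: float  # 100 * (post - pre) / pre = ratio_pct - 100


def classify_temporal(
    index: OscillationIndex, inert_cutoff_hz: float = INERT_CUTOFF_HZ
) -> str:
    """``inert`` iff frequency is strictly below the cutoff, else ``active``."""
    return "inert" if index.frequency_hz < inert_cutoff_hz else "active"


def classify_spatial(
    index: OscillationIndex,
    high_pct: float = AMPLITUDE_HIGH_PCT,
    low_pct: float = AMPLITUDE_LOW_PCT,
) -> str:
    """Amplitude > high -> ``aberrant_high``; < low -> ``aberrant_low``.

    Both inequalities are strict, so boundary amplitudes are ``normal``.
    """
    if index.amplitude_pct > high_pct:
        return "aberrant_high"
    if index.amplitude_pct < low_pct:
        return "aberrant_low"
    return "normal"


def change_rate(pre: float, post: float) -> ChangeRate:
    """Normalize a post-ischemia value to its pre-ischemia baseline."""
    if not pre > 0:
        raise ValueError(f"pre must be positive, got {pre}")
    ratio = 100.0 * post / pre
    return ChangeRate(ratio_pct=ratio, signed_pct=ratio - 100.0)


def _index_row(index: OscillationIndex, prefix: str) -> dict:
    return {
        f"{prefix}_frequency_hz": index.frequency_hz,
        f"{prefix}_amplitude_pct": index.amplitude_pct,
        f"{prefix}_peak_interval_sd_s": (
            np.nan if index.peak_interval_sd_s is None else index.peak_interval_sd_s
        ),
        f"{prefix}_n_events": index.n_events,
    }


def paired_table(
    pre_indices: dict,
    post_indices: dict,
    inert_cutoff_hz: float = INERT_CUTOFF_HZ,
    high_pct: float = AMPLITUDE_HIGH_PCT,
    low_pct: float = AMPLITUDE_LOW_PCT,
):
    """Strictly paired pre/post table with change rates and labels.

    ``pre_indices`` and ``post_indices`` map a (subject, vessel) key to
    an :class:`OscillationIndex`.  Only keys present in both are kept;
    the unmatched keys are returned alongside the table.  Duplicate keys
    cannot arise in a dict, but non-hashable or conflicting keys raise.

    Returns ``(table, excluded_keys)``.
    """
    pre_keys = list(pre_indices)
    if len(set(pre_keys)) != len(pre_keys) or len(set(post_indices)) != len(post_indices):
        raise ValueError("duplicate keys in index mapping")
    matched = [k for k in pre_keys if k in post_indices]
    excluded = sorted(
        (set(pre_keys) | set(post_indices)) - set(matched), key=str
    )
    rows = []
    for key in matched:
        pre, post = pre_indices[key], post_indices[key]
        row = {"key": key}
        row.update(_index_row(pre, "pre"))
        row.update(_index_row(post, "post"))
        for component in ("frequency_hz", "amplitude_pct"):
            pre_v = getattr(pre, component)
            post_v = getattr(post, component)
            if pre_v > 0:
                row[f"{component}_change_pct"] = change_rate(pre_v, post_v).ratio_pct
            else:
                row[f"{component}_change_pct"] = np.nan
        row["pre_temporal"] = classify_temporal(pre, inert_cutoff_hz)
        row["post_temporal"] = classify_temporal(post, inert_cutoff_hz)
        row["pre_spatial"] = classify_spatial(pre, high_pct, low_pct)
        row["post_spatial"] = classify_spatial(post, high_pct, low_pct)
        rows.append(row)
    table = pd.DataFrame(rows)
    return table, excluded


def label_counts(labels) -> dict:
    """Counts per label, as a plain dict (stable, sorted keys)."""
    series = pd.Series(list(labels), dtype=object)
    return {k: int(v) for k, v in sorted(series.value_counts().items())}
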