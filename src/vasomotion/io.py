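"""Readers and writers for the package's plain-text and TIFF formats.

Traces travel as CSV (``time_s,value[,flag]``), spectra and cooperation
profiles as CSV, specs and result summaries as JSON, and movies as
multi-page TIFF in TYX axis order.  All floating-point output is
formatted with ``repr``-level precision so that identical inputs give
byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .cooperation import CooperationProfile
from .images import FrameStack, LineScanKymograph
from .oscillation import OscillationIndex
from .spectral import PowerSpectrum
from .traces import TraceSeries

FLOAT_FORMAT = "%.12g"


# ---- traces ---------------------------------------------------------------


def write_trace_csv(trace: TraceSeries, path) -> None:
    df = pd.DataFrame(
        {"time_s": trace.times_s, "value": trace.values, "flag": trace.flags.astype(int)}
    )
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_trace_csv(path, kind: str = "radius") -> TraceSeries:
    df = pd.read_csv(path)
    value_col = next(
        (c for c in ("value", "value_um", "radius_um", "diameter_um") if c in df.columns),
        None,
    )
    if value_col is None or "time_s" not in df.columns:
        raise ValueError(f"{path}: need columns time_s and value")
    times = df["time_s"].to_numpy(dtype=float)
    interval = float(np.median(np.diff(times)))
    flags = df["flag"].to_numpy(dtype=bool) if "flag" in df.columns else None
    return TraceSeries(
        values=df[value_col].to_numpy(dtype=float),
        sampling_interval_s=interval,
        kind=kind,
        flags=flags,
    )


# ---- movies / kymographs --------------------------------------------------


def write_stack_tiff(stack: FrameStack, path) -> None:
    tifffile.imwrite(
        path,
        stack.data.astype(np.float32),
        metadata={
            "axes": "TYX",
            "frame_interval_s": stack.frame_interval_s,
            "pixel_size_um": stack.pixel_size_um,
        },
    )


def read_stack_tiff(path, frame_interval_s=None, pixel_size_um=None) -> FrameStack:
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    if data.ndim == 2:
        data = data[None]
    return FrameStack(
        data=data.astype(float),
        frame_interval_s=frame_interval_s or meta.get("frame_interval_s", 1.0),
        pixel_size_um=pixel_size_um or meta.get("pixel_size_um", 1.0),
    )


def write_linescan_tiff(kymo: LineScanKymograph, path) -> None:
    tifffile.imwrite(
        path,
        kymo.data.astype(np.float32),
        metadata={
            "axes": "YX",
            "line_period_s": kymo.line_period_s,
            "pixel_size_um": kymo.pixel_size_um,
            "polarity": kymo.polarity,
        },
    )


def read_linescan_tiff(path, line_period_s=None, pixel_size_um=None) -> LineScanKymograph:
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    return LineScanKymograph(
        data=data.astype(float),
        line_period_s=line_period_s or meta.get("line_period_s", 1.0),
        pixel_size_um=pixel_size_um or meta.get("pixel_size_um", 1.0),
        polarity=meta.get("polarity", "dark"),
    )


# ---- results --------------------------------------------------------------


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True) + "\n")


def write_index_csv(index: OscillationIndex, path) -> None:
    df = pd.DataFrame(
        [
            {
                "frequency_hz": index.frequency_hz,
                "amplitude_pct": index.amplitude_pct,
                "peak_interval_sd_s": (
                    np.nan if index.peak_interval_sd_s is None else index.peak_interval_sd_s
                ),
                "n_events": index.n_events,
                "duration_s": index.duration_s,
            }
        ]
    )
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_spectrum_csv(spectrum: PowerSpectrum, path) -> None:
    pd.DataFrame(
        {"frequency_hz": spectrum.frequencies_hz, "psd": spectrum.psd}
    ).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_profile_csv(profile: CooperationProfile, path) -> None:
    pd.DataFrame(
        {"offset_um": profile.offsets_um, "r": profile.r_values}
    ).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_matrix_csv(matrix: np.ndarray, offsets_um: np.ndarray, path) -> None:
    labels = [f"{o:+.1f}" for o in offsets_um]
    pd.DataFrame(matrix, index=labels, columns=labels).to_csv(
        path, float_format=FLOAT_FORMAT
    )


def read_path_csv(path) -> np.ndarray:
    """Reslice path from CSV with columns x,y (col, row) per point."""
    df = pd.read_csv(path)
    if not {"x", "y"} <= set(df.columns):
        raise ValueError(f"{path}: need columns x and y")
    return np.column_stack((df["y"].to_numpy(float), df["x"].to_numpy(float)))


def read_streaks_csv(path) -> list:
    """Streak annotations: columns streak_id,line0,px0,line1,px1."""
    df = pd.read_csv(path)
    needed = {"line0", "px0", "line1", "px1"}
    if not needed <= set(df.columns):
        raise ValueError(f"{path}: need columns {sorted(needed)}")
    return [
        ((row.line0, row.px0), (row.line1, row.px1)) for row in df.itertuples()
    ]
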