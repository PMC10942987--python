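"""Power spectral density of index traces and low-frequency band power.

Spontaneous vasomotion concentrates its power below ~0.3 Hz with a peak
near 0.1 Hz; the analysis therefore reduces a trace to a one-sided
periodogram, the accumulated power (AUC) over 0-0.3 Hz, and the location
of the in-band peak.

The default is a plain periodogram (rectangular window, mean detrend),
normalised as a density so that the integral of the PSD over frequency
equals the variance of the (windowed, detrended) signal; a Hann taper is
available for leakage control.  Absolute units depend on acquisition
settings, so only relative comparisons (e.g. pre- vs post-ischemia AUC)
are meaningful across datasets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import periodogram

from .errors import TraceTooShortError
from .traces import TraceSeries

__all__ = ["PowerSpectrum", "power_spectrum", "band_power_auc", "spectral_peak"]

_MIN_SAMPLES = 20


@dataclass
class PowerSpectrum:
    """One-sided periodogram on the grid 0 .. Nyquist."""

    frequencies_hz: np.ndarray
    psd: np.ndarray
    n_samples: int
    sampling_interval_s: float

    @property
    def nyquist_hz(self) -> float:
        return 0.5 / self.sampling_interval_s

    @property
    def df_hz(self) -> float:
        """Grid spacing, 1 / (N * dt)."""
        return 1.0 / (self.n_samples * self.sampling_interval_s)


def power_spectrum(
    trace: TraceSeries, detrend: str = "mean", window_fn: str = "rect"
) -> PowerSpectrum:
    """One-sided periodogram of a trace.

    ``detrend`` removes the mean or a linear trend before transforming;
    ``window_fn`` is ``rect`` (no taper) or ``hann``.
    """
    if len(trace) < _MIN_SAMPLES:
        raise TraceTooShortError(f"need >= {_MIN_SAMPLES} samples, got {len(trace)}")
    if detrend not in ("mean", "linear"):
        raise ValueError("detrend must be 'mean' or 'linear'")
    if window_fn not in ("rect", "hann"):
        raise ValueError("window_fn must be 'rect' or 'hann'")
    freqs, psd = periodogram(
        trace.values,
        fs=1.0 / trace.sampling_interval_s,
        window="boxcar" if window_fn == "rect" else "hann",
        detrend="constant" if detrend == "mean" else "linear",
        scaling="density",
    )
    return PowerSpectrum(
        frequencies_hz=freqs,
        psd=psd,
        n_samples=len(trace),
        sampling_interval_s=trace.sampling_interval_s,
    )


def band_power_auc(
    spectrum: PowerSpectrum, f_lo: float = 0.0, f_hi: float = 0.3
) -> float:
    """Trapezoidal integral of the PSD over ``[f_lo, f_hi]``.

    Band edges falling between grid points are handled by linear
    interpolation of the PSD, so adjacent bands add exactly.
    """
    if not f_lo < f_hi:
        raise ValueError("f_lo must be < f_hi")
    nyq = spectrum.nyquist_hz
    if f_hi > nyq * (1 + 1e-12):
        raise ValueError(f"f_hi = {f_hi} Hz exceeds Nyquist ({nyq:.4g} Hz)")
    f = spectrum.frequencies_hz
    inside = (f > f_lo) & (f < f_hi)
    grid = np.concatenate(([f_lo], f[inside], [f_hi]))
    values = np.interp(grid, f, spectrum.psd)
    return float(np.trapezoid(values, grid))


def spectral_peak(
    spectrum: PowerSpectrum, band: tuple = (0.0, 0.3)
) -> tuple:
    """(frequency, PSD value) of the maximum PSD bin inside ``band``.

    Band limits are inclusive; the earliest bin wins on ties.
    """
    f_lo, f_hi = band
    mask = (spectrum.frequencies_hz >= f_lo) & (spectrum.frequencies_hz <= f_hi)
    if not mask.any():
        raise ValueError(f"band {band} contains no frequency bins")
    idx = np.flatnonzero(mask)
    best = idx[int(np.argmax(spectrum.psd[idx]))]  # argmax -> earliest tie
    return float(spectrum.frequencies_hz[best]), float(spectrum.psd[best])
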