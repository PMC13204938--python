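"""Spectral readouts of simulated activity and learning-curve extraction."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import FlatSignalError, ParameterError

DEFAULT_BAND = (1.0, 100.0)

# variance below this is treated as a flat (non-oscillating) signal
_FLAT_VARIANCE = 1e-18


@dataclass(frozen=True)
class SpectralEstimate:
    """Single-taper periodogram restricted to an analysis band."""

    frequencies: np.ndarray  # Hz
    power: np.ndarray
    dominant: float  # Hz
    band: tuple[float, float]


def power_spectrum(
    x: np.ndarray,
    fs: float,
    band: tuple[float, float] = DEFAULT_BAND,
    resolution: float = 1.0,
) -> SpectralEstimate:
    """Detrended, Hann-tapered periodogram with grid resolution <= ``resolution`` Hz.

    The signal is zero-padded as needed to reach the requested frequency
    resolution.  Raises :class:`FlatSignalError` for (near-)constant input
    and :class:`ParameterError` when the window is too short for the band's
    lower edge or the sampling rate cannot resolve its upper edge.
    """
    x = np.asarray(x, dtype=float)
    lo, hi = band
    if lo <= 0 or hi <= lo:
        raise ParameterError(f"invalid band {band}")
    if fs <= 2 * hi:
        raise ParameterError(f"sampling rate {fs} Hz cannot resolve band up to {hi} Hz")
    # frequencies with fewer than two observed cycles are not trustworthy:
    # raise the band's effective lower edge accordingly
    lo = max(lo, 2.0 * fs / len(x))
    if hi <= lo:
        raise ParameterError(
            f"signal of {len(x)} samples is shorter than two cycles anywhere in {band} Hz"
        )
    if np.var(x) < _FLAT_VARIANCE:
        raise FlatSignalError("flat signal: dominant frequency undefined")

    nfft = int(2 ** np.ceil(np.log2(max(len(x), fs / resolution))))
    freqs, power = sps.periodogram(
        x, fs=fs, window="hann", nfft=nfft, detrend="constant"
    )
    mask = (freqs >= lo) & (freqs <= hi)
    freqs, power = freqs[mask], power[mask]
    dominant = float(freqs[np.argmax(power)])
    return SpectralEstimate(frequencies=freqs, power=power, dominant=dominant, band=band)


def dominant_frequency(
    x: np.ndarray, fs: float, band: tuple[float, float] = DEFAULT_BAND
) -> float:
    """Frequency (Hz) of the periodogram peak inside ``band``."""
    return power_spectrum(x, fs, band).dominant


def band_power(x: np.ndarray, fs: float, band: tuple[float, float] = DEFAULT_BAND) -> float:
    """Total periodogram power inside ``band`` (0.0 for a flat signal)."""
    try:
        est = power_spectrum(x, fs, band)
    except FlatSignalError:
        return 0.0
    return float(np.trapezoid(est.power, est.frequencies))


def learning_curve(result, fieldname: str) -> np.ndarray:
    """Per-trial series of a scalar :class:`~trustdyn.session.TrialRecord` field.

    Returns an array of shape (T,) for scalar fields, or (T, k) for vector
    fields (for example the per-option value vectors).
    """
    records = result.records
    if records and not hasattr(records[0], fieldname):
        raise KeyError(f"unknown TrialRecord field {fieldname!r}")
    return np.asarray([getattr(rec, fieldname) for rec in records])
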