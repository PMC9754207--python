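"""Prefiltering for abdominal ECG: band-pass, z-scoring, resampling.

The band-pass keeps 0.5-100 Hz: the low edge removes baseline wander while
preserving fetal T-waves, the high edge removes EMG/high-frequency content.
A 4th-order Butterworth applied forward-backward (zero phase) is used so
that waveform morphology is not phase-distorted; 3 s of reflect padding
suppresses edge transients on minute-long records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps


@dataclass
class FilterSpec:
    f_low: float = 0.5
    f_high: float = 100.0
    order: int = 4
    zero_phase: bool = True

    def validate(self, fs: float) -> None:
        if not (0 < self.f_low < self.f_high):
            raise ValueError("need 0 < f_low < f_high")
        if self.f_high >= fs / 2:
            raise ValueError(f"f_high={self.f_high} must be below Nyquist {fs / 2}")


def bandpass_filter(x: np.ndarray, fs: float, spec: FilterSpec = None) -> np.ndarray:
    """Band-pass one signal, preserving length and (by default) phase."""
    spec = spec or FilterSpec()
    spec.validate(fs)
    x = np.asarray(x, dtype=float)
    sos = sps.butter(spec.order, [spec.f_low, spec.f_high], btype="bandpass", fs=fs, output="sos")
    pad = min(int(round(3.0 * fs)), x.size - 1)
    if spec.zero_phase:
        return sps.sosfiltfilt(sos, x, padtype="even", padlen=pad)
    xp = np.concatenate([x[pad:0:-1], x, x[-2:-pad - 2:-1]]) if pad > 0 else x
    y = sps.sosfilt(sos, xp)
    return y[pad:pad + x.size]


def zscore_normalize(x: np.ndarray) -> np.ndarray:
    """Center and scale to unit standard deviation (population convention).

    A constant signal cannot be scaled; it is returned as zeros with a
    warning rather than raising, since flat leads occur in practice.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    sd = x.std()
    if sd == 0:
        warnings.warn("constant signal: z-score undefined, returning zeros", stacklevel=2)
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def preprocess_channel(x: np.ndarray, fs: float, spec: FilterSpec = None) -> np.ndarray:
    """Band-pass then z-score, the standard per-channel pipeline step."""
    return zscore_normalize(bandpass_filter(x, fs, spec))


def resample(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Band-limited rate conversion; output length round(n*fs_out/fs_in)."""
    if fs_in <= 0 or fs_out <= 0:
        raise ValueError("sampling rates must be positive")
    x = np.asarray(x, dtype=float)
    if fs_in == fs_out:
        return x.copy()
    from fractions import Fraction

    frac = Fraction(fs_out / fs_in).limit_denominator(1000)
    y = sps.resample_poly(x, frac.numerator, frac.denominator)
    n_out = int(round(x.size * fs_out / fs_in))
    if y.size > n_out:
        y = y[:n_out]
    elif y.size < n_out:
        y = np.pad(y, (0, n_out - y.size), mode="edge")
    return y
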