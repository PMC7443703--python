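"""Preprocessing and spectral estimation shared by all pipeline stages.

Welch power spectral densities are computed with 4 s Hamming windows and 50%
overlap (one-sided, density scaling, T^2/Hz).  Band summaries average the
log10 power over the bins of a band, which may be a union of intervals (the
movement band is 1-15 Hz excluding 11.5-12.5 Hz).  All "logarithmic power"
quantities in the package use base-10 logarithms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core import Recording

logger = logging.getLogger(__name__)


@dataclass
class SpectrumEstimate:
    """Per-channel Welch power spectral density."""

    freqs: np.ndarray            # Hz
    power: np.ndarray            # channels x freqs, T^2/Hz
    window_length: float         # s
    overlap: float               # fraction
    window_kind: str
    n_windows: int
    per_window_power: np.ndarray | None = None  # channels x freqs x windows

    def __post_init__(self):
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")
        df = np.diff(self.freqs)
        if np.any(df <= 0):
            raise ValueError("frequency axis must be strictly increasing")

    def copy_with_power(self, power, per_window_power=None) -> "SpectrumEstimate":
        return SpectrumEstimate(freqs=self.freqs, power=power,
                                window_length=self.window_length,
                                overlap=self.overlap, window_kind=self.window_kind,
                                n_windows=self.n_windows,
                                per_window_power=per_window_power)


@dataclass
class BandPowerSummary:
    """Per-channel averaged log10 power over a frequency band."""

    band: tuple                  # tuple of (lo, hi) Hz intervals
    pi: np.ndarray               # per-channel averaged log power
    n_channels: int

    def __post_init__(self):
        if not np.all(np.isfinite(self.pi)):
            raise ValueError("band log power is not finite on all channels")


def _as_data_fs(rec, fs=None):
    if isinstance(rec, Recording):
        return rec.data, rec.fs
    data = np.atleast_2d(np.asarray(rec, dtype=float))
    if fs is None:
        raise ValueError("fs must be given when passing a bare array")
    return data, fs


def notch_waveform(x: np.ndarray, fs: float, freqs, q: float = 35.0) -> np.ndarray:
    """Zero-phase IIR notch(es) applied to a 1-D or 2-D (channels x samples)
    array.  Frequencies at or above Nyquist are skipped with a log message."""
    x = np.asarray(x, dtype=float)
    freqs = np.atleast_1d(freqs)
    nyq = fs / 2.0
    for f0 in freqs:
        if f0 >= nyq:
            logger.info("skipping notch at %.1f Hz (>= Nyquist %.1f Hz)", f0, nyq)
            continue
        b, a = signal.iirnotch(f0, q, fs=fs)
        x = signal.filtfilt(b, a, x, axis=-1)
    return x


def notch_filter(rec: Recording, base: float = 50.0, max_harmonic: float = 550.0,
                 q: float = 35.0) -> Recording:
    """Zero-phase notches at ``base`` and its harmonics up to ``max_harmonic``.

    Harmonics at or above Nyquist are silently skipped (logged).  Attenuation
    at each notch centre exceeds 30 dB; the passband more than 1 Hz away from
    any notch is affected by less than 0.5 dB.
    """
    if base >= rec.fs / 2.0:
        raise ValueError("base frequency must be below Nyquist")
    freqs = np.arange(base, max_harmonic + 1e-9, base)
    data = notch_waveform(rec.data, rec.fs, freqs, q=q)
    return rec.copy_with(data)


def downsample(rec: Recording, fs_new: float) -> Recording:
    """Anti-alias filtered polyphase decimation to ``fs_new``.

    The decimation factor must be an integer; the output has
    ``floor(n * fs_new / fs)`` samples.
    """
    ratio = rec.fs / fs_new
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(f"sampling-rate ratio {ratio:.4f} is not an integer")
    q = int(round(ratio))
    if q == 1:
        return rec.copy_with(rec.data.copy())
    out = signal.resample_poly(rec.data, 1, q, axis=-1)
    n_out = int(np.floor(rec.n_samples * fs_new / rec.fs))
    out = out[:, :n_out]
    return Recording(data=out, fs=fs_new, sensors=rec.sensors,
                     condition=rec.condition, t0=rec.t0)


def welch_psd(rec, fs: float | None = None, window_length: float = 4.0,
              overlap: float = 0.5, window: str = "hamming",
              keep_windows: bool = False) -> SpectrumEstimate:
    """Welch power spectral density (default: 4 s Hamming windows, 50% overlap).

    Implemented by explicit framing so that the per-window power estimates
    (needed by the source-level bootstrap) are exactly the terms averaged
    into the PSD.  One-sided density scaling; windows are not detrended.
    """
    data, fs = _as_data_fs(rec, fs)
    nper = int(round(window_length * fs))
    if data.shape[1] < nper:
        raise ValueError("recording shorter than one analysis window")
    hop = int(round(nper * (1.0 - overlap)))
    win = signal.get_window(window, nper, fftbins=True)
    frames = np.lib.stride_tricks.sliding_window_view(data, nper, axis=1)[:, ::hop, :]
    n_win = frames.shape[1]
    scale = 1.0 / (fs * np.sum(win**2))
    spec = np.fft.rfft(frames * win, axis=-1)
    pw = (spec.real**2 + spec.imag**2) * scale
    pw[..., 1:] *= 2.0
    if nper % 2 == 0:
        pw[..., -1] /= 2.0
    power = pw.mean(axis=1)
    freqs = np.fft.rfftfreq(nper, 1.0 / fs)
    return SpectrumEstimate(
        freqs=freqs, power=power, window_length=window_length, overlap=overlap,
        window_kind=window, n_windows=n_win,
        per_window_power=np.moveaxis(pw, 1, 2) if keep_windows else None)


def band_mask(freqs: np.ndarray, band) -> np.ndarray:
    """Boolean mask of the bins belonging to a band (interval or union)."""
    intervals = band if hasattr(band[0], "__len__") else (band,)
    mask = np.zeros(freqs.shape, dtype=bool)
    for lo, hi in intervals:
        mask |= (freqs >= lo) & (freqs <= hi)
    return mask


def band_log_power(spec: SpectrumEstimate, band) -> BandPowerSummary:
    """Per-channel mean of log10 power over the bins of ``band``.

    ``band`` is an (lo, hi) pair or a sequence of pairs (a union of
    intervals).  Raises if the band covers no bins or any in-band power is
    non-positive.
    """
    mask = band_mask(spec.freqs, band)
    if not mask.any():
        raise ValueError(f"band {band} overlaps no frequency bins")
    p = spec.power[:, mask]
    if np.any(p <= 0):
        raise ValueError("non-positive power inside the band; log power undefined")
    intervals = band if hasattr(band[0], "__len__") else (band,)
    return BandPowerSummary(band=tuple(tuple(b) for b in intervals),
                            pi=np.mean(np.log10(p), axis=1),
                            n_channels=spec.power.shape[0])
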