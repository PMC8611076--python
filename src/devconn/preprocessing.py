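"""Phase-preserving filtering, band splitting, downsampling and RMS envelopes.

All filters are Butterworth designs applied forward and backward
(:func:`scipy.signal.sosfiltfilt`), which cancels the group delay exactly at
the price of doubling the effective order.  Edges are handled by reflect
padding of three filter lengths to suppress onset transients.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .data_model import Recording, ValidationError

__all__ = ["bandpass", "lowpass", "highpass", "make_lfp", "mua_band", "rms_envelope"]


def _apply_sos(x: np.ndarray, sos: np.ndarray) -> np.ndarray:
    ntaps = 2 * sos.shape[0] + 1
    padlen = min(3 * ntaps, x.shape[-1] - 1)
    return sps.sosfiltfilt(sos, x, axis=-1, padlen=padlen)


def _filter(obj, sos):
    if isinstance(obj, Recording):
        return Recording(
            signal=_apply_sos(obj.signal, sos), fs=obj.fs,
            channels=list(obj.channels), t0=obj.t0,
        )
    return _apply_sos(np.asarray(obj, dtype=float), sos)


def _fs_of(obj, fs):
    if isinstance(obj, Recording):
        return obj.fs
    if fs is None:
        raise ValueError("fs is required when filtering a bare array")
    return float(fs)


def bandpass(obj, low: float, high: float, order: int = 3, fs: float | None = None):
    """Zero-phase Butterworth band-pass between ``low`` and ``high`` Hz."""
    fs = _fs_of(obj, fs)
    if not (0 < low < high < fs / 2):
        raise ValidationError(
            f"band edges must satisfy 0 < low < high < fs/2, got ({low}, {high}) at fs={fs}"
        )
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return _filter(obj, sos)


def lowpass(obj, cutoff: float, order: int = 3, fs: float | None = None):
    fs = _fs_of(obj, fs)
    if not (0 < cutoff < fs / 2):
        raise ValidationError(f"cutoff must lie in (0, fs/2), got {cutoff} at fs={fs}")
    sos = sps.butter(order, cutoff, btype="lowpass", fs=fs, output="sos")
    return _filter(obj, sos)


def highpass(obj, cutoff: float, order: int = 3, fs: float | None = None):
    fs = _fs_of(obj, fs)
    if not (0 < cutoff < fs / 2):
        raise ValidationError(f"cutoff must lie in (0, fs/2), got {cutoff} at fs={fs}")
    sos = sps.butter(order, cutoff, btype="highpass", fs=fs, output="sos")
    return _filter(obj, sos)


def make_lfp(
    rec: Recording,
    target_fs: float = 1000.0,
    cutoff: float = 1500.0,
    order: int = 3,
    extra_antialias: bool = True,
    antialias_cutoff: float = 400.0,
) -> Recording:
    """Low-pass the wide-band signal and resample it to the LFP rate.

    The primary stage is a third-order zero-phase Butterworth low-pass below
    ``cutoff`` (1500 Hz).  Because that cutoff exceeds the post-resampling
    Nyquist frequency, a second, stricter anti-alias low-pass (default 400 Hz,
    switchable off via ``extra_antialias``) is applied before resampling.
    """
    if rec.fs < 2 * target_fs:
        raise ValidationError(
            f"input rate {rec.fs} Hz is below twice the target rate {target_fs} Hz"
        )
    x = rec.signal
    if cutoff < rec.fs / 2:
        x = _apply_sos(x, sps.butter(order, cutoff, btype="lowpass",
                                     fs=rec.fs, output="sos"))
    if extra_antialias and antialias_cutoff < target_fs / 2:
        x = _apply_sos(x, sps.butter(order, antialias_cutoff, btype="lowpass",
                                     fs=rec.fs, output="sos"))
    frac = Fraction(target_fs / rec.fs).limit_denominator(10000)
    y = sps.resample_poly(x, frac.numerator, frac.denominator, axis=-1)
    return Recording(signal=y, fs=target_fs, channels=list(rec.channels), t0=rec.t0)


def mua_band(rec: Recording, low: float = 500.0, high: float = 5000.0,
             order: int = 3) -> Recording:
    """Band-pass (500-5000 Hz) used for multi-unit spike detection."""
    if rec.fs <= 2 * high:
        raise ValidationError(
            f"MUA band needs fs > {2 * high} Hz, got {rec.fs}"
        )
    return bandpass(rec, low, high, order=order)


def rms_envelope(
    x: np.ndarray,
    fs: float,
    window: float = 0.2,
    step: float = 0.01,
    t0: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window root-mean-square of a 1-D signal.

    Returns ``(times, rms)`` where times are the window centers.  Defaults
    (200 ms window, 10 ms step) resolve events of one second and longer with
    dozens of samples.
    """
    if not (0 < step <= window):
        raise ValidationError("need window >= step > 0")
    x = np.asarray(x, dtype=float)
    n_win = max(1, int(round(window * fs)))
    n_step = max(1, int(round(step * fs)))
    if len(x) < n_win:
        raise ValidationError("signal shorter than one RMS window")
    csum = np.concatenate(([0.0], np.cumsum(x * x)))
    starts = np.arange(0, len(x) - n_win + 1, n_step)
    ms = (csum[starts + n_win] - csum[starts]) / n_win
    times = t0 + (starts + n_win / 2) / fs
    return times, np.sqrt(np.maximum(ms, 0.0))
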