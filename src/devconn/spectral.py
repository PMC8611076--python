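"""Power spectral density of oscillatory epochs and time-frequency maps.

Event-based PSDs follow the neonatal convention: every detected event is
tiled into non-overlapping one-second segments and the power is the Welch
average over all segments (Hamming taper, 1 Hz resolution).  Baseline power
``P0(f)`` uses the same estimator on inter-event stretches, and relative
power is the ratio ``P/P0``.  Continuous (pre-juvenile) recordings are
tiled over the whole trace instead.
"""

from __future__ import annotations

import warnings

import numpy as np
import pywt
from scipy import signal as sps

from .data_model import EventTable, PowerSpectrum, Recording, ValidationError

__all__ = [
    "tile_intervals", "segments_from_events", "psd_segments", "psd_events",
    "psd_baseline", "psd_continuous", "psd_relative", "band_average",
    "morlet_tf", "complement_intervals",
]


def tile_intervals(intervals: np.ndarray, seg_len: float) -> np.ndarray:
    """Tile [start, stop) intervals into non-overlapping ``seg_len`` windows.

    Remainders shorter than ``seg_len`` are discarded (a 3.5 s event yields
    three 1 s segments).
    """
    out = []
    for start, stop in np.asarray(intervals, dtype=float).reshape(-1, 2):
        n = int(np.floor((stop - start) / seg_len + 1e-9))
        for i in range(n):
            out.append((start + i * seg_len, start + (i + 1) * seg_len))
    return np.array(out).reshape(-1, 2)


def complement_intervals(intervals: np.ndarray, span: tuple) -> np.ndarray:
    """Gaps between sorted, disjoint intervals within ``span``."""
    t0, t1 = span
    out = []
    prev = t0
    for start, stop in np.asarray(intervals, dtype=float).reshape(-1, 2):
        if start > prev:
            out.append((prev, start))
        prev = max(prev, stop)
    if t1 > prev:
        out.append((prev, t1))
    return np.array(out).reshape(-1, 2)


def _slice(rec: Recording, channel: int, start: float, stop: float) -> np.ndarray:
    i0 = int(round((start - rec.t0) * rec.fs))
    i1 = int(round((stop - rec.t0) * rec.fs))
    return rec.signal[channel, max(i0, 0):min(i1, rec.n_samples)]


def segments_from_events(rec: Recording, events: EventTable, channel: int,
                         seg_len: float = 1.0) -> np.ndarray:
    """Stack of fixed-length signal segments tiled from event intervals."""
    tiles = tile_intervals(events.intervals(channel), seg_len)
    n_seg = int(round(seg_len * rec.fs))
    segs = [s for s in (_slice(rec, channel, a, b) for a, b in tiles)
            if len(s) == n_seg]
    return np.array(segs).reshape(-1, n_seg)


def psd_segments(segments: np.ndarray, fs: float,
                 window: str = "hamming") -> PowerSpectrum:
    """Welch PSD: mean tapered periodogram over non-overlapping segments."""
    segments = np.atleast_2d(np.asarray(segments, dtype=float))
    if segments.size == 0:
        raise ValidationError("no usable segments")
    freqs, p = sps.periodogram(segments, fs=fs, window=window,
                               detrend=False, axis=-1)
    return PowerSpectrum(freqs=freqs, power=p.mean(axis=0),
                         n_segments=segments.shape[0])


def psd_events(rec: Recording, events: EventTable, channel: int,
               seg_len: float = 1.0, window: str = "hamming") -> PowerSpectrum:
    """PSD of oscillatory activity: events tiled into 1 s Welch segments."""
    segs = segments_from_events(rec, events, channel, seg_len)
    if segs.shape[0] == 0:
        raise ValidationError(
            f"channel {channel}: no event segment of length {seg_len} s")
    return psd_segments(segs, rec.fs, window)


def psd_baseline(rec: Recording, events: EventTable, channel: int,
                 seg_len: float = 1.0, min_segments: int = 10,
                 window: str = "hamming") -> PowerSpectrum:
    """Baseline PSD ``P0(f)`` from inter-event stretches of >= ``seg_len``."""
    gaps = complement_intervals(events.intervals(channel),
                                (rec.t0, rec.t0 + rec.duration))
    tiles = tile_intervals(gaps, seg_len)
    n_seg = int(round(seg_len * rec.fs))
    segs = [s for s in (_slice(rec, channel, a, b) for a, b in tiles)
            if len(s) == n_seg]
    if not segs:
        raise ValidationError("no baseline segments outside events")
    if len(segs) < min_segments:
        warnings.warn(f"only {len(segs)} baseline segments (< {min_segments})")
    return psd_segments(np.array(segs), rec.fs, window)


def psd_continuous(rec: Recording, channel: int, seg_len: float = 1.0,
                   window: str = "hamming") -> PowerSpectrum:
    """Welch PSD over the entire trace (continuous oscillatory activity)."""
    n_seg = int(round(seg_len * rec.fs))
    n = (rec.n_samples // n_seg) * n_seg
    if n == 0:
        raise ValidationError("recording shorter than one segment")
    segs = rec.signal[channel, :n].reshape(-1, n_seg)
    return psd_segments(segs, rec.fs, window)


def psd_relative(p: PowerSpectrum, p0: PowerSpectrum) -> PowerSpectrum:
    """Event power normalized to the baseline power ``P(f)/P0(f)``."""
    if p.freqs.shape != p0.freqs.shape or not np.allclose(p.freqs, p0.freqs):
        raise ValidationError("frequency grids of P and P0 differ")
    if (p0.power <= 0).any():
        raise ValidationError("baseline power contains zeros")
    return PowerSpectrum(freqs=p.freqs, power=p.power / p0.power,
                         baseline=p0.power, normalized=True,
                         n_segments=p.n_segments)


def band_average(spectrum, f_lo: float, f_hi: float, values=None) -> float:
    """Arithmetic mean of spectral values over ``f_lo <= f <= f_hi`` inclusive.

    ``spectrum`` may be a PowerSpectrum/CoherenceSpectrum-like object (its
    ``power``/``coherence`` attribute is used) or a frequency array paired
    with an explicit ``values`` array.
    """
    if values is None:
        freqs = spectrum.freqs
        values = getattr(spectrum, "power", None)
        if values is None:
            values = spectrum.coherence
    else:
        freqs = np.asarray(spectrum, dtype=float)
    values = np.asarray(values, dtype=float)
    mask = (freqs >= f_lo) & (freqs <= f_hi)
    if not mask.any():
        raise ValidationError(
            f"band [{f_lo}, {f_hi}] Hz contains no grid point")
    return float(values[..., mask].mean(axis=-1))


def morlet_tf(x: np.ndarray, fs: float, freqs: np.ndarray,
              w0: float = 6.0) -> np.ndarray:
    """Morlet continuous-wavelet magnitude, shape (n_freqs, n_samples).

    Uses the complex Morlet with center-frequency parameter ``w0`` (default
    6), i.e. center frequency ``w0 / (2*pi)`` cycles per unit scale.
    """
    x = np.asarray(x, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    if ((freqs <= 0) | (freqs >= fs / 2)).any():
        raise ValidationError("wavelet frequencies must lie in (0, fs/2)")
    fc = w0 / (2 * np.pi)
    scales = fc * fs / freqs
    coeffs, _ = pywt.cwt(x, scales, f"cmor1.0-{fc:.6f}", sampling_period=1.0 / fs)
    return np.abs(coeffs)
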