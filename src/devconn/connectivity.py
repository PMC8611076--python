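"""Coherence, imaginary coherence with shuffled null, MVAR fitting and gPDC.

Synchrony between two regions is quantified by the magnitude coherence

    C_XY(f) = | P_XY(f) / sqrt(P_XX(f) P_YY(f)) |

estimated over co-occurring one-second oscillatory epochs, and by the
magnitude of the imaginary part of the complex coherency, which is blind to
instantaneous (volume-conducted) coupling.  A surrogate null is obtained by
permuting the epoch pairing between the two signals (derangements).

Directed interactions come from generalized partial directed coherence
(gPDC): with the MVAR transfer polynomial

    Abar(f) = I - sum_r A_r exp(-2*pi*i*f*r / fs_model)

the influence of source j on target i is

    gPDC_{i<-j}(f) = (|Abar_ij(f)| / s_i) / sqrt(sum_k |Abar_kj(f)|^2 / s_k^2)

where ``s_i`` is the innovation standard deviation of channel i.  For every
source j and frequency the squared values sum to one over targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .data_model import (
    CoherenceSpectrum, DirectedSpectrum, EventTable, MVARModel, Recording,
    ValidationError,
)
from .preprocessing import bandpass, lowpass
from .spectral import band_average, tile_intervals

__all__ = [
    "CrossSpectra", "cross_spectra", "coherence", "shuffle_null",
    "fit_mvar", "gpdc", "gpdc_pipeline", "extract_epochs",
    "intersect_intervals", "InsufficientDataError",
]


class InsufficientDataError(ValidationError):
    """Too few samples for the requested model order."""


# ---------------------------------------------------------------------------
# epoch handling


def intersect_intervals(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Intersection of two sorted disjoint interval sets."""
    out = []
    i = j = 0
    a = np.asarray(a, dtype=float).reshape(-1, 2)
    b = np.asarray(b, dtype=float).reshape(-1, 2)
    while i < len(a) and j < len(b):
        lo = max(a[i, 0], b[j, 0])
        hi = min(a[i, 1], b[j, 1])
        if hi > lo:
            out.append((lo, hi))
        if a[i, 1] < b[j, 1]:
            i += 1
        else:
            j += 1
    return np.array(out).reshape(-1, 2)


def extract_epochs(rec: Recording, events: EventTable, channels,
                   seg_len: float = 1.0) -> np.ndarray:
    """Co-occurring oscillatory epochs across ``channels``.

    Event intervals of the selected channels are intersected; stretches in
    which all channels oscillate simultaneously for at least ``seg_len`` are
    tiled into epochs.  Returns shape ``(n_epochs, n_channels, n_samples)``.
    """
    channels = list(channels)
    common = events.intervals(channels[0])
    for ch in channels[1:]:
        common = intersect_intervals(common, events.intervals(ch))
    tiles = tile_intervals(common, seg_len)
    n_seg = int(round(seg_len * rec.fs))
    epochs = []
    for start, stop in tiles:
        i0 = int(round((start - rec.t0) * rec.fs))
        seg = rec.signal[np.asarray(channels), i0:i0 + n_seg]
        if seg.shape[1] == n_seg:
            epochs.append(seg)
    return np.array(epochs).reshape(-1, len(channels), n_seg)


# ---------------------------------------------------------------------------
# cross spectra and coherence


@dataclass
class CrossSpectra:
    freqs: np.ndarray
    pxy: np.ndarray
    pxx: np.ndarray
    pyy: np.ndarray
    n_epochs: int


def _tapered_fft(epochs: np.ndarray, fs: float):
    n = epochs.shape[-1]
    w = sps.get_window("hamming", n)
    scale = 1.0 / (fs * (w * w).sum())
    return np.fft.rfftfreq(n, 1.0 / fs), np.fft.rfft(epochs * w, axis=-1), scale


def cross_spectra(x_epochs: np.ndarray, y_epochs: np.ndarray,
                  fs: float) -> CrossSpectra:
    """Welch cross- and auto-spectra averaged over paired epochs."""
    x_epochs = np.atleast_2d(x_epochs)
    y_epochs = np.atleast_2d(y_epochs)
    if x_epochs.shape != y_epochs.shape:
        raise ValidationError("x and y epoch arrays must have equal shape")
    freqs, fx, scale = _tapered_fft(x_epochs, fs)
    _, fy, _ = _tapered_fft(y_epochs, fs)
    pxy = (fx * np.conj(fy)).mean(axis=0) * scale
    pxx = (np.abs(fx) ** 2).mean(axis=0) * scale
    pyy = (np.abs(fy) ** 2).mean(axis=0) * scale
    return CrossSpectra(freqs=freqs, pxy=pxy, pxx=pxx.real, pyy=pyy.real,
                        n_epochs=x_epochs.shape[0])


def coherence(cs: CrossSpectra) -> CoherenceSpectrum:
    """Magnitude coherence and |imaginary coherency| from cross-spectra."""
    if (cs.pxx <= 0).any() or (cs.pyy <= 0).any():
        raise ValidationError("zero auto-spectrum")
    coh = cs.pxy / np.sqrt(cs.pxx * cs.pyy)
    return CoherenceSpectrum(
        freqs=cs.freqs,
        coherence=np.minimum(np.abs(coh), 1.0),
        imag_coherence=np.abs(coh.imag),
    )


def _derangement(n: int, rng: np.random.Generator) -> np.ndarray:
    while True:
        p = rng.permutation(n)
        if not (p == np.arange(n)).any():
            return p


def shuffle_null(x_epochs: np.ndarray, y_epochs: np.ndarray,
                 n_shuffle: int = 100, rng=0) -> CoherenceSpectrum:
    """Surrogate coherence with epoch pairing destroyed.

    The y epochs are re-paired with the x epochs by random derangements and
    the coherence recomputed; the mean over ``n_shuffle`` permutations
    estimates the no-coupling floor of the estimator.
    """
    if n_shuffle < 1:
        raise ValidationError("n_shuffle must be >= 1")
    x_epochs = np.atleast_2d(x_epochs)
    y_epochs = np.atleast_2d(y_epochs)
    if x_epochs.shape[0] < 2:
        raise ValidationError("need at least 2 epochs to shuffle")
    rng = np.random.default_rng(rng)
    acc_c = acc_i = None
    for _ in range(n_shuffle):
        perm = _derangement(x_epochs.shape[0], rng)
        c = coherence(cross_spectra(x_epochs, y_epochs[perm], fs=1.0))
        if acc_c is None:
            acc_c, acc_i, freqs = c.coherence, c.imag_coherence, c.freqs
        else:
            acc_c = acc_c + c.coherence
            acc_i = acc_i + c.imag_coherence
    return CoherenceSpectrum(freqs=freqs, coherence=acc_c / n_shuffle,
                             imag_coherence=acc_i / n_shuffle)


# ---------------------------------------------------------------------------
# MVAR estimation


def _design(epochs: np.ndarray, p: int):
    """Pooled lagged regression matrices without crossing epoch boundaries."""
    ys, xs = [], []
    for ep in epochs:
        k, n = ep.shape
        if n <= p:
            continue
        ys.append(ep[:, p:].T)
        lags = [ep[:, p - r:n - r].T for r in range(1, p + 1)]
        xs.append(np.concatenate(lags, axis=1))
    if not ys:
        raise InsufficientDataError("no epoch longer than the model order")
    return np.concatenate(ys), np.concatenate(xs)


def fit_mvar(epochs, order: int | None = None, p_max: int = 20,
             fs_model: float = 100.0, min_samples_factor: int = 10) -> MVARModel:
    """Least-squares MVAR fit pooled across epochs.

    With ``order=None`` the order is selected by BIC over ``1..p_max``.  The
    fit requires at least ``min_samples_factor * k^2 * p`` pooled samples and
    the resulting model must be stable.
    """
    epochs = np.asarray(epochs, dtype=float)
    if epochs.ndim == 2:
        epochs = epochs[None, :, :]
    n_ep, k, n = epochs.shape
    if k < 2:
        raise ValidationError("MVAR needs at least 2 channels")
    epochs = epochs - epochs.mean(axis=-1, keepdims=True)
    total = n_ep * n

    def _fit(p: int):
        if total < min_samples_factor * k * k * p:
            raise InsufficientDataError(
                f"{total} samples insufficient for order {p} with k={k} "
                f"(need >= {min_samples_factor * k * k * p})")
        y, x = _design(epochs, p)
        b, *_ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ b
        nobs = y.shape[0]
        sigma_ml = resid.T @ resid / nobs
        sign, logdet = np.linalg.slogdet(sigma_ml + 1e-300 * np.eye(k))
        bic = nobs * logdet + np.log(nobs) * (k * k * p)
        return b, resid, nobs, bic

    if order is None:
        best = None
        for p in range(1, p_max + 1):
            try:
                cand = (p,) + _fit(p)
            except InsufficientDataError:
                break
            if best is None or cand[4] < best[4]:
                best = cand
        if best is None:
            raise InsufficientDataError("too few samples for any model order")
        p, b, resid, nobs, _ = best
    else:
        p = int(order)
        b, resid, nobs, _ = _fit(p)

    coeffs = np.array([b[r * k:(r + 1) * k, :].T for r in range(p)])
    dof = max(nobs - k * p, 1)
    sigma = resid.T @ resid / dof
    sigma = 0.5 * (sigma + sigma.T)
    model = MVARModel(coeffs=coeffs, sigma=sigma, fs_model=fs_model)
    if not model.is_stable():
        raise ValidationError(
            f"fitted MVAR(p={p}) is unstable "
            f"(spectral radius {model.spectral_radius():.3f})")
    return model


# ---------------------------------------------------------------------------
# gPDC


def gpdc(model: MVARModel, freqs: np.ndarray,
         labels: list[str] | None = None) -> DirectedSpectrum:
    """Generalized partial directed coherence of an MVAR model."""
    freqs = np.asarray(freqs, dtype=float)
    sigma_d = np.diag(model.sigma)
    if (sigma_d <= 0).any():
        raise ValidationError("innovation variances must all be positive")
    s = np.sqrt(sigma_d)
    p, k = model.order, model.k
    # Abar[f, i, j] = I - sum_r A_r exp(-2 pi i f r / fs)
    r = np.arange(1, p + 1)
    phase = np.exp(-2j * np.pi * freqs[:, None] * r[None, :] / model.fs_model)
    abar = np.eye(k)[None, :, :] - np.einsum("fr,rij->fij", phase, model.coeffs)
    num = np.abs(abar) / s[None, :, None]          # |Abar_ij| / s_i
    den = np.sqrt((num ** 2).sum(axis=1))          # per (f, j)
    values = np.moveaxis(num / den[:, None, :], 0, -1)
    return DirectedSpectrum(freqs=freqs, values=values, labels=labels)


def gpdc_pipeline(
    rec: Recording,
    events: EventTable,
    region_channels: dict | None = None,
    band: tuple = (4.0, 30.0),
    fs_model: float = 100.0,
    order: int | None = None,
    p_max: int = 12,
    prefilter: tuple | None = (1.0, 45.0),
    freqs: np.ndarray | None = None,
    seg_len: float = 1.0,
):
    """Directed coupling between regions, band-averaged per ordered pair.

    One channel per region is selected (``region_channels`` maps region ->
    signal row; by default the first channel of each region present), the
    recording is band-limited by a zero-phase Butterworth (``prefilter``),
    co-occurring one-second oscillatory epochs are extracted and decimated to
    ``fs_model``, an MVAR is fit, and gPDC is band-averaged over ``band``.

    Returns ``(DirectedSpectrum, DataFrame)`` with one row per ordered
    region pair (columns source, target, gpdc).
    """
    if region_channels is None:
        region_channels = {}
        for region in ("LEC", "HP", "PFC"):
            try:
                region_channels[region] = rec.region_channel(region)
            except KeyError:
                pass
    if len(region_channels) < 2:
        raise ValidationError("directed coupling needs at least 2 regions")
    labels = list(region_channels)
    chans = [region_channels[r] for r in labels]

    work = rec
    if prefilter is not None:
        lo, hi = prefilter
        if hi >= fs_model / 2:
            raise ValidationError(
                "prefilter upper edge must stay below the model Nyquist rate")
        sig = bandpass(rec.signal[chans], lo, hi, order=3, fs=rec.fs)
    else:
        sig = lowpass(rec.signal[chans], 0.45 * fs_model, order=6, fs=rec.fs)
    work = Recording(signal=sig, fs=rec.fs,
                     channels=[rec.channels[c] for c in chans], t0=rec.t0)

    # re-index events onto the extracted rows
    sub = events.df[events.df.channel.isin(chans)].copy()
    remap = {c: i for i, c in enumerate(chans)}
    sub["channel"] = sub.channel.map(remap)
    epochs = extract_epochs(work, EventTable(sub), list(range(len(chans))),
                            seg_len=seg_len)
    if epochs.shape[0] == 0:
        raise ValidationError("no co-occurring oscillatory epochs")

    stride = int(round(rec.fs / fs_model))
    epochs = epochs[:, :, ::stride]   # anti-aliased by the prefilter

    model = fit_mvar(epochs, order=order, p_max=p_max, fs_model=fs_model)
    if freqs is None:
        freqs = np.arange(1.0, np.floor(fs_model / 2))
    ds = gpdc(model, freqs, labels=labels)
    rows = []
    for j, src in enumerate(labels):
        for i, dst in enumerate(labels):
            if i == j:
                continue
            rows.append({
                "source": src, "target": dst,
                "gpdc": band_average(freqs, band[0], band[1],
                                     values=ds.values[i, j, :]),
            })
    return ds, pd.DataFrame(rows)
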