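"""Unsupervised detection of discontinuous oscillatory events and MUA spikes.

Oscillatory events are found per channel from the RMS envelope of the
3-100 Hz band: the histogram of RMS values is dominated by the
non-oscillatory background, whose body (bins up to the histogram mode) is fit
with a Gaussian; intervals where the envelope exceeds ``mu + k*sigma`` of
that fit, merged across brief dips and longer than one second, are reported
as network oscillations.

MUA spike times are negative deflections of the 500-5000 Hz band exceeding a
multiple of the channel's standard deviation.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import curve_fit

from .data_model import EventTable, Recording, SpikeSet, SpikeTrain, ValidationError
from .preprocessing import bandpass, rms_envelope

__all__ = [
    "detect_oscillations", "detect_mua", "occurrence_and_duration",
    "score_detection", "rms_threshold",
]


def _gauss(x, a, mu, sigma):
    return a * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def rms_threshold(env: np.ndarray, k: float = 2.5, n_bins: int = 100,
                  fit_to: str = "hist_peak") -> float:
    """Variance-dependent threshold from the RMS-value histogram.

    A Gaussian is fit by least squares to the histogram bins from 0 up to the
    mode (``fit_to="hist_peak"``; with ``"max_value"`` all bins up to the
    maximal RMS value are used) and the threshold is ``mu + k*sigma``.  If
    the fit is degenerate the robust fallback ``median + k*1.4826*MAD`` is
    used and a warning issued.
    """
    env = np.asarray(env, dtype=float)
    lo, hi = 0.0, float(env.max())
    if hi <= 0 or env.max() == env.min():
        raise ValidationError("degenerate (constant) envelope")
    counts, edges = np.histogram(env, bins=n_bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    mode = int(np.argmax(counts))
    sel = slice(0, len(centers)) if fit_to == "max_value" else slice(0, mode + 1)
    xs, ys = centers[sel], counts[sel].astype(float)
    try:
        if len(xs) < 3:
            raise RuntimeError("too few bins left of the mode")
        m_c = float(centers[mode])
        p0 = (float(ys.max()), m_c,
              float(min(max(env.std(), hi / n_bins), m_c)))
        # fitting only the body left of the mode under-constrains the
        # Gaussian; bound the center at the mode and the width at its value
        bounds = ([0.0, 0.0, hi / (2 * n_bins)],
                  [2.0 * float(ys.max()) + 1.0, m_c + hi / n_bins, max(m_c, hi / n_bins)])
        popt, _ = curve_fit(_gauss, xs, ys, p0=p0, bounds=bounds, maxfev=5000)
        mu, sigma = float(popt[1]), abs(float(popt[2]))
        if not np.isfinite(mu + sigma) or sigma <= 0:
            raise RuntimeError("non-finite fit")
    except (RuntimeError, ValueError):
        warnings.warn("Gaussian fit to the RMS histogram failed; "
                      "falling back to median + k*1.4826*MAD")
        med = float(np.median(env))
        mad = float(np.median(np.abs(env - med)))
        mu, sigma = med, 1.4826 * mad
    return mu + k * sigma


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(len(mask))
    return list(zip(starts, stops))


def detect_oscillations(
    rec: Recording,
    band: tuple = (3.0, 100.0),
    k: float = 2.5,
    min_duration: float = 1.0,
    merge_gap: float = 0.2,
    rms_window: float = 0.2,
    rms_step: float = 0.01,
    n_bins: int = 100,
    fit_to: str = "hist_peak",
    channels=None,
) -> EventTable:
    """Detect discontinuous oscillatory events per channel.

    Events shorter than ``min_duration`` (strictly, > 1 s by default) are
    discarded; supra-threshold intervals separated by less than ``merge_gap``
    are merged first so RMS dips inside one burst do not split it.
    """
    if rec.duration < 60.0:
        warnings.warn("recording shorter than 60 s; RMS histogram may be unstable")
    rows = {c: [] for c in ("channel", "start_s", "stop_s", "peak_rms_uv")}
    chans = range(rec.n_channels) if channels is None else channels
    for ch in chans:
        if np.ptp(rec.signal[ch]) == 0:
            warnings.warn(f"channel {ch}: constant signal, no events")
            continue
        xb = bandpass(rec.signal[ch], band[0], band[1], order=3, fs=rec.fs)
        times, env = rms_envelope(xb, rec.fs, window=rms_window,
                                  step=rms_step, t0=rec.t0)
        try:
            thr = rms_threshold(env, k=k, n_bins=n_bins, fit_to=fit_to)
        except ValidationError:
            warnings.warn(f"channel {ch}: constant signal, no events")
            continue
        runs = _runs_above(env > thr)
        if not runs:
            continue
        # envelope sample i covers [t_i - step/2, t_i + step/2)
        iv = np.array([
            [times[a] - rms_step / 2, times[b - 1] + rms_step / 2]
            for a, b in runs
        ])
        merged = [iv[0].tolist()]
        for s, e in iv[1:]:
            if s - merged[-1][1] < merge_gap:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        # the sliding RMS window smears each true edge outward by about half
        # a window; shrink the supra-threshold interval accordingly
        shrink = (rms_window - rms_step) / 2.0
        for s, e in merged:
            s, e = s + shrink, e - shrink
            if e - s > min_duration:
                m = (times >= s) & (times <= e)
                rows["channel"].append(ch)
                rows["start_s"].append(s)
                rows["stop_s"].append(e)
                rows["peak_rms_uv"].append(float(env[m].max()))
    if not rows["channel"]:
        return EventTable.empty()
    return EventTable.from_arrays(
        np.array(rows["channel"]), np.array(rows["start_s"]),
        np.array(rows["stop_s"]), np.array(rows["peak_rms_uv"]))


def detect_mua(
    rec: Recording,
    k_sd: float = 5.0,
    dead_time: float = 1e-3,
    robust: bool = False,
) -> SpikeSet:
    """Threshold-crossing MUA detection on the 500-5000 Hz band.

    A spike is the local minimum of each excursion below ``-k_sd`` times the
    channel's standard deviation (MAD-based if ``robust``); spikes closer
    than ``dead_time`` to the previous one are discarded.  Returns one
    multi-unit train per channel.
    """
    units = []
    for ch in range(rec.n_channels):
        x = rec.signal[ch]
        sd = (1.4826 * np.median(np.abs(x - np.median(x)))) if robust else x.std()
        if sd == 0:
            warnings.warn(f"channel {ch}: zero variance, empty MUA train")
            times = np.empty(0)
        else:
            thr = -k_sd * sd
            runs = _runs_above(x < thr)
            idx = np.array([a + int(np.argmin(x[a:b])) for a, b in runs], dtype=int)
            times = rec.t0 + idx / rec.fs
            if len(times) > 1:
                keep = [0]
                for i in range(1, len(times)):
                    if times[i] - times[keep[-1]] >= dead_time:
                        keep.append(i)
                times = times[keep]
        info = rec.channels[ch]
        units.append(SpikeTrain(
            unit_id=f"mua_ch{ch:02d}", region=info.region, layer=info.layer,
            times=times))
    return SpikeSet(units)


def occurrence_and_duration(events: EventTable, span_s: float) -> dict:
    """Event occurrence (events/min) and mean duration over a recording span."""
    if span_s <= 0:
        raise ValidationError("span must be positive")
    n = len(events)
    return {
        "n_events": n,
        "rate_per_min": 60.0 * n / span_s,
        "mean_duration_s": float(events.df.duration_s.mean()) if n else float("nan"),
    }


def _overlap(a: np.ndarray, b: np.ndarray) -> float:
    return max(0.0, min(a[1], b[1]) - max(a[0], b[0]))


def score_detection(detected: EventTable, truth: EventTable,
                    min_frac: float = 0.5) -> dict:
    """Precision/recall of detected against ground-truth intervals.

    A true event is recalled if some detected event covers at least
    ``min_frac`` of its duration; a detected event is a true positive if at
    least ``min_frac`` of it overlaps ground truth.  Channels are matched.
    """
    channels = sorted(set(detected.df.channel) | set(truth.df.channel))
    n_true = n_recalled = n_det = n_tp = 0
    for ch in channels:
        t_iv = truth.intervals(ch)
        d_iv = detected.intervals(ch)
        n_true += len(t_iv)
        n_det += len(d_iv)
        for tv in t_iv:
            cov = sum(_overlap(tv, dv) for dv in d_iv)
            if cov >= min_frac * (tv[1] - tv[0]):
                n_recalled += 1
        for dv in d_iv:
            cov = sum(_overlap(dv, tv) for tv in t_iv)
            if cov >= min_frac * (dv[1] - dv[0]):
                n_tp += 1
    return {
        "recall": n_recalled / n_true if n_true else float("nan"),
        "precision": n_tp / n_det if n_det else float("nan"),
        "n_true": n_true, "n_detected": n_det,
    }
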