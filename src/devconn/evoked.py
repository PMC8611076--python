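"""Quantification of light-evoked spiking and field responses.

Covers the optogenetic read-outs: per-unit firing probability (spikes in the
20 ms window after each pulse divided by the pulse count), peri-stimulus
time histograms, a modulation index with a paired permutation test that
classifies units as activated / inhibited / unchanged, stimulus-locked LFP
averages, laminar current source density, relative band-power and coherence
changes around ramp or train stimulation, and eEPSC feature extraction from
voltage-clamp sweeps.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .data_model import (
    EPSCFeatures, Recording, SpikeSet, StimProtocol, UnitResponse,
    ValidationError,
)
from .connectivity import coherence, cross_spectra
from .spectral import band_average, psd_segments

__all__ = [
    "firing_probability", "firing_rate", "psth", "modulation_index",
    "evoked_lfp", "csd", "ramp_power_change", "ramp_coherence_change",
    "eepsc_features",
]


def _counts_in_windows(times: np.ndarray, starts: np.ndarray,
                       width: float) -> np.ndarray:
    """Spike count inside each half-open window [start, start + width)."""
    lo = np.searchsorted(times, starts, side="left")
    hi = np.searchsorted(times, starts + width, side="left")
    return hi - lo


def firing_probability(spikes: SpikeSet, protocol: StimProtocol,
                       window: float = 0.020) -> dict:
    """Light-evoked firing probability per unit.

    Counts spikes (not pulses) in the ``window`` after every pulse onset and
    divides by the total pulse count.
    """
    pulses = protocol.pulse_times()
    if len(pulses) == 0:
        raise ValidationError("protocol contains no pulses")
    return {
        u.unit_id: float(_counts_in_windows(u.times, pulses, window).sum()
                         / len(pulses))
        for u in spikes
    }


def firing_rate(spikes: SpikeSet, window: tuple) -> dict:
    """Firing rate in Hz per unit over the [t0, t1) analysis window."""
    t0, t1 = window
    if t1 <= t0:
        raise ValidationError("analysis window must have positive duration")
    return {
        u.unit_id: float(_counts_in_windows(u.times, np.array([t0]),
                                            t1 - t0)[0] / (t1 - t0))
        for u in spikes
    }


def psth(spikes: SpikeSet, protocol: StimProtocol, bin_ms: float = 1.0,
         span_ms: tuple = (-10.0, 50.0)) -> tuple[np.ndarray, dict]:
    """Peri-stimulus spike-probability histogram per unit.

    Returns ``(bin_edges_ms, {unit_id: probability per bin})`` where each
    bin holds spikes per pulse, so bins covering [0, 20) ms sum to the
    firing probability.
    """
    pulses = protocol.pulse_times()
    if len(pulses) == 0:
        raise ValidationError("protocol contains no pulses")
    edges = np.arange(span_ms[0], span_ms[1] + bin_ms / 2, bin_ms)
    out = {}
    for u in spikes:
        rel = (u.times[None, :] - pulses[:, None]).ravel() * 1e3
        rel = rel[(rel >= edges[0]) & (rel < edges[-1])]
        counts, _ = np.histogram(rel, bins=edges)
        out[u.unit_id] = counts / len(pulses)
    return edges, out


def _perm_pvalue(pre: np.ndarray, during: np.ndarray, n_perm: int,
                 rng: np.random.Generator) -> float:
    """Paired permutation p-value for a rate difference.

    Shuffling the pre/during labels within each sweep is a random sign flip
    of the per-sweep difference; two-sided with the +1 correction.
    """
    d = during - pre
    obs = abs(d.mean())
    signs = rng.integers(0, 2, size=(n_perm, len(d))) * 2 - 1
    perm = np.abs(signs @ d) / len(d)
    return float((1 + (perm >= obs - 1e-12).sum()) / (1 + n_perm))


def modulation_index(
    spikes: SpikeSet,
    protocol: StimProtocol,
    pre_s: float = 3.0,
    during_s: float = 3.0,
    n_perm: int = 1000,
    alpha: float = 0.05,
    rng=0,
) -> dict:
    """Modulation index MI = (r_during - r_pre)/(r_during + r_pre) per unit.

    Per-sweep spike counts in the ``pre_s`` window before and the
    ``during_s`` window after each sweep onset are converted to rates; the
    unit is classified activated / inhibited / unchanged by a paired
    permutation test on the per-sweep rates (two-sided ``alpha``).  With
    fewer than five sweeps the class is undefined (``None``).
    """
    rng = np.random.default_rng(rng)
    onsets = protocol.sweep_onsets
    if len(onsets) == 0:
        raise ValidationError("protocol has no sweeps")
    out = {}
    for u in spikes:
        c_pre = _counts_in_windows(u.times, onsets - pre_s, pre_s) / pre_s
        c_dur = _counts_in_windows(u.times, onsets, during_s) / during_s
        r_pre, r_dur = c_pre.mean(), c_dur.mean()
        mi = 0.0 if (r_pre + r_dur) == 0 else (r_dur - r_pre) / (r_dur + r_pre)
        if len(onsets) < 5:
            cls, p = None, float("nan")
        else:
            p = _perm_pvalue(c_pre, c_dur, n_perm, rng)
            if p < alpha and mi > 0:
                cls = "activated"
            elif p < alpha and mi < 0:
                cls = "inhibited"
            else:
                cls = "unchanged"
        out[u.unit_id] = UnitResponse(
            unit_id=u.unit_id, modulation_index=float(mi),
            responder_class=cls, p_value=p)
    return out


def evoked_lfp(rec: Recording, protocol: StimProtocol, channel: int,
               pre_s: float = 0.05, post_s: float = 0.1) -> dict:
    """Stimulus-locked LFP average and its largest deflection.

    Baseline is the mean of the 50 ms before pulse onset; the amplitude is
    the unsigned maximum of the baseline-subtracted average within 100 ms
    after onset, with the latency of that extremum.
    """
    pulses = protocol.pulse_times()
    if len(pulses) == 0:
        raise ValidationError("protocol contains no pulses")
    n_pre = int(round(pre_s * rec.fs))
    n_post = int(round(post_s * rec.fs))
    idx = np.round((pulses - rec.t0) * rec.fs).astype(int)
    idx = idx[(idx - n_pre >= 0) & (idx + n_post <= rec.n_samples)]
    if len(idx) == 0:
        raise ValidationError("no pulse fully inside the recording")
    sweeps = np.stack([rec.signal[channel, i - n_pre:i + n_post] for i in idx])
    trace = sweeps.mean(axis=0)
    t_ms = (np.arange(-n_pre, n_post) / rec.fs) * 1e3
    baseline = trace[:n_pre].mean()
    post = trace[n_pre:] - baseline
    i_ext = int(np.argmax(np.abs(post)))
    return {
        "time_ms": t_ms,
        "trace": trace,
        "baseline": float(baseline),
        "amplitude_uv": float(abs(post[i_ext])),
        "signed_amplitude_uv": float(post[i_ext]),
        "latency_ms": float(i_ext / rec.fs * 1e3),
        "n_pulses": int(len(idx)),
    }


def csd(lfp: np.ndarray, spacing_um: float, smooth: bool = False) -> dict:
    """Current source density of a laminar LFP profile.

    Second spatial difference ``-(V[i-1] - 2 V[i] + V[i+1]) / dz^2`` with
    Vaknin padding (the end channels duplicated) so the output keeps all
    channels; optional 3-point spatial Hamming smoothing.  The sink is the
    most negative extremum; its channel index is reported.
    """
    lfp = np.atleast_2d(np.asarray(lfp, dtype=float))
    n_ch = lfp.shape[0]
    if n_ch < 3:
        raise ValidationError("CSD needs at least 3 channels")
    v = np.concatenate([lfp[:1], lfp, lfp[-1:]], axis=0)
    if smooth:
        w = np.array([0.23, 0.54, 0.23])
        v = (w[0] * np.roll(v, 1, axis=0) + w[1] * v
             + w[2] * np.roll(v, -1, axis=0))
        v[0], v[-1] = v[1], v[-2]
    dz2 = (spacing_um * 1e-3) ** 2  # mm^2
    out = -(v[:-2] - 2 * v[1:-1] + v[2:]) / dz2
    sink_ch, sink_t = np.unravel_index(np.argmin(out), out.shape)
    return {
        "csd": out,
        "sink_channel": int(sink_ch),
        "sink_time_index": int(sink_t),
        "sink_depth_um": float(sink_ch * spacing_um),
    }


def _band_power_window(x: np.ndarray, fs: float, band: tuple) -> float:
    n_seg = min(len(x), int(round(fs / 2)))
    n = (len(x) // n_seg) * n_seg
    ps = psd_segments(x[:n].reshape(-1, n_seg), fs)
    return band_average(ps, band[0], band[1])


def _window_slices(rec, onsets, width):
    n_w = int(round(width * rec.fs))
    idx = np.round((np.asarray(onsets) - rec.t0) * rec.fs).astype(int)
    return [(i, i + n_w) for i in idx if 0 <= i and i + n_w <= rec.n_samples]


def ramp_power_change(rec: Recording, protocol: StimProtocol, channel: int,
                      band: tuple, window_s: float = 1.5,
                      test: str = "last") -> float:
    """Relative band-power change around stimulation, averaged over sweeps.

    ``(P_test - P_pre) / P_pre`` per sweep: the pre window is the
    ``window_s`` before sweep onset; ``test="last"`` takes the final
    ``window_s`` of the ramp/train, ``test="post"`` the ``window_s`` right
    after its offset (presynaptic-silencing analysis).
    """
    dur = protocol.ramp_duration_s
    if test == "last":
        t_test = protocol.sweep_onsets + dur - window_s
    elif test == "post":
        t_test = protocol.sweep_onsets + dur
    else:
        raise ValidationError("test must be 'last' or 'post'")
    pre = _window_slices(rec, protocol.sweep_onsets - window_s, window_s)
    tst = _window_slices(rec, t_test, window_s)
    if not pre or len(pre) != len(tst):
        raise ValidationError("sweep windows fall outside the recording")
    # band power averaged over sweeps before the ratio, which avoids the
    # upward bias of averaging per-sweep ratios with noisy denominators
    p_pre = np.mean([
        _band_power_window(rec.signal[channel, a0:a1], rec.fs, band)
        for a0, a1 in pre])
    p_tst = np.mean([
        _band_power_window(rec.signal[channel, b0:b1], rec.fs, band)
        for b0, b1 in tst])
    if p_pre <= 0:
        raise ValidationError("zero pre-stimulation band power")
    return float((p_tst - p_pre) / p_pre)


def _window_segments(x: np.ndarray, fs: float) -> np.ndarray:
    n_seg = int(round(fs / 2))
    step = n_seg // 2
    starts = np.arange(0, len(x) - n_seg + 1, step)
    return np.stack([x[s:s + n_seg] for s in starts])


def ramp_coherence_change(rec: Recording, protocol: StimProtocol,
                          channel_x: int, channel_y: int, band: tuple,
                          window_s: float = 1.5, test: str = "last") -> float:
    """Relative change of band-averaged coherence around stimulation.

    Half-second Welch segments from the pre windows of all sweeps are pooled
    into one coherence estimate, likewise for the test windows (mirroring
    the power rule: last ``window_s`` of the ramp, or the window after
    offset); the change is ``during/pre - 1``.
    """
    dur = protocol.ramp_duration_s
    t_test = (protocol.sweep_onsets + dur - window_s if test == "last"
              else protocol.sweep_onsets + dur)
    pre = _window_slices(rec, protocol.sweep_onsets - window_s, window_s)
    tst = _window_slices(rec, t_test, window_s)
    if not pre or len(pre) != len(tst):
        raise ValidationError("sweep windows fall outside the recording")

    def pooled(slices):
        xe = np.concatenate([
            _window_segments(rec.signal[channel_x, a:b], rec.fs)
            for a, b in slices])
        ye = np.concatenate([
            _window_segments(rec.signal[channel_y, a:b], rec.fs)
            for a, b in slices])
        c = coherence(cross_spectra(xe, ye, rec.fs))
        return band_average(c, band[0], band[1])

    c_pre = pooled(pre)
    c_tst = pooled(tst)
    if c_pre <= 0:
        raise ValidationError("zero pre-stimulation coherence")
    return float(c_tst / c_pre - 1.0)


def eepsc_features(
    traces: np.ndarray,
    fs: float,
    stim_onset_s: float,
    slope_threshold_pa_ms: float = 10.0,
    rise_frac: tuple = (0.2, 0.8),
    responsive_latency_ms: float = 9.0,
    responsive_k_sd: float = 3.0,
    search_s: float = 0.05,
) -> EPSCFeatures:
    """Features of light-evoked EPSCs from voltage-clamp sweeps.

    Sweeps (rows, pA; inward currents negative) are averaged; the peak
    amplitude is the baseline-subtracted magnitude of the largest inward
    deflection, the onset the first post-stimulus time at which |dI/dt|
    exceeds ``slope_threshold_pa_ms``, and the rise time the 20-80 % span on
    the average trace.  CV is the SD over mean of the per-sweep peak
    amplitudes.  A cell counts as responsive when the average peak exceeds
    ``responsive_k_sd`` baseline SDs and the onset latency is below
    ``responsive_latency_ms``.
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    if traces.shape[0] < 2:
        raise ValidationError("need at least 2 sweeps")
    i_on = int(round(stim_onset_s * fs))
    if not (0 < i_on < traces.shape[1]):
        raise ValidationError("stimulus onset outside the trace")
    i_end = min(traces.shape[1], i_on + int(round(search_s * fs)))

    avg = traces.mean(axis=0)
    baseline = avg[:i_on].mean()
    base_sd = avg[:i_on].std()
    seg = avg[i_on:i_end] - baseline
    i_pk = int(np.argmin(seg))
    amplitude = float(-seg[i_pk])

    # onset: response speed on the average trace, lightly smoothed (0.5 ms
    # boxcar) so sample-to-sample noise does not trip the slope threshold
    n_sm = max(1, int(round(0.5e-3 * fs)))
    smooth = np.convolve(seg, np.ones(n_sm) / n_sm, mode="same")
    slope = np.abs(np.diff(smooth)) * fs / 1e3  # pA per ms
    above = np.flatnonzero(slope > slope_threshold_pa_ms)
    onset_ms = float(above[0] / fs * 1e3) if len(above) else float("nan")

    # 20-80 % rise on the average trace
    rise_ms = float("nan")
    if amplitude > 0:
        lo, hi = rise_frac
        rising = -seg[:i_pk + 1]
        t_lo = np.flatnonzero(rising >= lo * amplitude)
        t_hi = np.flatnonzero(rising >= hi * amplitude)
        if len(t_lo) and len(t_hi):
            rise_ms = float((t_hi[0] - t_lo[0]) / fs * 1e3)

    per_sweep = np.array([
        -(tr[i_on:i_end] - tr[:i_on].mean()).min() for tr in traces
    ])
    mean_pk = per_sweep.mean()
    cv = float(per_sweep.std() / mean_pk) if mean_pk > 0 else 0.0

    responsive = bool(
        amplitude > responsive_k_sd * base_sd
        and np.isfinite(onset_ms)
        and onset_ms < responsive_latency_ms
    )
    return EPSCFeatures(
        amplitude_pa=amplitude if responsive or amplitude >= 0 else 0.0,
        onset_latency_ms=onset_ms,
        rise_time_ms=rise_ms,
        cv=cv,
        responsive=responsive,
    )
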