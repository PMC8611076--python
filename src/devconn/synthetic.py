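"""Ground-truth generator for recordings, spikes, stimulation and behavior.

The generator emulates the statistical structure of neonatal
entorhinal-hippocampal-prefrontal recordings:

* a latent three-region MVAR process sampled at 100 Hz whose per-region
  dynamics are a cascade of theta (~8 Hz) and beta (~20 Hz) resonators and
  whose directed coupling (LEC->HP strong, HP->PFC moderate, LEC->PFC weak)
  is known exactly in the form of the generating :class:`MVARModel`;
* discontinuous spindle bursts: the oscillatory component is gated by an
  envelope with raised-cosine edges, active only inside burst intervals drawn
  from a renewal process (log-normal durations, mean 3 s); outside bursts the
  oscillatory power is attenuated by >= 20 dB;
* a continuous 2-4 Hz slow rhythm and 1/f background noise;
* optional instantaneous mixing across regions (volume conduction) and a
  laminar dipole projection onto a multi-site probe per region;
* spike trains as inhomogeneous Poisson processes modulated by the region's
  theta-beta amplitude, with light-evoked spikes for responder units;
* behavior tables with per-animal object-interaction times.

The ``GE`` group modifies three things relative to ``CON``: the LEC->HP
coupling gain, the burst power, and the fraction of light-responsive units.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .data_model import (
    ChannelInfo, EventTable, MVARModel, Recording, SpikeSet, SpikeTrain,
    StimProtocol, ValidationError,
)
from .preprocessing import bandpass

__all__ = [
    "SimConfig", "build_mvar", "simulate_lfp", "simulate_spikes",
    "simulate_behavior", "make_pulse_protocol", "make_ramp_protocol",
    "laminar_dipole_weights", "colored_noise",
]


class MVARStabilityError(ValidationError):
    """The configured MVAR coefficients are unstable."""


@dataclass
class SimConfig:
    """Study conditions for the synthetic recordings.

    Defaults reproduce the neonatal control condition: discontinuous
    theta-beta spindle bursts (about six per minute, mean duration 3 s) on a
    continuous 2-4 Hz slow rhythm with 1/f background, and the directed
    coupling hierarchy LEC->HP > HP->PFC > LEC->PFC.
    """

    duration_s: float = 600.0
    fs: float = 1000.0
    fs_latent: float = 100.0
    regions: tuple = ("LEC", "HP", "PFC")
    # per-region resonances (radii chosen to give a broad theta-beta hump)
    theta_pole_hz: float = 8.0
    beta_pole_hz: float = 20.0
    theta_radius: float = 0.80
    beta_radius: float = 0.55
    # directed coupling gains g(source -> target) at lag 1
    coupling: dict = field(default_factory=lambda: {
        ("LEC", "HP"): 0.35,
        ("HP", "PFC"): 0.25,
        ("LEC", "PFC"): 0.08,
    })
    # bursts
    burst_rate_per_min: float = 6.0
    burst_duration_mean_s: float = 3.0
    burst_duration_sigma: float = 0.4
    burst_min_duration_s: float = 1.5
    burst_min_gap_s: float = 0.8
    burst_edge_s: float = 0.1
    burst_off_gain: float = 0.05
    burst_snr_db: float = 6.0
    # background
    slow_band_hz: tuple = (2.0, 4.0)
    slow_rel_amp: float = 0.5
    noise_exponent: float = 1.0
    noise_scale_uv: float = 25.0
    # volume conduction / laminar geometry
    mixing: np.ndarray | None = None
    channels_per_region: int = 1
    laminar_spacing_um: float = 50.0
    dipole_sink_channel: int = 8
    dipole_sep_channels: int = 2
    dipole_spread_channels: float = 1.0
    # spikes
    n_units_per_region: int = 5
    baseline_rate_hz: float = 2.0
    rate_mod_depth: float = 0.8
    p_resp: float = 0.8
    responder_fraction: float = 0.5
    response_latency_s: tuple = (0.003, 0.010)
    # group contrast
    group: str = "CON"
    ge_coupling_factor: float = 0.4
    ge_burst_power_factor: float = 0.5
    ge_responder_factor: float = 0.4

    def __post_init__(self):
        if any(g < 0 for g in self.coupling.values()):
            raise ValidationError("coupling gains must be >= 0")
        if not (0.0 <= self.p_resp <= 1.0):
            raise ValidationError("p_resp must lie in [0, 1]")
        if self.mixing is not None:
            m = np.asarray(self.mixing, dtype=float)
            if m.ndim != 2 or m.shape[0] != m.shape[1]:
                raise ValidationError("mixing matrix must be square")
            self.mixing = m
        if self.group not in ("CON", "GE"):
            raise ValidationError("group must be 'CON' or 'GE'")

    def effective_coupling(self) -> dict:
        c = dict(self.coupling)
        if self.group == "GE":
            key = ("LEC", "HP")
            if key in c:
                c[key] = c[key] * self.ge_coupling_factor
        return c

    def effective_snr_db(self) -> float:
        if self.group == "GE":
            return self.burst_snr_db + 10 * np.log10(self.ge_burst_power_factor)
        return self.burst_snr_db

    def effective_responder_fraction(self) -> float:
        f = self.responder_fraction
        if self.group == "GE":
            f = f * self.ge_responder_factor
        return f

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


# ---------------------------------------------------------------------------
# latent MVAR model


def _resonator_poly(f0: float, radius: float, fs: float) -> np.ndarray:
    theta = 2 * np.pi * f0 / fs
    return np.array([1.0, -2.0 * radius * np.cos(theta), radius ** 2])


def build_mvar(cfg: SimConfig) -> MVARModel:
    """Generating MVAR model implied by the configuration (unit innovations)."""
    k = len(cfg.regions)
    ar = np.convolve(
        _resonator_poly(cfg.theta_pole_hz, cfg.theta_radius, cfg.fs_latent),
        _resonator_poly(cfg.beta_pole_hz, cfg.beta_radius, cfg.fs_latent),
    )
    p = len(ar) - 1
    coeffs = np.zeros((p, k, k))
    for i in range(k):
        coeffs[:, i, i] = -ar[1:]
    idx = {r: i for i, r in enumerate(cfg.regions)}
    for (src, dst), g in cfg.effective_coupling().items():
        coeffs[0, idx[dst], idx[src]] += g
    model = MVARModel(coeffs=coeffs, sigma=np.eye(k), fs_model=cfg.fs_latent)
    if not model.is_stable():
        raise MVARStabilityError(
            f"configured MVAR is unstable (spectral radius {model.spectral_radius():.3f})"
        )
    return model


def _simulate_mvar(model: MVARModel, n: int, rng: np.random.Generator,
                   burn: int = 500) -> np.ndarray:
    """Sample ``n`` steps of the VAR process; returns shape (k, n)."""
    p, k = model.order, model.k
    comp = model.companion()
    chol = np.linalg.cholesky(model.sigma + 1e-12 * np.eye(k))
    z = np.zeros(k * p)
    e = rng.standard_normal((n + burn, k)) @ chol.T
    out = np.empty((n + burn, k))
    for t in range(n + burn):
        z = comp @ z
        z[:k] += e[t]
        out[t] = z[:k]
    return out[burn:].T


# ---------------------------------------------------------------------------
# background components


def colored_noise(n: int, exponent: float, fs: float,
                  rng: np.random.Generator, f_min: float = 0.5) -> np.ndarray:
    """Spectrally shaped Gaussian noise with power ~ 1/f**exponent, unit SD."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = 1.0 / np.maximum(f, f_min) ** (exponent / 2.0)
    shape[0] = 0.0
    x = np.fft.irfft(spectrum * shape, n=n)
    return x / x.std()


def _slow_rhythm(n: int, fs: float, band: tuple, rng: np.random.Generator) -> np.ndarray:
    x = bandpass(rng.standard_normal(n), band[0], band[1], order=4, fs=fs)
    return x / x.std()


# ---------------------------------------------------------------------------
# burst intervals and envelope


def _draw_burst_intervals(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    lam = cfg.burst_rate_per_min / 60.0
    mu = np.log(cfg.burst_duration_mean_s) - 0.5 * cfg.burst_duration_sigma ** 2
    # correct the gap rate for the busy period so the realized event rate
    # matches the configured one (renewal-process thinning compensation)
    busy = cfg.burst_duration_mean_s + cfg.burst_min_gap_s
    lam_eff = lam / max(1.0 - lam * busy, 0.05)
    events = []
    t = cfg.burst_min_gap_s + rng.exponential(1.0 / lam_eff)
    while True:
        dur = float(np.exp(rng.normal(mu, cfg.burst_duration_sigma)))
        while dur < cfg.burst_min_duration_s:
            dur = float(np.exp(rng.normal(mu, cfg.burst_duration_sigma)))
        if t + dur > cfg.duration_s - 0.5:
            break
        events.append((t, t + dur))
        t = t + dur + cfg.burst_min_gap_s + rng.exponential(1.0 / lam_eff)
    return np.array(events).reshape(-1, 2)


def _burst_envelope(intervals: np.ndarray, n: int, fs: float,
                    edge_s: float, off_gain: float) -> np.ndarray:
    env = np.full(n, off_gain)
    n_edge = max(1, int(round(edge_s * fs)))
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_edge) / n_edge))
    for start, stop in intervals:
        i0, i1 = int(round(start * fs)), int(round(stop * fs))
        i0, i1 = max(i0, 0), min(i1, n)
        if i1 - i0 <= 2 * n_edge:
            continue
        env[i0:i1] = 1.0
        env[i0:i0 + n_edge] = off_gain + (1 - off_gain) * ramp
        env[i1 - n_edge:i1] = off_gain + (1 - off_gain) * ramp[::-1]
    return env


def laminar_dipole_weights(n_channels: int, sink_channel: int,
                           sep_channels: int = 2,
                           spread_channels: float = 1.0) -> np.ndarray:
    """Sink/source dipole profile across a linear probe.

    The sink sits at ``sink_channel``, the return source ``sep_channels``
    above it; both have a Gaussian spatial spread.  The profile is normalized
    to unit maximum magnitude.
    """
    ch = np.arange(n_channels, dtype=float)
    w = (np.exp(-0.5 * ((ch - sink_channel) / spread_channels) ** 2)
         - np.exp(-0.5 * ((ch - (sink_channel - sep_channels)) / spread_channels) ** 2))
    return w / np.abs(w).max()


# ---------------------------------------------------------------------------
# main generators


def _band_var(x: np.ndarray, fs: float, band=(4.0, 30.0)) -> float:
    return float(np.var(bandpass(x, band[0], band[1], order=3, fs=fs)))


def _peak_psd(x: np.ndarray, fs: float, band: tuple) -> float:
    """Mean Welch PSD over a narrow reference band (1 s segments)."""
    n_seg = int(round(fs))
    n = (len(x) // n_seg) * n_seg
    if n == 0:
        raise ValidationError("signal shorter than one PSD segment")
    f, p = sps.welch(x[:n].reshape(-1, n_seg).ravel(), fs=fs,
                     nperseg=n_seg, noverlap=0, window="hamming",
                     detrend=False)
    m = (f >= band[0]) & (f <= band[1])
    return float(p[m].mean())


def simulate_lfp(cfg: SimConfig, rng=0, return_components: bool = False):
    """Synthesize a multichannel recording with known ground truth.

    Returns ``(Recording, EventTable, MVARModel)`` — the recording, the true
    burst intervals (replicated per channel) and the generating latent model.
    With ``return_components=True`` a dict of the per-region additive
    components (``burst``, ``noise``, ``slow``, ``envelope``) is appended.
    """
    rng = np.random.default_rng(rng)
    model = build_mvar(cfg)
    k = len(cfg.regions)
    n_lat = int(round(cfg.duration_s * cfg.fs_latent))
    n = int(round(cfg.duration_s * cfg.fs))

    latent = _simulate_mvar(model, n_lat, rng)
    latent /= latent.std(axis=1, keepdims=True)

    up = int(round(cfg.fs / cfg.fs_latent))
    osc = sps.resample_poly(latent, up, 1, axis=1)[:, :n]

    intervals = _draw_burst_intervals(cfg, rng)
    env = _burst_envelope(intervals, n, cfg.fs, cfg.burst_edge_s, cfg.burst_off_gain)
    burst = osc * env[None, :]

    noise = np.stack([
        colored_noise(n, cfg.noise_exponent, cfg.fs, rng) for _ in range(k)
    ]) * cfg.noise_scale_uv
    slow = np.stack([
        _slow_rhythm(n, cfg.fs, cfg.slow_band_hz, rng) for _ in range(k)
    ]) * (cfg.slow_rel_amp * cfg.noise_scale_uv)

    # scale the oscillatory component to the target in-burst SNR: power of
    # the burst component relative to the background (noise + slow rhythm)
    # within the 3-100 Hz detection band
    mask = np.zeros(n, dtype=bool)
    for start, stop in intervals:
        mask[int(round(start * cfg.fs)):int(round(stop * cfg.fs))] = True
    target = 10.0 ** (cfg.effective_snr_db() / 10.0)
    ref_band = (3.0, 100.0)
    for i in range(k):
        sig = burst[i][mask] if mask.any() else burst[i]
        p_sig = _band_var(sig, cfg.fs, ref_band)
        p_bg = _band_var(noise[i] + slow[i], cfg.fs, ref_band)
        burst[i] *= np.sqrt(target * p_bg / max(p_sig, 1e-30))

    region_sig = burst + noise + slow
    if cfg.mixing is not None:
        if cfg.mixing.shape != (k, k):
            raise ValidationError("mixing matrix shape must match region count")
        region_sig = cfg.mixing @ region_sig

    # laminar projection
    channels: list[ChannelInfo] = []
    rows = []
    idx = 0
    for r, region in enumerate(cfg.regions):
        if cfg.channels_per_region <= 1:
            rows.append(region_sig[r])
            channels.append(ChannelInfo(index=idx, region=region))
            idx += 1
        else:
            w = laminar_dipole_weights(
                cfg.channels_per_region, cfg.dipole_sink_channel,
                cfg.dipole_sep_channels, cfg.dipole_spread_channels)
            sensor = rng.standard_normal(
                (cfg.channels_per_region, n)) * (0.05 * cfg.noise_scale_uv)
            for c in range(cfg.channels_per_region):
                rows.append(w[c] * region_sig[r] + sensor[c])
                channels.append(ChannelInfo(
                    index=idx, region=region, layer=f"site{c}",
                    depth_um=c * cfg.laminar_spacing_um))
                idx += 1

    rec = Recording(signal=np.vstack(rows), fs=cfg.fs, channels=channels)

    # ground-truth events, replicated per channel; peak RMS from the 3-100 Hz
    # band of the region signal
    ev_rows = {c: [] for c in ("channel", "start_s", "stop_s", "peak_rms_uv")}
    if len(intervals):
        region_rms = {}
        for r, region in enumerate(cfg.regions):
            xb = bandpass(region_sig[r], 3.0, 100.0, order=3, fs=cfg.fs)
            region_rms[region] = [
                float(np.sqrt(np.mean(
                    xb[int(s * cfg.fs):int(e * cfg.fs)] ** 2)))
                for s, e in intervals
            ]
        for ci, ch in enumerate(channels):
            ev_rows["channel"].extend([ci] * len(intervals))
            ev_rows["start_s"].extend(intervals[:, 0])
            ev_rows["stop_s"].extend(intervals[:, 1])
            ev_rows["peak_rms_uv"].extend(region_rms[ch.region])
    events = EventTable.from_arrays(
        np.array(ev_rows["channel"], dtype=int),
        np.array(ev_rows["start_s"], dtype=float),
        np.array(ev_rows["stop_s"], dtype=float),
        np.array(ev_rows["peak_rms_uv"], dtype=float),
    ) if len(intervals) else EventTable.empty()

    if return_components:
        comps = {"burst": burst, "noise": noise, "slow": slow,
                 "envelope": env, "intervals": intervals}
        return rec, events, model, comps
    return rec, events, model


def simulate_spikes(
    rec: Recording,
    cfg: SimConfig,
    protocol: StimProtocol | None = None,
    rng=0,
) -> SpikeSet:
    """Inhomogeneous Poisson spike trains phase-locked to the region LFP.

    Rates are modulated by the instantaneous 4-30 Hz amplitude of the
    region's LFP.  Responder units emit one extra spike with probability
    ``p_resp`` at a latency drawn from ``response_latency_s`` after each
    light-pulse onset; non-responders ignore the protocol.
    """
    rng = np.random.default_rng(rng)
    dt = 1e-3
    n_bins = int(round(rec.duration / dt))
    pulses = (protocol.pulse_times()
              if protocol is not None and protocol.kind == "pulse" else None)

    units: list[SpikeTrain] = []
    frac = cfg.effective_responder_fraction()
    for region in cfg.regions:
        try:
            ch = rec.region_channel(region)
        except KeyError:
            continue
        if cfg.baseline_rate_hz > 0 and cfg.rate_mod_depth > 0:
            xb = bandpass(rec.signal[ch], 4.0, 30.0, order=3, fs=rec.fs)
            amp = np.abs(sps.hilbert(xb))
            stride = max(1, int(round(rec.fs * dt)))
            amp_b = amp[::stride][:n_bins]
            amp_b = amp_b / amp_b.mean()
            rate = cfg.baseline_rate_hz * (
                1.0 - cfg.rate_mod_depth + cfg.rate_mod_depth * amp_b)
        else:
            rate = np.full(n_bins, cfg.baseline_rate_hz)
        n_resp = int(round(frac * cfg.n_units_per_region))
        for u in range(cfg.n_units_per_region):
            hit = rng.random(n_bins) < rate * dt
            times = (np.flatnonzero(hit) + rng.random(hit.sum())) * dt + rec.t0
            is_resp = u < n_resp
            if is_resp and pulses is not None and cfg.p_resp > 0:
                fired = rng.random(len(pulses)) < cfg.p_resp
                lat = rng.uniform(*cfg.response_latency_s, size=fired.sum())
                times = np.concatenate([times, pulses[fired] + lat])
            times = np.sort(times)
            if len(times) > 1:
                times = times[np.concatenate(([True], np.diff(times) > 1e-4))]
            units.append(SpikeTrain(
                unit_id=f"{region}_u{u:02d}", region=region, layer="",
                times=times, meta={"responder": bool(is_resp)}))
    return SpikeSet(units)


# ---------------------------------------------------------------------------
# stimulation protocols


def make_pulse_protocol(n_sweeps: int = 50, rate_hz: float = 8.0,
                        train_s: float = 3.0, pulse_width_s: float = 0.003,
                        period_s: float = 10.0, start_s: float = 5.0) -> StimProtocol:
    """Pulse-train protocol: ``rate_hz`` pulses for ``train_s`` per sweep."""
    n_pulses = int(round(train_s * rate_hz))
    return StimProtocol(
        kind="pulse",
        sweep_onsets=start_s + period_s * np.arange(n_sweeps),
        pulse_onsets=np.arange(n_pulses) / rate_hz,
        pulse_width_s=pulse_width_s,
        rate_hz=rate_hz,
    )


def make_ramp_protocol(n_sweeps: int = 20, ramp_s: float = 3.0,
                       period_s: float = 10.0, start_s: float = 5.0) -> StimProtocol:
    return StimProtocol(
        kind="ramp",
        sweep_onsets=start_s + period_s * np.arange(n_sweeps),
        ramp_duration_s=ramp_s,
    )


# ---------------------------------------------------------------------------
# behavior


def simulate_behavior(
    n_per_group: int = 20,
    effects: dict | None = None,
    rng=0,
    sd_s: float = 1.0,
    task: str = "NOPd",
    velocity_mean: float = 30.0,
    velocity_sd: float = 5.0,
    sedentary_fraction: float = 0.1,
):
    """Per-animal object-interaction times drawn from truncated normals.

    ``effects`` maps group -> (mean novel s, mean familiar s).  A fraction of
    animals gets a velocity below the 20 cm/min exploration threshold so the
    downstream exclusion rule is exercised.
    """
    import pandas as pd

    rng = np.random.default_rng(rng)
    if effects is None:
        effects = {"CON": (5.25, 2.13), "GE": (3.81, 1.93)}

    def trunc_normal(mean, sd, size):
        x = rng.normal(mean, sd, size)
        while (x < 0.1).any():
            bad = x < 0.1
            x[bad] = rng.normal(mean, sd, bad.sum())
        return x

    rows = []
    for group, (m_nov, m_fam) in effects.items():
        t_nov = trunc_normal(m_nov, sd_s, n_per_group)
        t_fam = trunc_normal(m_fam, sd_s, n_per_group)
        vel = rng.normal(velocity_mean, velocity_sd, n_per_group)
        n_sed = int(round(sedentary_fraction * n_per_group))
        if n_sed:
            sed_idx = rng.choice(n_per_group, size=n_sed, replace=False)
            vel[sed_idx] = rng.uniform(10.0, 19.9, n_sed)
        vel = np.clip(vel, 1.0, None)
        for i in range(n_per_group):
            rows.append({
                "animal_id": f"{group}{i:03d}", "group": group, "task": task,
                "t_novel_s": t_nov[i], "t_familiar_s": t_fam[i],
                "velocity_cm_min": vel[i],
            })
    return pd.DataFrame(rows)
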