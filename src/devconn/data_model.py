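"""Domain containers and file I/O shared by every analysis stage.

The pipeline works on four kinds of primary data: continuous multichannel
extracellular recordings (:class:`Recording`), tables of detected oscillatory
events (:class:`EventTable`), per-unit spike times (:class:`SpikeSet`) and
optogenetic stimulation protocols (:class:`StimProtocol`).  Derived results
are held in :class:`PowerSpectrum`, :class:`CoherenceSpectrum`,
:class:`MVARModel`, :class:`DirectedSpectrum`, :class:`UnitResponse`,
:class:`EPSCFeatures` and behavior tables.

Conventions
-----------
* times are seconds (float64); epochs are half-open ``[start, stop)``
* channel indices are 0-based in memory, 1-based only in printed reports
* LFP amplitudes are microvolts; region labels come from :data:`REGIONS`
* one HDF5 container per recording (groups ``/lfp``, ``/spikes``, ``/stim``),
  tabular results as CSV with fixed headers
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

REGIONS = ("LEC", "HP", "PFC")

EVENT_COLUMNS = ("channel", "start_s", "stop_s", "duration_s", "peak_rms_uv")


class ValidationError(ValueError):
    """An invariant of a domain type is violated."""


class MissingFieldError(KeyError):
    """A required field/dataset is absent from a container file."""


# ---------------------------------------------------------------------------
# recordings


@dataclass(frozen=True)
class ChannelInfo:
    index: int
    region: str
    layer: str = ""
    depth_um: float = float("nan")

    def __post_init__(self):
        if self.region not in REGIONS:
            raise ValidationError(
                f"unknown region {self.region!r}; expected one of {REGIONS}"
            )


@dataclass
class Recording:
    """Multichannel continuous signal in microvolts.

    ``signal`` has shape ``(n_channels, n_samples)``; ``fs`` is the sampling
    rate in Hz and ``t0`` the recording start time in seconds.
    """

    signal: np.ndarray
    fs: float
    channels: list[ChannelInfo]
    t0: float = 0.0

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2:
            raise ValidationError("signal must be a 2-D (n_channels, n_samples) array")
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if self.signal.shape[0] < 1:
            raise ValidationError("recording needs at least one channel")
        if len(self.channels) != self.signal.shape[0]:
            raise ValidationError(
                f"{len(self.channels)} channel descriptions for "
                f"{self.signal.shape[0]} signal rows"
            )
        if not np.isfinite(self.signal).all():
            raise ValidationError("signal contains NaN or Inf samples")
        idx = [c.index for c in self.channels]
        if len(set(idx)) != len(idx):
            raise ValidationError("channel indices must be unique")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def region_channels(self, region: str) -> list[int]:
        """Row positions (0-based) of all channels assigned to ``region``."""
        return [i for i, c in enumerate(self.channels) if c.region == region]

    def region_channel(self, region: str) -> int:
        rows = self.region_channels(region)
        if not rows:
            raise KeyError(f"recording has no channel in region {region!r}")
        return rows[0]


# ---------------------------------------------------------------------------
# event tables


@dataclass
class EventTable:
    """Detected (or ground-truth) oscillatory events, one row per event."""

    df: pd.DataFrame

    def __post_init__(self):
        df = pd.DataFrame(self.df).reset_index(drop=True)
        missing = [c for c in EVENT_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"event table lacks columns {missing}")
        self.df = df[list(EVENT_COLUMNS)].astype(
            {"channel": int, "start_s": float, "stop_s": float,
             "duration_s": float, "peak_rms_uv": float}
        )
        if len(self.df) == 0:
            return
        if not (self.df.stop_s > self.df.start_s).all():
            raise ValidationError("every event must satisfy stop > start")
        if not np.allclose(
            self.df.duration_s, self.df.stop_s - self.df.start_s, atol=1e-9
        ):
            raise ValidationError("duration must equal stop - start")
        for ch, sub in self.df.groupby("channel"):
            starts = sub.start_s.to_numpy()
            stops = sub.stop_s.to_numpy()
            if not (np.diff(starts) > 0).all():
                raise ValidationError(f"events on channel {ch} are not sorted")
            if (starts[1:] < stops[:-1]).any():
                raise ValidationError(f"events on channel {ch} overlap")

    @classmethod
    def from_arrays(cls, channel, start_s, stop_s, peak_rms_uv=None) -> "EventTable":
        start_s = np.asarray(start_s, dtype=float)
        stop_s = np.asarray(stop_s, dtype=float)
        if peak_rms_uv is None:
            peak_rms_uv = np.full_like(start_s, np.nan)
        channel = np.broadcast_to(np.asarray(channel, dtype=int), start_s.shape)
        return cls(pd.DataFrame({
            "channel": channel,
            "start_s": start_s,
            "stop_s": stop_s,
            "duration_s": stop_s - start_s,
            "peak_rms_uv": peak_rms_uv,
        }))

    @classmethod
    def empty(cls) -> "EventTable":
        return cls(pd.DataFrame({c: [] for c in EVENT_COLUMNS}))

    def __len__(self) -> int:
        return len(self.df)

    def channel(self, ch: int) -> "EventTable":
        return EventTable(self.df[self.df.channel == ch])

    def intervals(self, ch: int | None = None) -> np.ndarray:
        """``(n, 2)`` array of [start, stop) pairs, optionally per channel."""
        df = self.df if ch is None else self.df[self.df.channel == ch]
        return df[["start_s", "stop_s"]].to_numpy(dtype=float).reshape(-1, 2)


# ---------------------------------------------------------------------------
# spikes


@dataclass
class SpikeTrain:
    unit_id: str
    region: str
    layer: str
    times: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.region not in REGIONS:
            raise ValidationError(f"unknown region {self.region!r}")
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.times.ndim != 1:
            raise ValidationError("spike times must be a 1-D vector")
        if len(self.times) > 1 and not (np.diff(self.times) > 0).all():
            raise ValidationError(
                f"spike times of unit {self.unit_id} are not strictly increasing"
            )

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class SpikeSet:
    units: list[SpikeTrain]

    def __post_init__(self):
        ids = [u.unit_id for u in self.units]
        if len(set(ids)) != len(ids):
            raise ValidationError("unit ids must be unique")

    def __len__(self) -> int:
        return len(self.units)

    def __iter__(self):
        return iter(self.units)

    def check_span(self, t0: float, t1: float) -> None:
        for u in self.units:
            if len(u) and (u.times[0] < t0 or u.times[-1] > t1):
                raise ValidationError(
                    f"unit {u.unit_id} has spikes outside the recording span"
                )


# ---------------------------------------------------------------------------
# stimulation


@dataclass
class StimProtocol:
    """Optogenetic stimulation protocol.

    ``kind`` is ``"pulse"`` (on/off pulse trains) or ``"ramp"`` (linearly
    increasing power).  ``sweep_onsets`` are absolute sweep start times;
    ``pulse_onsets`` are pulse times relative to the sweep start (empty for
    ramps).
    """

    kind: str
    sweep_onsets: np.ndarray
    pulse_onsets: np.ndarray = field(default_factory=lambda: np.empty(0))
    pulse_width_s: float = 0.003
    ramp_duration_s: float = 3.0
    rate_hz: float | None = None

    def __post_init__(self):
        if self.kind not in ("pulse", "ramp"):
            raise ValidationError(f"kind must be 'pulse' or 'ramp', got {self.kind!r}")
        self.sweep_onsets = np.asarray(self.sweep_onsets, dtype=np.float64)
        self.pulse_onsets = np.asarray(self.pulse_onsets, dtype=np.float64)
        if self.pulse_width_s <= 0:
            raise ValidationError("pulse width must be positive")
        if len(self.pulse_onsets):
            if (self.pulse_onsets < 0).any():
                raise ValidationError("pulse onsets must be non-negative")
            if not (np.diff(self.pulse_onsets) > 0).all():
                raise ValidationError("pulse onsets must be increasing")
        if self.kind == "pulse" and self.rate_hz and len(self.pulse_onsets) > 2:
            spacing = np.diff(self.pulse_onsets)
            if abs(np.median(spacing) - 1.0 / self.rate_hz) > 0.25 / self.rate_hz:
                raise ValidationError(
                    "pulse spacing inconsistent with the stated rate"
                )

    @property
    def n_sweeps(self) -> int:
        return len(self.sweep_onsets)

    def pulse_times(self) -> np.ndarray:
        """Absolute onset time of every pulse over all sweeps, sorted."""
        if self.kind != "pulse":
            raise ValidationError("ramp protocols have no discrete pulses")
        t = (self.sweep_onsets[:, None] + self.pulse_onsets[None, :]).ravel()
        return np.sort(t)


# ---------------------------------------------------------------------------
# spectra and models


@dataclass
class PowerSpectrum:
    freqs: np.ndarray
    power: np.ndarray
    baseline: np.ndarray | None = None
    normalized: bool = False
    n_segments: int = 0

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.shape != self.power.shape:
            raise ValidationError("freqs and power shapes differ")
        if len(self.freqs) > 1 and not (np.diff(self.freqs) > 0).all():
            raise ValidationError("frequency grid must be increasing")
        if (self.power < 0).any():
            raise ValidationError("power must be non-negative")


@dataclass
class CoherenceSpectrum:
    freqs: np.ndarray
    coherence: np.ndarray
    imag_coherence: np.ndarray
    shuffle_null: np.ndarray | None = None

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.coherence = np.asarray(self.coherence, dtype=float)
        self.imag_coherence = np.asarray(self.imag_coherence, dtype=float)
        tol = 1e-9
        if ((self.imag_coherence < -tol)
                | (self.imag_coherence > self.coherence + tol)
                | (self.coherence > 1 + tol)).any():
            raise ValidationError("need 0 <= |imC| <= C <= 1")


@dataclass
class MVARModel:
    """Multivariate autoregressive model x_t = sum_r A_r x_{t-r} + e_t.

    ``coeffs`` has shape ``(order, k, k)``; ``sigma`` is the innovation
    covariance; ``fs_model`` the sampling rate the model lives at.
    """

    coeffs: np.ndarray
    sigma: np.ndarray
    fs_model: float

    def __post_init__(self):
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.coeffs.ndim != 3 or self.coeffs.shape[1] != self.coeffs.shape[2]:
            raise ValidationError("coeffs must have shape (order, k, k)")
        k = self.coeffs.shape[1]
        if self.sigma.shape != (k, k):
            raise ValidationError("sigma shape must match the channel count")
        if not np.allclose(self.sigma, self.sigma.T, atol=1e-8):
            raise ValidationError("sigma must be symmetric")
        if np.linalg.eigvalsh(self.sigma).min() < -1e-8:
            raise ValidationError("sigma must be positive semi-definite")

    @property
    def order(self) -> int:
        return self.coeffs.shape[0]

    @property
    def k(self) -> int:
        return self.coeffs.shape[1]

    def companion(self) -> np.ndarray:
        p, k = self.order, self.k
        top = np.concatenate(list(self.coeffs), axis=1)
        comp = np.zeros((k * p, k * p))
        comp[:k, :] = top
        if p > 1:
            comp[k:, :-k] = np.eye(k * (p - 1))
        return comp

    def spectral_radius(self) -> float:
        return float(np.abs(np.linalg.eigvals(self.companion())).max())

    def is_stable(self) -> bool:
        return self.spectral_radius() < 1.0


@dataclass
class DirectedSpectrum:
    """gPDC values: ``values[i, j, f]`` is the influence j -> i at freqs[f]."""

    freqs: np.ndarray
    values: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[0] != self.values.shape[1]:
            raise ValidationError("values must have shape (k, k, n_freqs)")
        if self.values.shape[2] != len(self.freqs):
            raise ValidationError("frequency axis mismatch")
        if ((self.values < -1e-12) | (self.values > 1 + 1e-9)).any():
            raise ValidationError("gPDC values must lie in [0, 1]")
        colsum = (self.values ** 2).sum(axis=0)
        if not np.allclose(colsum, 1.0, atol=1e-8):
            raise ValidationError("column normalization sum_i gpdc^2 != 1")

    def pair(self, source: int, target: int) -> np.ndarray:
        return self.values[target, source, :]


@dataclass
class UnitResponse:
    unit_id: str
    firing_probability: float = np.nan
    modulation_index: float = np.nan
    responder_class: str | None = None
    firing_rate_hz: float = np.nan
    p_value: float = np.nan

    def __post_init__(self):
        if np.isfinite(self.firing_probability) and self.firing_probability < 0:
            raise ValidationError("firing probability must be >= 0")
        if np.isfinite(self.modulation_index) and not (
            -1 - 1e-12 <= self.modulation_index <= 1 + 1e-12
        ):
            raise ValidationError("modulation index must lie in [-1, 1]")
        if self.responder_class not in (None, "activated", "inhibited", "unchanged"):
            raise ValidationError(f"bad responder class {self.responder_class!r}")


@dataclass
class EPSCFeatures:
    amplitude_pa: float
    onset_latency_ms: float
    rise_time_ms: float
    cv: float
    responsive: bool

    def __post_init__(self):
        if self.responsive and self.amplitude_pa < 0:
            raise ValidationError("amplitude of a responsive cell must be >= 0")
        if np.isfinite(self.onset_latency_ms) and self.onset_latency_ms < 0:
            raise ValidationError("onset latency must be >= 0")
        if np.isfinite(self.cv) and self.cv < 0:
            raise ValidationError("CV must be >= 0")


BEHAVIOR_COLUMNS = (
    "animal_id", "group", "task", "t_novel_s", "t_familiar_s", "velocity_cm_min"
)


def validate_behavior(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in BEHAVIOR_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"behavior table lacks columns {missing}")
    bad_task = set(df.task) - {"NOP", "NOPd", "OLP"}
    if bad_task:
        raise ValidationError(f"unknown task labels {sorted(bad_task)}")
    if (df[["t_novel_s", "t_familiar_s", "velocity_cm_min"]] < 0).any().any():
        raise ValidationError("interaction times and velocity must be >= 0")
    return df


# ---------------------------------------------------------------------------
# HDF5 container I/O


def write_recording(rec: Recording, path, mode: str = "a") -> None:
    with h5py.File(path, mode) as f:
        if "lfp" in f:
            del f["lfp"]
        g = f.create_group("lfp")
        g.create_dataset("data", data=rec.signal, track_times=False)
        g.attrs["fs"] = float(rec.fs)
        g.attrs["t0"] = float(rec.t0)
        g.create_dataset(
            "channel_index", data=np.array([c.index for c in rec.channels]),
            track_times=False)
        g.create_dataset(
            "region",
            data=np.array([c.region for c in rec.channels], dtype="S8"),
            track_times=False)
        g.create_dataset(
            "layer",
            data=np.array([c.layer for c in rec.channels], dtype="S32"),
            track_times=False)
        g.create_dataset(
            "depth_um", data=np.array([c.depth_um for c in rec.channels]),
            track_times=False)


def read_recording(path) -> Recording:
    with h5py.File(path, "r") as f:
        if "lfp" not in f:
            raise MissingFieldError("container has no /lfp group")
        g = f["lfp"]
        if "data" not in g:
            raise MissingFieldError("container has no /lfp/data dataset")
        if "fs" not in g.attrs:
            raise MissingFieldError("container lacks the fs attribute")
        signal = np.asarray(g["data"], dtype=np.float64)
        fs = float(g.attrs["fs"])
        t0 = float(g.attrs.get("t0", 0.0))
        channels = [
            ChannelInfo(int(i), r.decode(), l.decode(), float(d))
            for i, r, l, d in zip(
                g["channel_index"], g["region"], g["layer"], g["depth_um"]
            )
        ]
    return Recording(signal=signal, fs=fs, channels=channels, t0=t0)


def write_spikes(spikes: SpikeSet, path, mode: str = "a") -> None:
    with h5py.File(path, mode) as f:
        if "spikes" in f:
            del f["spikes"]
        g = f.create_group("spikes")
        for u in spikes:
            d = g.create_dataset(u.unit_id, data=u.times, track_times=False)
            d.attrs["region"] = u.region
            d.attrs["layer"] = u.layer


def read_spikes(path) -> SpikeSet:
    with h5py.File(path, "r") as f:
        if "spikes" not in f:
            raise MissingFieldError("container has no /spikes group")
        units = [
            SpikeTrain(
                unit_id=name,
                region=d.attrs["region"],
                layer=d.attrs.get("layer", ""),
                times=np.asarray(d, dtype=np.float64),
            )
            for name, d in sorted(f["spikes"].items())
        ]
    return SpikeSet(units)


def write_stim(stim: StimProtocol, path, mode: str = "a") -> None:
    with h5py.File(path, mode) as f:
        if "stim" in f:
            del f["stim"]
        g = f.create_group("stim")
        g.attrs["kind"] = stim.kind
        g.attrs["pulse_width_s"] = stim.pulse_width_s
        g.attrs["ramp_duration_s"] = stim.ramp_duration_s
        if stim.rate_hz is not None:
            g.attrs["rate_hz"] = stim.rate_hz
        g.create_dataset("sweep_onsets", data=stim.sweep_onsets, track_times=False)
        g.create_dataset("pulse_onsets", data=stim.pulse_onsets, track_times=False)


def read_stim(path) -> StimProtocol:
    with h5py.File(path, "r") as f:
        if "stim" not in f:
            raise MissingFieldError("container has no /stim group")
        g = f["stim"]
        rate = g.attrs.get("rate_hz")
        return StimProtocol(
            kind=g.attrs["kind"],
            sweep_onsets=np.asarray(g["sweep_onsets"], dtype=np.float64),
            pulse_onsets=np.asarray(g["pulse_onsets"], dtype=np.float64),
            pulse_width_s=float(g.attrs["pulse_width_s"]),
            ramp_duration_s=float(g.attrs["ramp_duration_s"]),
            rate_hz=None if rate is None else float(rate),
        )


# ---------------------------------------------------------------------------
# CSV table I/O


def write_events(events: EventTable, path) -> None:
    events.df.to_csv(path, index=False, float_format="%.9f")


def read_events(path) -> EventTable:
    df = pd.read_csv(path)
    if len(df) == 0:
        return EventTable.empty()
    return EventTable(df)


def write_table(df: pd.DataFrame, path) -> None:
    pd.DataFrame(df).to_csv(path, index=False, float_format="%.9f")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
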