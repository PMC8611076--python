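"""Light-evoked spiking/field quantification, CSD, ramp changes, eEPSCs."""

import numpy as np
import pytest

from devconn.data_model import (
    ChannelInfo, Recording, SpikeSet, SpikeTrain, StimProtocol, ValidationError,
)
from devconn.evoked import (
    csd, eepsc_features, evoked_lfp, firing_probability, firing_rate,
    modulation_index, psth, ramp_coherence_change, ramp_power_change,
)
from devconn.preprocessing import bandpass
from devconn.synthetic import (
    laminar_dipole_weights, make_pulse_protocol, make_ramp_protocol,
)


def _protocol(n_pulses=10, spacing=1.0):
    return StimProtocol(kind="pulse", sweep_onsets=[0.0],
                        pulse_onsets=np.arange(n_pulses) * spacing)


def _spikeset(times, region="HP"):
    return SpikeSet([SpikeTrain("u0", region, "", np.sort(times))])


class TestFiringProbability:
    def test_three_of_ten_pulses_with_one_spike(self):
        proto = _protocol()
        spikes = _spikeset([0.005, 2.010, 7.019])
        assert firing_probability(spikes, proto)["u0"] == pytest.approx(0.3)

    def test_spikes_not_pulses_are_counted(self):
        proto = _protocol()
        spikes = _spikeset([3.004, 3.010])  # two spikes inside one window
        assert firing_probability(spikes, proto)["u0"] == pytest.approx(0.2)

    def test_window_is_half_open_20ms(self):
        proto = _protocol()
        spikes = _spikeset([0.0199999, 1.020001])
        assert firing_probability(spikes, proto)["u0"] == pytest.approx(0.1)

    def test_empty_protocol_rejected(self):
        proto = StimProtocol(kind="pulse", sweep_onsets=[], pulse_onsets=[])
        with pytest.raises(ValidationError):
            firing_probability(_spikeset([1.0]), proto)


class TestFiringRate:
    def test_basic_rate(self):
        spikes = _spikeset(np.linspace(0.1, 59.9, 120))
        assert firing_rate(spikes, (0.0, 60.0))["u0"] == pytest.approx(2.0)

    def test_empty_train(self):
        assert firing_rate(_spikeset([]), (0.0, 60.0))["u0"] == 0.0

    def test_poisson_rate_recovery(self, rng):
        t = np.cumsum(rng.exponential(1 / 5.0, 4000))
        t = t[t < 600.0]
        rate = firing_rate(_spikeset(t), (0.0, 600.0))["u0"]
        assert rate == pytest.approx(5.0, abs=0.3)


class TestPsth:
    def test_fixed_latency_gives_single_bin(self):
        proto = _protocol()
        spikes = _spikeset(proto.pulse_times() + 0.0055)
        edges, h = psth(spikes, proto)
        assert h["u0"].max() == pytest.approx(1.0)
        peak_bin = edges[np.argmax(h["u0"])]
        assert peak_bin == pytest.approx(5.0)

    def test_bins_sum_to_firing_probability(self, rng):
        proto = make_pulse_protocol(n_sweeps=10)
        times = np.sort(rng.uniform(0, 100, 500))
        spikes = _spikeset(times)
        fp = firing_probability(spikes, proto)["u0"]
        edges, h = psth(spikes, proto, bin_ms=1.0, span_ms=(-10, 50))
        mask = (edges[:-1] >= 0) & (edges[:-1] < 20)
        assert h["u0"][mask].sum() == pytest.approx(fp, abs=1e-12)

    def test_nonresponder_histogram_flat_at_baseline(self, rng):
        proto = make_pulse_protocol(n_sweeps=50)
        rate = 20.0
        t = np.cumsum(rng.exponential(1 / rate, 20000))
        t = t[t < 510]
        edges, h = psth(_spikeset(t), proto, bin_ms=5.0)
        expected = rate * 0.005
        np.testing.assert_allclose(h["u0"], expected, atol=4 * np.sqrt(
            expected / (50 * 24)))


class TestModulationIndex:
    def _sweep_proto(self, n=20):
        return StimProtocol(kind="pulse", sweep_onsets=10.0 * np.arange(1, n + 1),
                            pulse_onsets=[0.0], ramp_duration_s=3.0)

    def test_doubled_rate_is_activated_third(self, rng):
        proto = self._sweep_proto(40)
        times = []
        for o in proto.sweep_onsets:
            times.extend(o - 3.0 + np.sort(rng.uniform(0, 3.0, rng.poisson(30))))
            times.extend(o + np.sort(rng.uniform(0, 3.0, rng.poisson(60))))
        r = modulation_index(_spikeset(np.sort(times)), proto, rng=0)["u0"]
        assert r.modulation_index == pytest.approx(1 / 3, abs=0.06)
        assert r.responder_class == "activated"

    def test_silent_during_gives_minus_one(self, rng):
        proto = self._sweep_proto(20)
        times = []
        for o in proto.sweep_onsets:
            times.extend(o - 3.0 + np.sort(rng.uniform(0, 2.9, 20)))
        r = modulation_index(_spikeset(np.sort(times)), proto, rng=0)["u0"]
        assert r.modulation_index == pytest.approx(-1.0)
        assert r.responder_class == "inhibited"

    def test_type_one_error_controlled(self, rng):
        """Identical pre/during rates stay 'unchanged' in >= 94 % of null
        simulations (permutation-test calibration, alpha = 0.05)."""
        proto = self._sweep_proto(10)
        unchanged = 0
        n_sim = 300
        for _ in range(n_sim):
            counts_pre = rng.poisson(9.0, 10)
            counts_dur = rng.poisson(9.0, 10)
            times = []
            for o, cp, cd in zip(proto.sweep_onsets, counts_pre, counts_dur):
                times.extend(o - 3.0 + np.sort(rng.uniform(0, 3.0, cp)))
                times.extend(o + np.sort(rng.uniform(0, 3.0, cd)))
            r = modulation_index(_spikeset(np.sort(times)), proto,
                                 n_perm=500, rng=rng)["u0"]
            unchanged += r.responder_class == "unchanged"
        assert unchanged / n_sim >= 0.94

    def test_too_few_sweeps_class_undefined(self):
        proto = self._sweep_proto(3)
        r = modulation_index(_spikeset([5.0, 15.0]), proto)["u0"]
        assert r.responder_class is None


class TestEvokedLfp:
    def test_synthetic_deflection_amplitude_and_latency(self, rng):
        fs = 1000.0
        proto = make_pulse_protocol(n_sweeps=13, rate_hz=8.0, period_s=10.0)
        n = int(fs * (proto.sweep_onsets[-1] + 10))
        x = rng.standard_normal(n) * 20.0
        kern = -40.0 * np.exp(-0.5 * ((np.arange(50) / fs - 0.015) / 0.004) ** 2)
        for p in proto.pulse_times():
            i = int(p * fs)
            x[i:i + len(kern)] += kern
        rec = Recording(x[None, :], fs, [ChannelInfo(0, "HP")])
        r = evoked_lfp(rec, proto, 0)
        assert r["amplitude_uv"] == pytest.approx(40.0, abs=3.0)
        assert r["latency_ms"] == pytest.approx(15.0, abs=2.0)

    def test_no_evoked_component_amplitude_near_noise_floor(self, rng):
        fs = 1000.0
        proto = make_pulse_protocol(n_sweeps=13)
        n = int(fs * (proto.sweep_onsets[-1] + 10))
        sd = 20.0
        rec = Recording((rng.standard_normal(n) * sd)[None, :], fs,
                        [ChannelInfo(0, "HP")])
        r = evoked_lfp(rec, proto, 0)
        floor = sd / np.sqrt(len(proto.pulse_times()))
        assert r["amplitude_uv"] < 5 * floor

    def test_zero_pulses_rejected(self, rng):
        rec = Recording(rng.standard_normal((1, 1000)), 1000.0,
                        [ChannelInfo(0, "HP")])
        proto = StimProtocol(kind="pulse", sweep_onsets=[], pulse_onsets=[])
        with pytest.raises(ValidationError):
            evoked_lfp(rec, proto, 0)


class TestCsd:
    def test_linear_profile_has_zero_interior_csd(self):
        v = np.outer(np.arange(16.0), np.ones(5)) * 3.0 + 7.0
        out = csd(v, spacing_um=50.0)
        np.testing.assert_allclose(out["csd"][1:-1], 0.0, atol=1e-9)

    def test_dipole_sink_localized(self, rng):
        w = laminar_dipole_weights(16, sink_channel=8, sep_channels=2)
        profile = np.outer(w, np.ones(20)) * (-30.0)
        profile += rng.standard_normal(profile.shape) * 0.5
        out = csd(profile, spacing_um=50.0)
        assert abs(out["sink_channel"] - 8) <= 1

    def test_two_channels_rejected(self):
        with pytest.raises(ValidationError):
            csd(np.zeros((2, 10)), 50.0)

    def test_conservation_for_dipolar_source(self):
        w = laminar_dipole_weights(16, sink_channel=8, sep_channels=2)
        out = csd(np.outer(w, np.ones(4)), spacing_um=50.0)
        interior = out["csd"][1:-1, 0]
        assert abs(interior.sum()) < 0.1 * np.abs(out["csd"]).max()


class TestRampChanges:
    def _components(self, rng, proto, fs=1000.0):
        n = int(fs * (proto.sweep_onsets[-1] + 10))
        nb = bandpass(rng.standard_normal(n), 14.0, 28.0, order=4, fs=fs)
        ob = bandpass(rng.standard_normal(n), 2.0, 9.0, order=4, fs=fs)
        return n, nb, ob

    def test_no_change_gives_zero(self):
        rng = np.random.default_rng(0)
        proto = make_ramp_protocol(n_sweeps=20, period_s=8.0, start_s=3.0)
        n, nb, ob = self._components(rng, proto)
        sig = nb + ob
        fs = 1000.0
        # make the test window an exact copy of the pre window per sweep
        for o in proto.sweep_onsets:
            pre = slice(int((o - 1.5) * fs), int(o * fs))
            last = slice(int((o + 1.5) * fs), int((o + 3.0) * fs))
            sig[last] = sig[pre]
        rec = Recording(sig[None, :], 1000.0, [ChannelInfo(0, "HP")])
        assert ramp_power_change(rec, proto, 0, (14, 28)) == pytest.approx(
            0.0, abs=1e-12)

    def test_power_doubling_gives_plus_one(self):
        rng = np.random.default_rng(1)
        proto = make_ramp_protocol(n_sweeps=40, period_s=8.0, start_s=3.0)
        n, nb, ob = self._components(rng, proto)
        sig = ob + nb
        fs = 1000.0
        for o in proto.sweep_onsets:
            i0, i1 = int((o + 1.5) * fs), int((o + 3.0) * fs)
            sig[i0:i1] = ob[i0:i1] + np.sqrt(2.0) * nb[i0:i1]
        rec = Recording(sig[None, :], fs, [ChannelInfo(0, "HP")])
        assert ramp_power_change(rec, proto, 0, (14, 28)) == pytest.approx(
            1.0, abs=0.25)

    def test_configured_gain_recovered(self):
        rng = np.random.default_rng(0)
        proto = make_ramp_protocol(n_sweeps=40, period_s=8.0, start_s=3.0)
        n, nb, ob = self._components(rng, proto)
        sig = ob + nb
        fs = 1000.0
        for o in proto.sweep_onsets:
            i0, i1 = int((o + 1.5) * fs), int((o + 3.0) * fs)
            sig[i0:i1] = ob[i0:i1] + np.sqrt(1.3) * nb[i0:i1]
        rec = Recording(sig[None, :], fs, [ChannelInfo(0, "HP")])
        assert ramp_power_change(rec, proto, 0, (14, 28)) == pytest.approx(
            0.3, abs=0.1)

    def test_coherence_gain_sign_detected(self):
        proto = make_ramp_protocol(n_sweeps=20, period_s=8.0, start_s=3.0)
        fs = 1000.0
        wins = 0
        n_seeds = 8
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            n = int(fs * (proto.sweep_onsets[-1] + 10))
            com = bandpass(r.standard_normal(n), 10.0, 20.0, order=4, fs=fs)
            x = com + 0.8 * r.standard_normal(n)
            y = 0.6 * com + 0.8 * r.standard_normal(n)
            for o in proto.sweep_onsets:
                i0, i1 = int((o + 1.5) * fs), int((o + 3.0) * fs)
                y[i0:i1] += 0.5 * com[i0:i1]
            rec = Recording(np.vstack([x, y]), fs,
                            [ChannelInfo(0, "LEC"), ChannelInfo(1, "HP")])
            wins += ramp_coherence_change(rec, proto, 0, 1, (10, 20)) > 0
        assert wins == n_seeds

    def test_identical_pre_during_coherence_near_zero(self, rng):
        proto = make_ramp_protocol(n_sweeps=20, period_s=8.0, start_s=3.0)
        fs = 1000.0
        n = int(fs * (proto.sweep_onsets[-1] + 10))
        com = bandpass(rng.standard_normal(n), 10.0, 20.0, order=4, fs=fs)
        x = com + 0.8 * rng.standard_normal(n)
        y = 0.6 * com + 0.8 * rng.standard_normal(n)
        rec = Recording(np.vstack([x, y]), fs,
                        [ChannelInfo(0, "LEC"), ChannelInfo(1, "HP")])
        assert abs(ramp_coherence_change(rec, proto, 0, 1, (10, 20))) < 0.1


class TestEepsc:
    fs = 20000.0

    def _alpha_sweeps(self, rng, amp=45.0, onset_ms=6.0, n=20, noise=1.0):
        t = np.arange(0, 0.08, 1 / self.fs)
        on = 0.02 + onset_ms / 1e3
        tau = 0.002
        alpha = np.where(t > on, (t - on) / tau * np.exp(1 - (t - on) / tau), 0)
        return np.stack([-amp * alpha + rng.standard_normal(len(t)) * noise
                         for _ in range(n)])

    def test_alpha_epsc_amplitude_and_onset(self, rng):
        f = eepsc_features(self._alpha_sweeps(rng), self.fs, 0.02)
        assert f.amplitude_pa == pytest.approx(45.0, abs=2.0)
        assert f.onset_latency_ms == pytest.approx(6.0, abs=0.5)
        assert f.responsive

    def test_identical_sweeps_have_zero_cv(self, rng):
        one = self._alpha_sweeps(rng, n=1, noise=0.0)
        sweeps = np.repeat(one, 20, axis=0)
        f = eepsc_features(sweeps, self.fs, 0.02)
        assert f.cv == pytest.approx(0.0, abs=1e-12)

    def test_flat_traces_not_responsive(self):
        f = eepsc_features(np.zeros((20, 1600)), self.fs, 0.02)
        assert not f.responsive
        assert f.amplitude_pa == pytest.approx(0.0)

    def test_single_sweep_rejected(self, rng):
        with pytest.raises(ValidationError):
            eepsc_features(self._alpha_sweeps(rng, n=1), self.fs, 0.02)
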