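"""Simulator behaviour: pulse trains, movement, aliasing, linked conditions."""

import numpy as np
import pytest

from megdbs.phantom import (SimConfig, _Components, acquire,
                            make_condition_set, simulate_dbs_train,
                            simulate_movement_waveform)
from megdbs.spectral import notch_waveform, welch_psd


@pytest.fixture(scope="module")
def short_config():
    return SimConfig(duration=10.0, n_channels=32, seed=3, stim_gain=4e-13)


class TestDbsTrain:
    def test_pulse_rate_matches_stimulation_frequency(self, short_config):
        train = simulate_dbs_train(short_config)
        fs = short_config.fs_internal
        one_second = train[: int(fs)]
        onsets = np.sum(np.diff((one_second > 0.5).astype(int)) == 1)
        # first pulse starts at t=0, so the rising-edge count is 129 or 130
        assert onsets in (129, 130)

    def test_each_pulse_is_charge_balanced(self, short_config):
        train = simulate_dbs_train(short_config)
        fs = short_config.fs_internal
        period = int(round(fs / short_config.f_stim))
        pulse = train[:period]
        assert abs(pulse.sum()) < 1e-9

    def test_spectrum_peaks_at_stimulation_harmonics(self, short_config):
        train = simulate_dbs_train(short_config)
        n = int(short_config.fs_internal)  # 1 s for 1 Hz resolution
        X = np.abs(np.fft.rfft(train[:n])) ** 2
        freqs = np.fft.rfftfreq(n, 1.0 / short_config.fs_internal)
        mask = (freqs > 50) & (freqs < 2000)
        peak_f = freqs[mask][np.argmax(X[mask])]
        assert abs(peak_f % short_config.f_stim) < 1.0 or \
            abs(short_config.f_stim - peak_f % short_config.f_stim) < 1.0
        # harmonic bins carry far more power than in-between bins
        harm = [X[int(round(k * 130))] for k in range(1, 10)]
        mid = [X[int(round(k * 130 + 65))] for k in range(1, 10)]
        assert np.mean(harm) > 100 * np.mean(mid)


class TestMovement:
    def test_event_count_and_amplitude(self):
        cfg = SimConfig(duration=120.0, n_channels=32, seed=1, stim_gain=1e-13)
        disp = simulate_movement_waveform(cfg)
        assert abs(disp.max() - 3e-3) < 1e-9
        # 120 s / 2.5 s = 48 inflation events
        onsets = np.sum(np.diff((disp > 1.5e-3).astype(int)) == 1)
        assert onsets == 48

    def test_power_concentrated_below_5hz(self, short_config):
        disp = simulate_movement_waveform(short_config)
        d = disp - disp.mean()
        X = np.abs(np.fft.rfft(d)) ** 2
        freqs = np.fft.rfftfreq(d.size, 1.0 / short_config.fs_out)
        assert X[freqs < 5].sum() / X.sum() > 0.6


class TestAcquire:
    def test_empty_room_flat_except_line_harmonics(self, short_config):
        rec = acquire(short_config, include=set())
        spec = welch_psd(rec)
        ml = np.log10(spec.power.mean(axis=0))
        f = spec.freqs
        line = np.zeros(f.size, dtype=bool)
        for k in range(1, 12):
            line |= np.abs(f - 50 * k) < 1.0
        # line bins protrude, the rest is flat white noise
        assert ml[line].max() > ml[~line & (f > 5)].mean() + 2
        flat = ml[~line & (f > 5) & (f < 1150)]
        assert flat.std() < 0.1

    def test_dipole_condition_has_12hz_peak(self, short_config):
        rec = acquire(short_config, include={"dipole"})
        spec = welch_psd(rec)
        ml = np.log10(spec.power.mean(axis=0))
        f = spec.freqs
        peak = ml[(f >= 11) & (f <= 13)].max()
        floor = ml[(f >= 20) & (f <= 40)].mean()
        assert peak > floor + 2

    def test_full_condition_shows_artefact_signatures(self, short_config):
        rec = acquire(short_config, include={"dipole", "stim", "movement_wire"})
        spec = welch_psd(rec)
        ml = np.log10(spec.power.mean(axis=0))
        f = spec.freqs
        ref = acquire(short_config, include={"dipole"})
        mlr = np.log10(welch_psd(ref).power.mean(axis=0))
        # 12 Hz dipole peak survives
        assert ml[(f >= 11) & (f <= 13)].max() > ml[(f >= 20) & (f <= 40)].mean() + 2
        # low-frequency movement artefact, strongest below 5 Hz
        lo = (f >= 1) & (f <= 5)
        hi = (f >= 10) & (f <= 15)
        assert ml[lo].mean() > mlr[lo].mean() + 0.5
        assert ml[lo].mean() - mlr[lo].mean() > ml[hi].mean() - mlr[hi].mean()
        # stimulation peak at 130 Hz
        assert ml[np.abs(f - 130) < 0.5].max() > ml[(f >= 100) & (f <= 120)].mean() + 1

    def test_aliased_peaks_not_at_stimulation_harmonics(self, short_config):
        comp = _Components(short_config)
        spec = welch_psd(comp.stim_wave_plain[None, :], fs=short_config.fs_out)
        ml = np.log10(spec.power[0])
        f = spec.freqs
        floor = np.median(ml)
        peaks = f[(ml > floor + 3) & (f > 1) & (f < 1190)]
        assert peaks.size > 0
        off_harmonic = [p for p in peaks
                        if min(p % 130.0, 130.0 - p % 130.0) > 2.0]
        assert len(off_harmonic) >= 1


class TestConditionSet:
    def test_reference_is_empty_room_plus_dipole(self, tiny_set):
        comp = _Components(tiny_set.config)
        dipole_term = np.outer(comp.dipole_topo, comp.dipole_wave)
        assert np.allclose(tiny_set.reference.data,
                           tiny_set.empty_room.data + dipole_term,
                           rtol=0, atol=1e-25)

    def test_dsmw_decomposes_into_reference_plus_artefact_terms(self, tiny_set):
        cfg = tiny_set.config
        comp = _Components(cfg)
        wire = np.outer(comp.wire_topo, comp.wire_wave)
        stim = cfg.stim_gain * np.outer(comp.stim_topo, comp.stim_wave_coupled)
        assert np.allclose(tiny_set.dsmw.data,
                           tiny_set.reference.data + wire + stim,
                           rtol=0, atol=1e-25)
        assert np.allclose(tiny_set.dmw.data,
                           tiny_set.reference.data + wire, rtol=0, atol=1e-25)

    def test_conditions_share_length_and_rate(self, tiny_set):
        recs = [tiny_set.reference, tiny_set.dmw, tiny_set.dsmw,
                tiny_set.empty_room]
        assert len({r.n_samples for r in recs}) == 1
        assert len({r.fs for r in recs}) == 1
        assert tiny_set.dbs_reference_channel.size == tiny_set.dsmw.n_samples

    def test_bit_identical_for_identical_config(self, tiny_config):
        a = make_condition_set(tiny_config)
        b = make_condition_set(tiny_config)
        assert np.array_equal(a.dsmw.data, b.dsmw.data)
        assert np.array_equal(a.dbs_reference_channel, b.dbs_reference_channel)

    def test_reference_channel_12hz_leak_removed_by_notch(self, tiny_set):
        fs = tiny_set.fs
        ref = tiny_set.dbs_reference_channel
        spec = welch_psd(ref[None, :], fs=fs)
        f = spec.freqs
        b = int(np.argmin(np.abs(f - tiny_set.config.f_dipole)))
        # detectable leak: the 12 Hz bin stands well above its neighbourhood
        neighbourhood = np.median(spec.power[0, b - 8:b + 9])
        assert spec.power[0, b] > 5 * neighbourhood
        notched = notch_waveform(ref, fs, tiny_set.config.f_dipole)
        spec_n = welch_psd(notched[None, :], fs=fs)
        # the notch takes out the dominant dipole leakage at that bin
        assert spec_n.power[0, b] < 0.1 * spec.power[0, b]


def test_consistent_sampling_of_pulses_warns():
    with pytest.warns(UserWarning, match="sampled consistently"):
        SimConfig(duration=5.0, f_stim=120.0, stim_gain=1e-13)
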