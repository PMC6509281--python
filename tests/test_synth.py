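import numpy as np
import pytest

from slowstates.core import StateLabel, TimeSeries
from slowstates.signal import hilbert_phase
from slowstates.synth import (SynthParams, generate_lfp, generate_opto_session,
                              generate_session, generate_spikes,
                              generate_states, generate_voltage_traces,
                              ideal_phase)


class TestStates:
    def test_cycle_frequency_in_slow_oscillation_band(self):
        states = generate_states(SynthParams(), 700.0, seed=1)
        cycles = [a.duration + b.duration
                  for a, b in zip(states[:-1], states[1:])
                  if a.label == StateLabel.DOWN]
        assert len(cycles) >= 500
        freq = np.mean(1.0 / np.array(cycles))
        assert 0.2 <= freq <= 1.0

    def test_near_deterministic_durations_give_fixed_alternation(self):
        p = SynthParams(up_mean=0.5, down_mean=0.5, up_shape=1e6,
                        down_shape=1e6)
        states = generate_states(p, 60.0, seed=2)
        durs = [iv.duration for iv in states[:-1]]
        assert np.allclose(durs, 0.5, atol=0.01)

    def test_same_seed_reproduces_interval_list(self):
        a = generate_states(SynthParams(), 60.0, seed=3)
        b = generate_states(SynthParams(), 60.0, seed=3)
        assert len(a) == len(b)
        assert all(x.start == y.start and x.end == y.end and x.label == y.label
                   for x, y in zip(a, b))

    def test_tiling_and_alternation(self):
        states = generate_states(SynthParams(), 30.0, seed=4)
        assert states[0].start == 0.0
        assert states[-1].end == pytest.approx(30.0)
        for a, b in zip(states[:-1], states[1:]):
            assert a.end == pytest.approx(b.start)
            assert a.label != b.label

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            generate_states(SynthParams(), -1.0, seed=0)
        with pytest.raises(ValueError):
            SynthParams(down_mean=0.0)


class TestLfp:
    def test_betagamma_rms_ratio_matches_configuration(self):
        p = SynthParams(pink_sd=0.0, betagamma_ratio=3.0)
        states = generate_states(p, 200.0, seed=5)
        lfp = generate_lfp(states, p, 1000.0, seed=6)
        from slowstates.core import StateSegmentation
        from slowstates.signal import elliptic_filter, running_rms
        band = elliptic_filter(lfp, "band", (10, 51))
        rms = running_rms(band, 0.005).samples
        labels = StateSegmentation(states, 1000.0).sample_labels(len(rms))
        # exclude 150 ms around transitions: envelope ramps plus the
        # band-pass filter's ringing smear the state contrast there
        interior = np.ones(len(rms), bool)
        for iv in states:
            i = int(iv.start * 1000)
            interior[max(i - 150, 0):i + 150] = False
        ratio = (np.mean(rms[(labels == 2) & interior])
                 / np.mean(rms[(labels == 0) & interior]))
        assert ratio == pytest.approx(3.0, rel=0.10)

    def test_zero_noise_range_is_delta_amplitude(self):
        p = SynthParams(pink_sd=0.0, betagamma_sd_down=0.0, delta_amp=1.5)
        states = generate_states(p, 30.0, seed=7)
        lfp = generate_lfp(states, p, 1000.0, seed=8)
        assert lfp.samples.max() == pytest.approx(1.5, abs=1e-9)
        assert lfp.samples.min() == pytest.approx(-1.5, abs=1e-9)

    def test_hilbert_phase_at_up_midpoints_near_180(self):
        p = SynthParams()
        states = generate_states(p, 300.0, seed=9)
        lfp = generate_lfp(states, p, 1000.0, seed=10)
        ph = hilbert_phase(lfp, (0.1, 4.0))
        mids = np.array([(iv.start + iv.end) / 2 for iv in states
                         if iv.label == StateLabel.UP
                         and 10 < iv.start < 290])
        circ_mean = np.angle(np.mean(np.exp(1j * ph.at_times(mids))))
        assert abs(np.rad2deg(circ_mean) % 360 - 180.0) < 15.0

    def test_low_rate_rejected(self):
        states = generate_states(SynthParams(), 10.0, seed=0)
        with pytest.raises(ValueError):
            generate_lfp(states, SynthParams(), rate=200.0)


class TestSpikes:
    def test_uncoupled_counts_match_state_rates(self):
        p = SynthParams(coupling_gain=0.0)
        states = generate_states(p, 600.0, seed=11)
        phase = ideal_phase(states, 1000.0)
        pv, vpm = generate_spikes(states, phase, p, seed=12)
        for train, r_up, r_dn in ((pv, p.pv_rate_up, p.pv_rate_down),
                                  (vpm, p.vpm_rate_up, p.vpm_rate_down)):
            for label, rate in ((StateLabel.UP, r_up), (StateLabel.DOWN, r_dn)):
                t_state = sum(iv.duration for iv in states if iv.label == label)
                n = sum(int(np.count_nonzero(iv.contains(train.times)))
                        for iv in states if iv.label == label)
                expected = rate * t_state
                assert abs(n - expected) < 3 * np.sqrt(expected)

    def test_pv_locking_stronger_than_vpm(self, short_session):
        from slowstates.phase import phase_locking
        ph = hilbert_phase(short_session.lfp, (0.1, 4.0))
        s_pv = phase_locking(ph, short_session.pv).locking_strength
        s_vpm = phase_locking(ph, short_session.vpm).locking_strength
        assert s_pv > s_vpm

    def test_coupling_lag_appears_in_down_state_delays(self):
        p = SynthParams(coupling_gain=1.0, coupling_lag=0.020)
        states = generate_states(p, 400.0, seed=13)
        phase = ideal_phase(states, 1000.0)
        pv, vpm = generate_spikes(states, phase, p, seed=14)
        downs = [iv for iv in states if iv.label == StateLabel.DOWN]
        delays = []
        for iv in downs:
            v = vpm.times[iv.contains(vpm.times)]
            pvt = pv.times[iv.contains(pv.times)]
            for t in pvt:
                d = t - v[(v < t) & (v > t - 0.06)]
                delays.extend(d)
        hist, edges = np.histogram(delays, bins=np.arange(0, 0.06, 0.005))
        peak = (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1]) / 2
        assert abs(peak - 0.020) <= 0.005

    def test_determinism_and_seed_sensitivity(self):
        p = SynthParams()
        states = generate_states(p, 60.0, seed=15)
        phase = ideal_phase(states, 1000.0)
        a1, _ = generate_spikes(states, phase, p, seed=16)
        a2, _ = generate_spikes(states, phase, p, seed=16)
        b, _ = generate_spikes(states, phase, p, seed=17)
        assert np.array_equal(a1.times, a2.times)
        assert not np.array_equal(a1.times, b.times)

    def test_overflowing_intensity_rejected(self):
        p = SynthParams(coupling_gain=1e4, coupling_sd=1e-4)
        states = generate_states(p, 60.0, seed=18)
        phase = ideal_phase(states, 1000.0)
        with pytest.raises(ValueError, match="coupling_gain"):
            generate_spikes(states, phase, p, seed=19)


class TestVoltageTraces:
    def test_zero_spikes_gives_pure_noise(self):
        from slowstates.core import SpikeTrain
        empty = SpikeTrain([], duration=5.0)
        jx, mua = generate_voltage_traces((empty, empty), SynthParams(),
                                          20000.0, seed=20)
        assert abs(jx.samples.std() - 1.0) < 0.02
        assert np.abs(jx.samples).max() < 6.0

    def test_overlap_regime_rejected(self):
        from slowstates.core import SpikeTrain
        dense = SpikeTrain(np.arange(0, 1.0, 0.005), duration=1.0)
        with pytest.raises(ValueError):
            generate_voltage_traces((dense, dense), SynthParams(), 20000.0)


class TestOptoSession:
    def test_programmed_latency_means(self):
        p = SynthParams()
        ses = generate_opto_session(p, 80, seed=21)
        lat = ses.truth.evoked_latencies
        lat = lat[np.isfinite(lat)]
        assert lat.size > 20
        assert np.mean(lat) == pytest.approx(0.11, abs=0.02)
        pm = p.muscimol_like()
        ses2 = generate_opto_session(pm, 80, seed=22)
        lat2 = ses2.truth.evoked_latencies
        lat2 = lat2[np.isfinite(lat2)]
        assert np.mean(lat2) == pytest.approx(0.25, abs=0.06)

    def test_onset_in_up_state_inserts_no_transition(self):
        ses = generate_opto_session(SynthParams(), 40, seed=23)
        labels = ses.truth.states.label_at(ses.truth.onsets)
        for lab, lat in zip(labels, ses.truth.evoked_latencies):
            if lab == StateLabel.UP:
                assert not np.isfinite(lat)

    def test_ground_truth_consistent_with_trace(self):
        ses = generate_opto_session(SynthParams(), 20, seed=24)
        assert ses.truth.states.extent[1] == pytest.approx(100.0)
        assert len(ses.lfp) == 100000
        assert len(ses.protocol) == 20


class TestSessionDeterminism:
    def test_full_session_reproducible(self):
        a = generate_session(SynthParams(), 30.0, seed=25)
        b = generate_session(SynthParams(), 30.0, seed=25)
        assert np.array_equal(a.lfp.samples, b.lfp.samples)
        assert np.array_equal(a.pv.times, b.pv.times)
        assert np.array_equal(a.vpm.times, b.vpm.times)
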