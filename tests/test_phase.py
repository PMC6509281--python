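import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from slowstates.core import (Interval, SpikeTrain, StateLabel,
                             StateSegmentation)
from slowstates.phase import (fit_von_mises, invert_a_ratio, locking_stats,
                              phase_locking, rayleigh_test, rescale_phases,
                              state_restricted_distribution)
from slowstates.signal import PhaseTrace


class TestRescalePhases:
    def test_uniform_trace_rescaling_is_near_identity(self, rng):
        trace = rng.uniform(-np.pi, np.pi, 100000)
        spikes = rng.uniform(-np.pi, np.pi, 200)
        out = rescale_phases(trace, spikes)
        assert np.max(np.abs(out - spikes)) < 2 * np.pi / np.sqrt(trace.size) * 5

    def test_any_trace_rescales_to_uniform(self, rng):
        from scipy import stats
        # strongly skewed phase occupancy
        trace = np.mod(rng.beta(0.5, 2.0, 50000) * 2 * np.pi, 2 * np.pi) - np.pi
        out = rescale_phases(trace, trace[::7])
        u = (out + np.pi) / (2 * np.pi)
        assert stats.kstest(u, "uniform").pvalue > 0.05

    def test_median_phase_maps_to_zero(self, rng):
        trace = rng.normal(1.0, 0.5, 10001)
        trace = np.clip(trace, -np.pi, np.pi - 1e-9)
        med = np.median(trace)
        out = rescale_phases(trace, np.array([med]))
        assert abs(out[0]) < 0.01

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            rescale_phases(np.array([]), np.array([0.0]))


class TestRayleigh:
    def test_balanced_quartet_is_uniform(self):
        p = rayleigh_test(np.deg2rad([0.0, 90.0, 180.0, 270.0]))
        assert p > 0.9

    def test_identical_angles_highly_significant(self):
        p = rayleigh_test(np.full(50, 1.3))
        assert p < 1e-10

    def test_von_mises_sample_detected(self):
        from scipy import stats
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            angles = stats.vonmises.rvs(1.4, size=200, random_state=r)
            hits += rayleigh_test(angles) < 0.01
        assert hits >= 19

    def test_too_few_angles_rejected(self):
        with pytest.raises(ValueError):
            rayleigh_test(np.array([0.1]))


class TestLockingStats:
    @pytest.mark.parametrize("angles_deg, expected", [
        ([90.0, 90.0, 90.0], (90.0, 1.0)),
        ([0.0, 90.0], (45.0, np.sqrt(2) / 2)),
        ([350.0, 10.0], (0.0, np.cos(np.deg2rad(10.0)))),
    ])
    def test_analytic_values(self, angles_deg, expected):
        pref, strength = locking_stats(np.deg2rad(angles_deg))
        assert pref % 360.0 == pytest.approx(expected[0] % 360.0, abs=1e-9)
        assert strength == pytest.approx(expected[1], abs=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.floats(-np.pi, np.pi),
           st.integers(2, 40),
           st.integers(0, 1000))
    def test_rotation_equivariance(self, delta, n, seed):
        r = np.random.default_rng(seed)
        angles = r.uniform(-np.pi, np.pi, n)
        p0, s0 = locking_stats(angles)
        p1, s1 = locking_stats(angles + delta)
        d = (p1 - p0 - np.rad2deg(delta)) % 360.0
        assert min(d, 360.0 - d) < 1e-6
        assert s1 == pytest.approx(s0, abs=1e-12)


class TestVonMises:
    def test_uniform_grid_gives_zero_kappa(self):
        angles = np.linspace(-np.pi, np.pi, 36, endpoint=False)
        mu, kappa = fit_von_mises(angles)
        assert kappa < 1e-6

    def test_parameter_recovery_at_fig_scale(self):
        from scipy import stats
        mu_true = np.deg2rad(188.0) - np.pi  # wrapped form
        r = np.random.default_rng(5)
        angles = stats.vonmises.rvs(1.38, loc=np.deg2rad(188.0), size=5000,
                                    random_state=r)
        mu, kappa = fit_von_mises(angles)
        d = abs(mu - 188.0) % 360.0
        assert min(d, 360.0 - d) < 5.0
        assert kappa == pytest.approx(1.38, abs=0.15)

    def test_kappa_inversion_against_grid_oracle(self):
        from scipy.special import i0, i1
        grid = np.linspace(1e-4, 120, 600000)
        a = i1(grid) / i0(grid)
        for rbar in (0.1, 0.3, 0.5, 0.7, 0.9, 0.99):
            oracle = grid[np.argmin(np.abs(a - rbar))]
            assert invert_a_ratio(rbar) == pytest.approx(oracle, abs=1e-3)

    def test_known_inversion_value(self):
        # A(kappa) = 0.5 at kappa ~ 1.159
        assert invert_a_ratio(0.5) == pytest.approx(1.159, abs=0.005)

    def test_agrees_with_scipy_vonmises_fit(self):
        from scipy import stats
        r = np.random.default_rng(9)
        angles = stats.vonmises.rvs(2.5, loc=0.7, size=3000, random_state=r)
        mu, kappa = fit_von_mises(angles)
        k_sp, loc_sp, _ = stats.vonmises.fit(angles, fscale=1)
        assert kappa == pytest.approx(k_sp, rel=0.02)
        d = abs(mu - np.rad2deg(loc_sp) % 360.0) % 360.0
        assert min(d, 360.0 - d) < 1.0


class TestPhaseLockingPipeline:
    def test_poisson_spikes_on_stationary_trace_not_locked(self):
        hits = 0
        n_runs = 100
        for seed in range(n_runs):
            r = np.random.default_rng(seed)
            phase = np.mod(np.cumsum(np.full(60000, 2 * np.pi * 0.8 / 1000.0))
                           + np.pi, 2 * np.pi) - np.pi
            pt = PhaseTrace(phase, 1000.0, (0.1, 4.0))
            times = np.sort(r.uniform(0, 59.9, 150))
            times = times[np.concatenate(([True], np.diff(times) > 0))]
            res = phase_locking(pt, SpikeTrain(times, duration=60.0))
            hits += res.rayleigh_p > 0.01
        assert hits >= 95

    def test_histogram_density_sums_to_one(self, short_session):
        from slowstates.signal import hilbert_phase
        pt = hilbert_phase(short_session.lfp)
        res = phase_locking(pt, short_session.pv)
        assert res.hist_density.sum() == pytest.approx(1.0)
        assert res.rayleigh_p < 0.01  # PV is strongly locked


class TestStateRestricted:
    def _fixture(self):
        ivs, t = [], 0.0
        for _ in range(20):
            ivs.append(Interval(t, t + 0.5, StateLabel.UP))
            ivs.append(Interval(t + 0.5, t + 1.0, StateLabel.DOWN))
            t += 1.0
        seg = StateSegmentation(ivs, 1000.0)
        # idealized phase: up sweeps [90, 270], down [270, 450)
        n = 20000
        phase = np.empty(n)
        tt = np.arange(n) / 1000.0
        frac = np.mod(tt, 0.5) / 0.5
        in_up = np.mod(tt, 1.0) < 0.5
        phase[in_up] = np.pi / 2 + frac[in_up] * np.pi
        phase[~in_up] = 3 * np.pi / 2 + frac[~in_up] * np.pi
        phase = np.mod(phase + np.pi, 2 * np.pi) - np.pi
        return seg, PhaseTrace(phase, 1000.0, (0.1, 4.0))

    def test_midpoint_spikes_have_median_relative_time_half(self):
        seg, pt = self._fixture()
        times = np.array([iv.start + 0.25 for iv in seg.of_label(StateLabel.UP)])
        dist = state_restricted_distribution(
            seg, pt, SpikeTrain(times, duration=20.0), StateLabel.UP)
        assert np.allclose(dist.relative_times, 0.5, atol=1e-6)
        assert dist.median_relative_time == pytest.approx(0.5)

    def test_down_range_wraps_through_zero(self):
        seg, pt = self._fixture()
        from slowstates.phase import _in_range_deg
        assert _in_range_deg(np.array([350.0]), 295.0, 75.0)[0]
        assert not _in_range_deg(np.array([200.0]), 295.0, 75.0)[0]

    def test_uniform_down_spikes_give_uniform_relative_times(self):
        from scipy import stats
        hits, runs = 0, 20
        for seed in range(runs):
            seg, pt = self._fixture()
            r = np.random.default_rng(seed)
            times = np.sort(np.concatenate(
                [iv.start + r.uniform(0.05, 0.45, 8)
                 for iv in seg.of_label(StateLabel.DOWN)]))
            times = times[np.concatenate(([True], np.diff(times) > 0))]
            dist = state_restricted_distribution(
                seg, pt, SpikeTrain(times, duration=20.0), StateLabel.DOWN)
            # the [295, 75] deg range keeps relative times in the span
            # [25/180, 165/180]; uniform-in-time spikes are uniform there
            counts, _ = np.histogram(dist.relative_times,
                                     bins=np.linspace(25 / 180, 165 / 180, 6))
            hits += stats.chisquare(counts).pvalue > 0.05
        assert hits >= runs - 2

    def test_no_spikes_flagged_empty(self):
        seg, pt = self._fixture()
        dist = state_restricted_distribution(
            seg, pt, SpikeTrain([], duration=20.0), StateLabel.DOWN)
        assert dist.empty
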