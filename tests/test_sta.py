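import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from slowstates.core import SpikeTrain, StateLabel
from slowstates.signal import RateTrace, kernel_ifr
from slowstates.sta import (STAParams, binomial_tail, fdr_bh,
                            generate_surrogates, normalized_variation,
                            pre_post_comparison, spike_triggered_analysis,
                            spike_triggered_ifr, surrogate_zscore,
                            window_means)


class TestSpikeTriggeredIfr:
    def test_self_alignment_peaks_at_zero_lag(self):
        train = SpikeTrain(np.arange(1.0, 59.0, 1.0), duration=60.0)
        ifr = kernel_ifr(train, 0.0125, 1000.0)
        lags, mean, sem, n = spike_triggered_ifr(ifr, train.times, 0.2)
        assert n == len(train)
        assert lags[np.argmax(mean)] == pytest.approx(0.0, abs=1e-9)
        assert mean.max() == pytest.approx(1 / (0.0125 * np.sqrt(2 * np.pi)),
                                           rel=0.01)

    def test_independent_triggers_give_flat_curve(self, rng):
        times = np.sort(rng.uniform(0.5, 99.5, 2000))
        times = times[np.concatenate(([True], np.diff(times) > 0))]
        ifr = kernel_ifr(SpikeTrain(times, duration=100.0), 0.0125, 1000.0)
        triggers = rng.uniform(1.0, 99.0, 100)
        lags, mean, sem, n = spike_triggered_ifr(ifr, triggers, 0.5)
        assert np.all(np.abs(mean - 20.0) < 3 * np.maximum(sem, 1e-9) + 1.0)

    def test_single_trigger_sem_zero(self):
        ifr = kernel_ifr(SpikeTrain([0.5], duration=1.0), 0.0125, 1000.0)
        lags, mean, sem, n = spike_triggered_ifr(ifr, np.array([0.5]), 0.2)
        assert n == 1
        assert np.all(sem == 0)

    def test_no_usable_triggers_rejected(self):
        ifr = kernel_ifr(SpikeTrain([0.5], duration=1.0), 0.0125, 1000.0)
        with pytest.raises(ValueError):
            spike_triggered_ifr(ifr, np.array([0.1]), 0.5)


class TestWindowMeans:
    def test_time_reversal_swaps_pre_and_post_exactly(self, rng):
        values = rng.uniform(0, 10, 5000)
        ifr = RateTrace(values, 1000.0, 0.0125)
        triggers = np.array([1.0, 2.5, 3.25])
        pre, post = window_means(ifr, triggers, 0.1)
        rev = RateTrace(values[::-1].copy(), 1000.0, 0.0125)
        rev_triggers = (values.size - 1) / 1000.0 - triggers[::-1]
        pre_r, post_r = window_means(rev, rev_triggers, 0.1)
        assert np.allclose(pre, post_r[::-1], atol=1e-12)
        assert np.allclose(post, pre_r[::-1], atol=1e-12)


class TestSurrogates:
    def test_constraints_hold_for_every_member(self, uncoupled_session):
        ses = uncoupled_session
        seg = ses.truth.states
        ifr = kernel_ifr(ses.vpm, 0.0125, 1000.0)
        params = STAParams(n_surrogates=20)
        ens = generate_surrogates(seg, ses.pv, ses.phase, ifr, params, seed=3)
        downs = seg.of_label(StateLabel.DOWN)
        silent = [iv for iv in downs
                  if not np.any(iv.contains(ses.pv.times))]
        n_real = sum(int(np.count_nonzero(iv.contains(ses.pv.times)))
                     for iv in downs)
        for ts_k in ens.spike_sets:
            assert ts_k.size == n_real
            inside = np.zeros(ts_k.size, bool)
            for iv in silent:
                inside |= iv.contains(ts_k)
            assert inside.all()
            per_state = [int(np.count_nonzero(iv.contains(ts_k)))
                         for iv in silent]
            assert max(per_state) <= ens.max_spikes_per_state

    def test_surrogate_phases_match_real_distribution(self, uncoupled_session):
        from scipy import stats
        ses = uncoupled_session
        seg = ses.truth.states
        ifr = kernel_ifr(ses.vpm, 0.0125, 1000.0)
        ens = generate_surrogates(seg, ses.pv, ses.phase, ifr,
                                  STAParams(n_surrogates=10), seed=4)
        downs = seg.of_label(StateLabel.DOWN)
        mask = np.zeros(len(ses.pv), bool)
        for iv in downs:
            mask |= iv.contains(ses.pv.times)
        real = ses.phase.at_times(ses.pv.times[mask])
        pooled = ses.phase.at_times(np.concatenate(ens.spike_sets))
        assert stats.ks_2samp(real, pooled).pvalue > 0.05

    def test_insufficient_capacity_rejected(self, uncoupled_session):
        ses = uncoupled_session
        with pytest.raises(ValueError, match="surrogate"):
            generate_surrogates(ses.truth.states, ses.pv, ses.phase,
                                kernel_ifr(ses.vpm, 0.0125, 1000.0),
                                STAParams(min_state_factor=50.0), seed=5)


class TestZScore:
    def test_real_equal_to_surrogate_mean_gives_half_p(self):
        z, p = surrogate_zscore(5.0, np.array([4.0, 5.0, 6.0]))
        assert z == 0.0
        assert p == pytest.approx(0.5)

    def test_zero_spread_rejected(self):
        with pytest.raises(ValueError):
            surrogate_zscore(5.0, np.full(10, 5.0))


class TestPrePost:
    def test_causal_coupling_raises_pre_over_post(self):
        from slowstates.synth import SynthParams, generate_session
        ses = generate_session(SynthParams(coupling_gain=0.5), 200.0,
                               seed=40, with_lfp=False)
        seg = ses.truth.states
        ifr = kernel_ifr(ses.vpm, 0.0125, 1000.0)
        downs = seg.of_label(StateLabel.DOWN)
        mask = np.zeros(len(ses.pv), bool)
        for iv in downs:
            mask |= iv.contains(ses.pv.times)
        res = pre_post_comparison(ifr, ses.pv.times[mask], 0.1)
        assert res["pre_mean"] > res["post_mean"]
        assert res["p"] < 0.05

    def test_independent_triggers_pvalues_uniform(self):
        from scipy import stats
        pvals = []
        for seed in range(100):
            r = np.random.default_rng(seed)
            times = np.sort(r.uniform(0, 60, 600))
            times = times[np.concatenate(([True], np.diff(times) > 0))]
            ifr = kernel_ifr(SpikeTrain(times, duration=60.0), 0.0125, 1000.0)
            triggers = r.uniform(0.5, 59.5, 40)
            res = pre_post_comparison(ifr, triggers, 0.1,
                                      alternative="two-sided")
            pvals.append(res["p"])
        # approximately uniform: calibrated rejection rate and centered mean
        # (the signed-rank p is mildly discrete at 40 triggers, so an exact
        # KS-uniformity requirement is too strict)
        pvals = np.asarray(pvals)
        assert 0.0 <= np.mean(pvals < 0.05) <= 0.12
        assert abs(pvals.mean() - 0.5) < 0.06


class TestNormalizedVariation:
    @pytest.mark.parametrize("pre, expected", [
        (10.0, 0.0), (20.0, 100.0), (0.0, -100.0)])
    def test_scaling(self, pre, expected):
        nv_pre, _ = normalized_variation(pre, 10.0, 10.0)
        assert nv_pre == pytest.approx(expected)

    def test_zero_surrogate_mean_rejected(self):
        with pytest.raises(ValueError):
            normalized_variation(1.0, 1.0, 0.0)


def _bh_oracle(pvals, alpha):
    """Exhaustive step-up: largest k with p_(k) <= k alpha / m."""
    m = len(pvals)
    order = np.argsort(pvals)
    sorted_p = np.asarray(pvals)[order]
    k_star = 0
    for k in range(1, m + 1):
        if sorted_p[k - 1] <= k * alpha / m:
            k_star = k
    rejected = np.zeros(m, bool)
    rejected[order[:k_star]] = True
    return rejected


class TestFdrBh:
    def test_hand_checkable_example(self):
        rejected, adj = fdr_bh([0.001, 0.02, 0.04], alpha=0.05)
        assert rejected.all()

    def test_all_ones_none_rejected(self):
        rejected, _ = fdr_bh([1.0, 1.0, 1.0])
        assert not rejected.any()

    def test_single_p_is_raw(self):
        rejected, adj = fdr_bh([0.04], alpha=0.05)
        assert rejected[0]
        assert adj[0] == pytest.approx(0.04)

    def test_matches_exhaustive_oracle_on_grid_subsets(self):
        grid = [0.001, 0.008, 0.02, 0.04, 0.06, 0.2, 0.5, 0.9]
        for size in range(1, 9):
            for subset in itertools.combinations(grid, size):
                got, _ = fdr_bh(list(subset), alpha=0.05)
                want = _bh_oracle(list(subset), 0.05)
                assert np.array_equal(got, want), subset

    def test_adjusted_monotone_in_rank(self, rng):
        p = rng.uniform(0, 1, 30)
        _, adj = fdr_bh(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.2])


class TestBinomialTail:
    def test_population_combination_values(self):
        # printed population-level p-values for 18 recordings at alpha 0.05
        assert binomial_tail(18, 11, 0.05) == pytest.approx(1.12e-10,
                                                            rel=5e-3)
        assert binomial_tail(18, 2, 0.05) == pytest.approx(0.2265, abs=5e-5)
        assert binomial_tail(18, 3, 0.05) == pytest.approx(0.0581, abs=5e-5)

    def test_trivial_cases(self):
        assert binomial_tail(18, 0, 0.05) == 1.0
        assert binomial_tail(5, 5, 0.5) == pytest.approx(0.03125)

    def test_k_above_n_rejected(self):
        with pytest.raises(ValueError):
            binomial_tail(5, 6, 0.5)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.integers(1, 25), st.data(),
           st.floats(0.01, 0.99))
    def test_matches_brute_force_summation(self, n, data, p0):
        from math import comb
        k = data.draw(st.integers(0, n))
        brute = sum(comb(n, i) * p0**i * (1 - p0)**(n - i)
                    for i in range(k, n + 1))
        assert binomial_tail(n, k, p0) == pytest.approx(brute, rel=1e-12,
                                                        abs=1e-300)


class TestFullPipeline:
    def test_coupled_session_detected(self):
        from slowstates.synth import SynthParams, generate_session
        ses = generate_session(SynthParams(), 240.0, seed=50, with_lfp=False)
        res = spike_triggered_analysis(ses.truth.states, ses.pv, ses.vpm,
                                       ses.phase, seed=50)
        assert res.p_pre < 0.05
        assert res.norm_variation_pre_pct > res.norm_variation_post_pct

    def test_recovery_of_programmed_lag(self):
        # peak of (real - surrogate mean) curve within lag +- 10 ms pre-trigger
        from slowstates.synth import SynthParams, generate_session
        from slowstates.sta import STAParams
        hits = 0
        for lag, seed in ((0.010, 60), (0.020, 61), (0.040, 62)):
            p = SynthParams(coupling_lag=lag, coupling_gain=0.15)
            ses = generate_session(p, 240.0, seed=seed, with_lfp=False)
            res = spike_triggered_analysis(ses.truth.states, ses.pv, ses.vpm,
                                           ses.phase,
                                           STAParams(curve_halfwidth=0.15),
                                           seed=seed)
            pre_lags = res.lags[res.lags < 0]
            pre_curve = res.mean_curve[res.lags < 0]
            peak = pre_lags[np.argmax(pre_curve)]
            hits += abs(-peak - lag) <= 0.010
        assert hits >= 2
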