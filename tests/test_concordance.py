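import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from socksig.concordance import (
    association_screen,
    extra_event_count,
    full_signal_correlation,
    lag_statistics,
    match_peaks,
    windowed_scr_correlations,
)
from socksig.io import SignalRecord
from socksig.simulate import EdaSimConfig, simulate_dual_site_eda
from conftest import brute_force_match


class TestMatchPeaks:
    def test_closest_assignment_example(self):
        res = match_peaks([10.0, 20.0, 30.0], [10.5, 29.0])
        assert [(r, t) for r, t, _ in res.pairs] == [(10.0, 10.5), (30.0, 29.0)]
        assert res.consensus == pytest.approx(2 / 3)
        assert res.unmatched_ref == [20.0]

    def test_equidistant_tie_goes_to_earlier_reference(self):
        res = match_peaks([10.0, 13.0], [11.5])
        assert res.pairs == [(10.0, 11.5, 1.5)]
        assert res.consensus == pytest.approx(0.5)

    def test_empty_test_side(self):
        res = match_peaks([10.0], [])
        assert res.consensus == 0.0 and res.unmatched_ref == [10.0]

    def test_each_test_peak_used_once(self):
        res = match_peaks([10.0, 11.0, 12.0], [11.2])
        assert len(res.pairs) == 1
        assert res.pairs[0][0] == 11.0

    def test_agrees_with_brute_force_on_random_instances(self, rng):
        """Exclusive matching is optimal (max pairs, min total |lag|)."""
        for _ in range(300):
            n_ref = int(rng.integers(0, 7))
            n_test = int(rng.integers(0, 7))
            ref = np.sort(rng.uniform(0, 30, n_ref))
            test = np.sort(rng.uniform(0, 30, n_test))
            res = match_peaks(ref, test, half_window=2.0)
            n_opt, total_opt = brute_force_match(ref, test, 2.0)
            assert len(res.pairs) == n_opt
            total = sum(abs(l) for _, _, l in res.pairs)
            assert total == pytest.approx(total_opt, abs=1e-9)

    def test_greedy_trap_instance_still_optimal(self):
        # nearest-first pairing would find only one pair here
        res = match_peaks([0.0, 1.0], [-1.5, 0.1], half_window=2.0)
        assert len(res.pairs) == 2

    @settings(derandomize=True, max_examples=50)
    @given(shift=st.floats(-1e3, 1e3, allow_nan=False))
    def test_consensus_translation_invariant(self, shift):
        ref = np.array([5.0, 9.0, 20.0])
        test = np.array([5.5, 12.0, 19.0])
        a = match_peaks(ref, test)
        b = match_peaks(ref + shift, test + shift)
        assert a.consensus == b.consensus

    def test_strict_rule_discards_crowded_windows(self):
        # two free foot peaks inside the window of ref 10 -> discarded
        res = match_peaks([10.0, 30.0], [9.0, 10.2, 11.0, 29.5], rule="strict")
        assert all(r != 10.0 for r, _, _ in res.pairs)
        assert (30.0, 29.5, -0.5) in res.pairs

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError):
            match_peaks([3.0, 1.0], [2.0])

    def test_negative_window_rejected(self):
        with pytest.raises(ValueError):
            match_peaks([1.0], [2.0], half_window=-1.0)


class TestLagStatistics:
    def test_constant_lags(self):
        res = match_peaks([10.0, 20.0, 30.0], [10.4, 20.4, 30.4])
        ls = lag_statistics(res)
        assert ls.mean == pytest.approx(0.4)
        assert ls.sd == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_lags_cancel(self):
        res = match_peaks([10.0, 20.0], [9.0, 21.0])
        assert lag_statistics(res).mean == pytest.approx(0.0)

    def test_no_pairs_flagged_undefined(self):
        ls = lag_statistics(match_peaks([1.0], [100.0]))
        assert not ls.defined and np.isnan(ls.mean)

    def test_planted_lag_recovered_within_three_se(self):
        """Synthetic shared events with lag N(0.41, 0.1) recover the mean."""
        lags = []
        for seed in range(10):
            cfg = EdaSimConfig(
                duration=300, sampling_rate=8, p_shared=1.0, event_rate=6.0,
                foot_lag_mean=0.41, foot_lag_sd=0.1, seed=seed,
            )
            _, _, truth = simulate_dual_site_eda(cfg)
            m = match_peaks(truth.hand_scr_times, np.sort(truth.foot_scr_times))
            lags.extend(lag_statistics(m).lags)
        lags = np.asarray(lags)
        assert lags.size >= 200
        se = lags.std(ddof=1) / np.sqrt(lags.size)
        assert abs(lags.mean() - 0.41) <= 3 * se


class TestFullSignalCorrelation:
    def test_affine_invariance(self, rng):
        x = rng.normal(0, 1, 1000)
        a = SignalRecord(x, 100.0)
        b = SignalRecord(2 * x + 3, 100.0)
        assert full_signal_correlation(a, b) == pytest.approx(1.0)

    def test_anticorrelated(self, rng):
        x = rng.normal(0, 1, 1000)
        assert full_signal_correlation(
            SignalRecord(x, 100.0), SignalRecord(-x, 100.0)
        ) == pytest.approx(-1.0)

    def test_independent_noise_near_zero(self, rng):
        a = SignalRecord(rng.normal(0, 1, 300_000), 1000.0)
        b = SignalRecord(rng.normal(0, 1, 300_000), 1000.0)
        assert abs(full_signal_correlation(a, b)) < 0.01

    def test_constant_input_flagged(self):
        with pytest.warns(UserWarning):
            r = full_signal_correlation(
                SignalRecord(np.ones(100), 10.0),
                SignalRecord(np.arange(100.0), 10.0),
            )
        assert np.isnan(r)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            full_signal_correlation(
                SignalRecord(np.ones(10), 10.0), SignalRecord(np.ones(11), 10.0)
            )


class TestWindowedCorrelations:
    def test_identical_signals_give_unit_r(self, rng):
        fs = 100.0
        x = rng.normal(0, 1, 3000).cumsum()  # non-constant in every window
        rec = SignalRecord(x, fs)
        m = match_peaks([10.0, 20.0], [10.1, 20.1])
        out = windowed_scr_correlations(rec, rec, m)
        assert len(out) == 2
        assert all(w.pearson_r == pytest.approx(1.0) for w in out)

    def test_delayed_event_decorrelates_window(self):
        fs = 100.0
        t = np.arange(0, 40, 1 / fs)
        bump = np.exp(-0.5 * ((t - 20.0) / 0.7) ** 2)
        delayed = np.exp(-0.5 * ((t - 22.1) / 0.7) ** 2)
        m = match_peaks([20.0], [21.9])
        (w,) = windowed_scr_correlations(
            SignalRecord(bump, fs), SignalRecord(delayed, fs), m
        )
        assert w.pearson_r < 0.2

    def test_edge_window_dropped(self, rng):
        fs = 100.0
        x = rng.normal(0, 1, 3000).cumsum()
        rec = SignalRecord(x, fs)
        m = match_peaks([1.0, 15.0], [1.2, 15.2])  # 1.0 - 2.0 < 0: clipped
        out = windowed_scr_correlations(rec, rec, m)
        assert len(out) == 1
        assert out[0].ref_peak_time == 15.0


class TestExtraEventCount:
    def test_all_matched_counts_zero(self):
        assert extra_event_count([10.0, 20.0], [10.5, 19.5]) == 0

    def test_isolated_test_event_counts(self):
        assert extra_event_count([10.0], [10.5, 50.0]) == 1

    def test_empty_reference(self):
        assert extra_event_count([], [1.0, 2.0, 3.0]) == 3


class TestAssociationScreen:
    def test_identity_candidate_perfect_pearson(self, rng):
        y = rng.normal(0, 1, 20)
        (res,) = association_screen(
            {"same": y}, {"same": "continuous"}, y
        )
        assert res.test_name == "Pearson"
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value < 0.05

    def test_monotone_ordinal_perfect_spearman(self, rng):
        y = rng.normal(0, 1, 20)
        (res,) = association_screen(
            {"rank": np.exp(y)}, {"rank": "ordinal"}, y
        )
        assert res.test_name == "Spearman"
        assert res.statistic == pytest.approx(1.0)

    def test_group_comparison_routes_by_normality(self, rng):
        y = np.concatenate([rng.normal(0, 1, 15), rng.normal(2, 1, 15)])
        g = np.array([0] * 15 + [1] * 15)
        (res,) = association_screen({"grp": g}, {"grp": "binary-group"}, y)
        assert res.test_name in ("ANOVA", "Mann-Whitney U")
        assert res.p_value < 0.05

    def test_null_mannwhitney_p_uniform(self, rng):
        """Same-distribution groups yield uniform p-values over repeats."""
        pvals = []
        for _ in range(200):
            g0 = rng.normal(0, 1, 500)
            g1 = rng.normal(0, 1, 500)
            pvals.append(stats.mannwhitneyu(g0, g1, alternative="two-sided").pvalue)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_constant_candidate_flagged(self, rng):
        y = rng.normal(0, 1, 10)
        (res,) = association_screen(
            {"const": np.ones(10)}, {"const": "continuous"}, y
        )
        assert res.test_name == "undefined" and np.isnan(res.p_value)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            association_screen({"x": [1, 2]}, {"x": "continuous"}, [1.0, 2.0])


class TestConsensusRecovery:
    def test_consensus_tracks_planted_sharing(self):
        """Consensus over many seeds falls in the binomial 99% CI of p_shared."""
        p = 0.7
        pairs = refs = 0
        for seed in range(50):
            cfg = EdaSimConfig(
                duration=300, sampling_rate=8, p_shared=p, event_rate=3.0,
                foot_lag_mean=0.41, foot_lag_sd=0.1, seed=seed,
            )
            _, _, truth = simulate_dual_site_eda(cfg)
            if truth.hand_scr_times.size == 0:
                continue
            m = match_peaks(truth.hand_scr_times, np.sort(truth.foot_scr_times))
            pairs += len(m.pairs)
            refs += m.n_ref
        lo, hi = stats.binom.interval(0.99, refs, p)
        assert lo <= pairs <= hi
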