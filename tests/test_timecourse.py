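"""Timecourses: binning, FDR, difference waveforms, cluster permutation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from rivaltouch.config import TimecourseSpec
from rivaltouch.preprocess import clean_trace
from rivaltouch.timecourse import (
    bin_tests,
    cluster_permutation_test,
    congruency_trace,
    difference_waveform,
    find_clusters,
    participant_timecourses,
)
from rivaltouch.trace import LEFT, NONE, RIGHT, TactileEvent

from test_preprocess import make_trace
from test_segments import event


SPEC = TimecourseSpec()


def tc_frame(data: np.ndarray) -> pd.DataFrame:
    rows = []
    for i, trace in enumerate(data):
        row = {"participant_id": f"P{i:02d}", "condition": "c"}
        row.update({f"bin{b:02d}": trace[b] for b in range(data.shape[1])})
        rows.append(row)
    return pd.DataFrame(rows)


class TestCongruencyTrace:
    def test_fully_congruent_segment_is_all_ones(self):
        tr = clean_trace(make_trace([(0, 30, RIGHT)]))
        probs = congruency_trace(tr, event(5, RIGHT), 9.0)
        assert np.allclose(probs, 1.0)

    def test_midpoint_switch_halves_the_trace(self):
        # incongruent until exactly the segment midpoint, congruent after
        L = 9.0
        tr = clean_trace(make_trace([(0, 5 + L / 2, LEFT), (5 + L / 2, 30, RIGHT)]))
        probs = congruency_trace(tr, event(5, RIGHT), L)
        assert np.allclose(probs[:18], 0.0)
        assert np.allclose(probs[18:], 1.0)

    def test_boundary_bin_is_time_weighted(self):
        """Brute-force time integration on a constructed trace."""
        L, onset = 9.0, 5.0
        switch = onset + 0.51 * L  # inside bin 18
        tr = clean_trace(make_trace([(0, switch, LEFT), (switch, 30, RIGHT)]))
        probs = congruency_trace(tr, event(onset, RIGHT), L)
        edges = onset + np.linspace(0, L, 37)
        expected = np.empty(36)
        for b in range(36):
            lo, hi = edges[b], edges[b + 1]
            congruent = max(0.0, hi - max(lo, switch))
            expected[b] = congruent / (hi - lo)
        assert np.allclose(probs, expected)

    def test_mixed_time_excluded_by_weighting(self):
        tr = clean_trace(
            make_trace([(0, 6, RIGHT), (6, 8, NONE), (8, 30, RIGHT)])
        )
        probs = congruency_trace(tr, event(5, RIGHT), 9.0)
        assert np.allclose(probs[~np.isnan(probs)], 1.0)
        # bins fully inside the NONE gap have no dominance time
        gap_bins = np.isnan(probs)
        assert gap_bins.any()

    def test_truncated_segment_raises(self):
        tr = clean_trace(make_trace([(0, 10, RIGHT)]))
        with pytest.raises(ValueError, match="truncated"):
            congruency_trace(tr, event(5, RIGHT), 9.0)

    def test_null_traces_hover_at_chance(self, clean_null_dataset):
        cfg, clean, events = clean_null_dataset
        tc = participant_timecourses(
            clean, events, SPEC, cfg.switcher_profile()
        )
        cols = [f"bin{i:02d}" for i in range(36)]
        grand = tc[cols].to_numpy().mean()
        assert abs(grand - 0.5) < 0.05

    def test_averaging_order_segments_then_participants(self):
        """The participant trace is the mean of segment traces, missing
        bins excluded per segment."""
        tr1 = clean_trace(make_trace([(0, 30, RIGHT)]))  # all congruent
        tr2 = clean_trace(
            make_trace([(0, 30, LEFT)], trial_id="t2")
        )  # all incongruent
        events = {
            "t1": [event(5, RIGHT, trial_id="t1")],
            "t2": [event(5, RIGHT, trial_id="t2")],
        }
        tc = participant_timecourses(
            [tr1, tr2], events, SPEC, {"P1": "slow"}
        )
        cols = [f"bin{i:02d}" for i in range(36)]
        assert np.allclose(tc[cols].to_numpy(), 0.5)


def brute_force_bh(pvals: np.ndarray, alpha: float) -> np.ndarray:
    """Definitional Benjamini–Hochberg: largest k with p_(k) <= k/m * alpha;
    reject the k smallest p-values."""
    m = len(pvals)
    order = np.argsort(pvals)
    k_max = 0
    for k in range(1, m + 1):
        if pvals[order[k - 1]] <= k / m * alpha:
            k_max = k
    mask = np.zeros(m, dtype=bool)
    mask[order[:k_max]] = True
    return mask


class TestBinTests:
    def test_constant_chance_bins_not_significant(self):
        data = np.full((8, 36), 0.5)
        data += np.linspace(0, 1e-12, 8)[:, None]  # avoid exact zero variance
        res = bin_tests(tc_frame(data), SPEC)
        assert not res.significant.any()

    def test_zero_variance_bin_masked(self):
        data = np.random.default_rng(0).uniform(0.4, 0.6, (8, 36))
        data[:, 3] = 0.7  # identical across participants
        res = bin_tests(tc_frame(data), SPEC)
        assert not res.tested[3]
        assert np.isnan(res.p_fdr[3])

    def test_bh_mask_matches_definitional_oracle(self):
        rng = np.random.default_rng(2)
        # strong offsets in the first bins produce a mix of p-values
        data = rng.normal(0.5, 0.05, (10, 36))
        data[:, :6] += 0.12
        res = bin_tests(tc_frame(data), SPEC)
        expected = brute_force_bh(res.p, SPEC.alpha_bin)
        assert np.array_equal(res.significant, expected)

    def test_significant_duration_arithmetic(self):
        data = np.random.default_rng(3).normal(0.5, 0.02, (10, 36))
        data[:, :8] = 0.9  # 8 clearly significant bins
        data += np.random.default_rng(4).normal(0, 1e-3, data.shape)
        res = bin_tests(tc_frame(data), SPEC)
        n_sig = int(res.significant.sum())
        assert n_sig == 8
        assert res.significant_duration_s["slow"] == pytest.approx(
            n_sig * 9.0 / 36
        )
        assert res.significant_duration_s["slow"] == pytest.approx(2.0)

    def test_bins_with_too_few_participants_masked(self):
        data = np.random.default_rng(5).uniform(0.3, 0.7, (6, 36))
        data[1:, 10] = np.nan
        res = bin_tests(tc_frame(data), SPEC)
        assert not res.tested[10]


class TestDifferenceWaveform:
    def test_identical_conditions_zero(self):
        data = np.random.default_rng(0).uniform(0, 1, (6, 36))
        d = difference_waveform(tc_frame(data), tc_frame(data))
        cols = [c for c in d.columns if c.startswith("bin")]
        assert np.allclose(d[cols].to_numpy(), 0.0)

    def test_antisymmetric_under_swap(self):
        rng = np.random.default_rng(1)
        a, b = tc_frame(rng.uniform(0, 1, (6, 36))), tc_frame(
            rng.uniform(0, 1, (6, 36))
        )
        cols = [f"bin{i:02d}" for i in range(36)]
        d1 = difference_waveform(a, b)[cols].to_numpy()
        d2 = difference_waveform(b, a)[cols].to_numpy()
        assert np.allclose(d1, -d2)

    def test_missing_propagates(self):
        a = tc_frame(np.full((3, 36), 0.6))
        b = tc_frame(np.full((3, 36), 0.4))
        a.loc[0, "bin05"] = np.nan
        d = difference_waveform(a, b)
        assert np.isnan(d.loc[0, "bin05"])
        assert d.loc[1, "bin05"] == pytest.approx(0.2)


def brute_force_clusters(t, threshold, tested):
    """Independent run-length scan for maximal same-sign supra-threshold runs."""
    out = []
    b = 0
    n = len(t)
    while b < n:
        if tested[b] and abs(t[b]) > threshold[b]:
            sign = 1 if t[b] > 0 else -1
            start = b
            mass = 0.0
            while (
                b < n
                and tested[b]
                and abs(t[b]) > threshold[b]
                and (1 if t[b] > 0 else -1) == sign
            ):
                mass += t[b]
                b += 1
            out.append((start, b - 1, sign, mass))
        else:
            b += 1
    return out


class TestClusterFormation:
    @given(st.integers(0, 10_000))
    def test_matches_brute_force_on_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(1, 40)
        t = rng.normal(0, 2.5, n)
        thr = np.full(n, 1.5)
        tested = rng.random(n) > 0.15
        got = [
            (c.start_bin, c.end_bin, c.sign, c.mass)
            for c in find_clusters(np.where(tested, t, 0.0), thr, tested)
        ]
        expected = brute_force_clusters(t, thr, tested)
        assert [(a, b, s) for a, b, s, _ in got] == [
            (a, b, s) for a, b, s, _ in expected
        ]
        assert np.allclose(
            [m for *_, m in got], [m for *_, m in expected]
        )

    def test_all_zero_differences_no_clusters(self):
        d = tc_frame(np.zeros((6, 36)))
        res = cluster_permutation_test(
            d, n_perm=200, rng=np.random.default_rng(0)
        )
        assert res.observed_clusters == []
        assert res.significant_clusters == []


class TestClusterPermutation:
    def test_exhaustive_enumeration_matches_independent_oracle(self):
        """n = 5: all 2^5 sign flips enumerated; cluster p equals a fully
        independent enumeration, and Monte-Carlo p agrees within sampling
        error."""
        rng = np.random.default_rng(6)
        data = rng.normal(0.08, 0.1, (5, 36))
        data[:, 5:12] += 0.25  # a real cluster
        d = tc_frame(data)
        res = cluster_permutation_test(d, exhaustive=True)
        assert res.n_permutations == 32

        # independent oracle: recompute everything from scratch
        thr = stats.t.ppf(0.975, 4)
        maxima = []
        for signs in itertools.product((1.0, -1.0), repeat=5):
            flipped = data * np.array(signs)[:, None]
            t = flipped.mean(0) / (flipped.std(0, ddof=1) / np.sqrt(5))
            runs = brute_force_clusters(
                t, np.full(36, thr), np.ones(36, bool)
            )
            maxima.append(max((abs(m) for *_, m in runs), default=0.0))
        maxima = np.array(maxima)
        assert np.allclose(np.sort(res.perm_distribution), np.sort(maxima))
        for c, p in zip(res.observed_clusters, res.cluster_p):
            p_oracle = (1 + np.sum(maxima >= abs(c.mass))) / (32 + 1)
            assert p == pytest.approx(p_oracle)

        mc = cluster_permutation_test(
            d, n_perm=2000, rng=np.random.default_rng(7)
        )
        for p_exact, p_mc in zip(res.cluster_p, mc.cluster_p):
            assert p_mc == pytest.approx(p_exact, abs=0.08)

    def test_detects_injected_cluster(self):
        rng = np.random.default_rng(8)
        data = rng.normal(0.0, 0.05, (10, 36))
        data[:, 4:13] += 0.15
        res = cluster_permutation_test(
            tc_frame(data), n_perm=500, rng=np.random.default_rng(9)
        )
        assert any(
            c.sign > 0 and c.start_bin <= 5 and c.end_bin >= 11
            for c in res.significant_clusters
        )

    def test_sign_flip_distribution_contains_observed_scale(self):
        rng = np.random.default_rng(10)
        res = cluster_permutation_test(
            tc_frame(rng.normal(0, 0.1, (8, 36))),
            n_perm=300,
            rng=np.random.default_rng(11),
        )
        assert res.significance_limit >= 0.0
        assert len(res.perm_distribution) == 300

    def test_null_p_values_approximately_uniform(self):
        """Exchangeability validity: under a sign-symmetric null the global
        permutation p-value is approximately uniform (coarse KS check)."""
        rng = np.random.default_rng(12)
        ps = []
        for _ in range(300):
            data = rng.normal(0.0, 0.1, (8, 36))
            res = cluster_permutation_test(
                tc_frame(data), n_perm=99, rng=rng
            )
            obs = max(
                (abs(c.mass) for c in res.observed_clusters), default=0.0
            )
            ps.append(
                (1 + np.sum(res.perm_distribution >= obs)) / (99 + 1)
            )
        # the statistic is discrete (an atom at p = 1 when no cluster forms),
        # so exact uniformity fails at the top; require coarse global
        # agreement plus calibration at the decision-relevant quantiles
        ps = np.asarray(ps)
        d_stat = stats.kstest(ps, "uniform").statistic
        assert d_stat < 0.25
        for alpha in (0.05, 0.1, 0.2, 0.5):
            assert abs(np.mean(ps <= alpha) - alpha) < 0.06

    def test_too_few_participants_rejected(self):
        with pytest.raises(ValueError):
            cluster_permutation_test(tc_frame(np.zeros((1, 36))))


class TestSpecGeometry:
    def test_touch_fractions_agree_across_groups(self):
        assert round(3.2 / SPEC.segment_length_slow_s, 2) == 0.36
        assert round(2.1 / SPEC.segment_length_fast_s, 2) == 0.36

    def test_bins_partition_normalized_axis(self):
        assert SPEC.n_bins * (1.0 / SPEC.n_bins) == 1.0
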