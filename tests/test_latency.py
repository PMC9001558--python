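"""First-switch latency: segment geometry, rm-ANOVA, sphericity, contrasts."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.anova import AnovaRM

from rivaltouch.config import LatencySpec
from rivaltouch.latency import (
    BIMODAL_CONGRUENT,
    BIMODAL_INCONGRUENT,
    SEGMENT_KINDS,
    UNIMODAL,
    build_latency_segments,
    latency_table,
    paired_contrasts,
    rm_anova_2x3,
)
from rivaltouch.preprocess import clean_trace
from rivaltouch.trace import LEFT, NONE, RIGHT

from test_preprocess import make_trace
from test_segments import event


def clean(intervals, **kw):
    return clean_trace(make_trace(intervals, **kw))


class TestSegmentGeometry:
    def test_unimodal_ends_at_onset_bimodal_starts_there(self):
        tr = clean([(0, 30, RIGHT)])
        segs = build_latency_segments(tr, [event(8, RIGHT)], 4.25)
        kinds = {s.kind: s for s in segs}
        uni = kinds[UNIMODAL]
        bi = kinds[BIMODAL_CONGRUENT]
        assert uni.start_s + uni.length_s == pytest.approx(8.0)
        assert bi.start_s == pytest.approx(8.0)
        assert uni.length_s == bi.length_s == 4.25

    def test_equal_pair_counts_before_filtering(self, clean_null_dataset):
        cfg, traces, events = clean_null_dataset
        n_uni = n_bi = 0
        for tr in traces:
            segs = build_latency_segments(tr, events[tr.trial_id], 4.25)
            n_uni += sum(s.kind == UNIMODAL for s in segs)
            n_bi += sum(s.kind != UNIMODAL for s in segs)
        # bimodal segments with a mixed percept at onset are dropped
        assert n_uni >= n_bi > 0

    def test_midpoint_switch_latency_half(self):
        L = 4.0
        tr = clean([(0, 10, LEFT), (10, 30, RIGHT)])
        segs = build_latency_segments(tr, [event(8, RIGHT)], L)
        bi = next(s for s in segs if s.kind != UNIMODAL)
        assert bi.first_switch_latency_prop == pytest.approx(0.5)

    def test_zero_and_multi_switch_excluded(self):
        L = 4.0
        tr_zero = clean([(0, 30, LEFT)])
        tr_multi = clean([(0, 9, LEFT), (9, 10, RIGHT), (10, 30, LEFT)])
        for tr in (tr_zero, tr_multi):
            for s in build_latency_segments(tr, [event(8, RIGHT)], L):
                assert s.first_switch_latency_prop is None

    def test_latency_proportions_in_unit_interval(self, clean_null_dataset):
        cfg, traces, events = clean_null_dataset
        lat = latency_table(
            traces, events, LatencySpec(), cfg.switcher_profile()
        )
        assert ((lat["latency_prop"] > 0) & (lat["latency_prop"] <= 1)).all()

    def test_window_outside_trial_dropped(self):
        tr = clean([(0, 10, RIGHT)])
        assert build_latency_segments(tr, [event(2, RIGHT)], 4.0) == []

    def test_null_unimodal_and_bimodal_latencies_agree(self, clean_null_dataset):
        cfg, traces, events = clean_null_dataset
        lat = latency_table(
            traces, events, LatencySpec(), cfg.switcher_profile()
        )
        means = lat.groupby("kind")["latency_prop"].mean()
        assert abs(means[UNIMODAL] - means[[BIMODAL_CONGRUENT,
                                            BIMODAL_INCONGRUENT]].mean()) < 0.08


def anova_frame(values: np.ndarray) -> pd.DataFrame:
    """values: participants × 2 conditions × 3 kinds."""
    rows = []
    for s in range(values.shape[0]):
        for ci, cond in enumerate(["A", "B"]):
            for ki, kind in enumerate(SEGMENT_KINDS):
                rows.append(
                    {
                        "participant_id": f"P{s:02d}",
                        "condition": cond,
                        "kind": kind,
                        "latency_prop": values[s, ci, ki],
                    }
                )
    return pd.DataFrame(rows)


def gg_epsilon_oracle(data: np.ndarray) -> float:
    """Greenhouse–Geisser epsilon from the sample covariance of the
    within-subject conditions (double-centered covariance eigenvalues)."""
    S = np.cov(data, rowvar=False)
    k = S.shape[0]
    C = np.eye(k) - np.ones((k, k)) / k
    Sc = C @ S @ C
    lam = np.linalg.eigvalsh(Sc)
    lam = lam[lam > 1e-12]
    return float(lam.sum() ** 2 / ((k - 1) * (lam**2).sum()))


class TestRmAnova:
    def test_equal_cell_means_give_zero_f(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(0.5, 0.05, (8, 2, 3))
        vals -= vals.mean(axis=0, keepdims=True)  # every cell mean exactly 0
        vals += 0.5
        results = {r.effect: r for r in rm_anova_2x3(anova_frame(vals))}
        for r in results.values():
            assert r.F == pytest.approx(0.0, abs=1e-20)

    def test_two_level_factor_epsilon_is_one(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(0.5, 0.05, (8, 2, 3))
        res = {r.effect: r for r in rm_anova_2x3(anova_frame(vals))}
        assert res["condition"].gg_epsilon == 1.0

    def test_epsilon_matches_covariance_oracle(self):
        rng = np.random.default_rng(2)
        # correlated cells induce a sphericity violation
        base = rng.normal(0, 0.08, (12, 1))
        vals = 0.5 + np.concatenate(
            [base * w for w in (1.0, 0.2, 1.4)], axis=1
        ) + rng.normal(0, 0.03, (12, 3))
        vals = np.stack([vals, vals + rng.normal(0, 0.03, (12, 3))], axis=1)
        res = {r.effect: r for r in rm_anova_2x3(anova_frame(vals))}
        # oracle on the kind means (averaged over condition)
        kind_means = vals.mean(axis=1)
        eps_oracle = gg_epsilon_oracle(kind_means)
        assert res["kind"].gg_epsilon == pytest.approx(eps_oracle, abs=1e-6)
        assert 1.0 / 2.0 < res["kind"].gg_epsilon <= 1.0  # (1/(k-1), 1]

    def test_f_values_match_statsmodels_anova_rm(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(0.5, 0.06, (10, 2, 3))
        vals[:, 0, 2] += 0.08
        df = anova_frame(vals)
        ours = {r.effect: r for r in rm_anova_2x3(df)}
        ref = AnovaRM(
            df,
            depvar="latency_prop",
            subject="participant_id",
            within=["condition", "kind"],
        ).fit()
        tbl = ref.anova_table
        assert ours["condition"].F == pytest.approx(
            tbl.loc["condition", "F Value"]
        )
        assert ours["kind"].F == pytest.approx(tbl.loc["kind", "F Value"])
        assert ours["condition * kind"].F == pytest.approx(
            tbl.loc["condition:kind", "F Value"]
        )

    def test_gg_correction_applied_only_when_mauchly_fails(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(0.5, 0.05, (10, 2, 3))
        res = rm_anova_2x3(anova_frame(vals))
        for r in res:
            if r.mauchly_p >= 0.05:
                assert not r.gg_applied
                assert r.df_num in (1.0, 2.0)

    def test_too_few_participants_rejected(self):
        vals = np.random.default_rng(5).normal(0.5, 0.05, (2, 2, 3))
        with pytest.raises(ValueError):
            rm_anova_2x3(anova_frame(vals))


class TestPairedContrasts:
    def test_identical_vectors_t_zero_p_one(self):
        vals = np.random.default_rng(0).normal(0.5, 0.05, (8, 2, 3))
        vals[:, 0, 1] = vals[:, 0, 0]  # two identical kinds in condition A
        df = anova_frame(vals)
        out = paired_contrasts(df, "A")
        row = out[out["pair"] == f"{UNIMODAL} vs {BIMODAL_CONGRUENT}"].iloc[0]
        assert row["t"] == 0.0 and row["p_adj"] == 1.0

    def test_bonferroni_cap(self):
        vals = np.random.default_rng(1).normal(0.5, 0.05, (8, 2, 3))
        out = paired_contrasts(anova_frame(vals), "A")
        assert (out["p_adj"] == np.minimum(1.0, 3 * out["p_raw"])).all()
        assert (out["p_adj"] <= 1.0).all()

    def test_injected_delay_ordering_detected(self, clean_effect_dataset):
        """Congruent-onset percepts are stabilised (late switch to
        incongruence), incongruent-onset percepts destabilised (early
        switch to congruence): late > baseline > early."""
        cfg, traces, events = clean_effect_dataset
        lat = latency_table(
            traces, events, LatencySpec(), cfg.switcher_profile()
        )
        eff = lat[lat["condition"] == "parallel_aligned_visible"]
        means = eff.groupby("kind")["latency_prop"].mean()
        assert (
            means[BIMODAL_CONGRUENT]
            > means[UNIMODAL]
            > means[BIMODAL_INCONGRUENT]
        )
        out = paired_contrasts(eff, "parallel_aligned_visible")
        pair = f"{BIMODAL_CONGRUENT} vs {BIMODAL_INCONGRUENT}"
        assert out[out["pair"] == pair]["p_adj"].iloc[0] < 0.05
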