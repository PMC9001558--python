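"""End-to-end pipeline: simulate → clean → segment → models/timecourse/latency.

The three experimental effects are each assessed by comparing the
reference condition (parallel axes, spatially aligned, hand visible)
against the condition that differs in exactly one respect:

* direction selectivity — parallel vs orthogonal motion axes;
* spatial alignment — aligned vs misaligned stimulus locations;
* hand visibility — hand visible vs hidden.

Each effect gets a switch-probability mixed-model interaction test with
follow-up contrasts, per-condition binned timecourses with FDR-corrected
bin tests, a cluster-mass permutation test on the condition difference
waveforms, and a 2 × 3 first-switch latency ANOVA.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .config import PipelineConfig, SimConfig
from .glmm import fit_switch_model, lrt_interaction, pairwise_contrasts
from .latency import latency_table, paired_contrasts, rm_anova_2x3
from .preprocess import clean_trace, dominance_stats
from .segments import (
    MAINTAINED,
    SWITCHED,
    extract_all_segments,
    segments_to_frame,
    tabulate_outcomes,
)
from .simulate import simulate_dataset
from .timecourse import (
    bin_tests,
    cluster_permutation_test,
    difference_waveform,
    participant_timecourses,
)

log = logging.getLogger(__name__)

REFERENCE_CONDITION = "parallel_aligned_visible"

EFFECTS = {
    "direction_selectivity": (REFERENCE_CONDITION, "orthogonal_aligned"),
    "spatial_alignment": (REFERENCE_CONDITION, "parallel_misaligned"),
    "hand_visibility": (REFERENCE_CONDITION, "parallel_aligned_invisible"),
}

N_CALIBRATION_TRIALS = 4  # practice-block stand-in for switcher classing


def classify_switchers(
    clean_traces, n_calibration: int = N_CALIBRATION_TRIALS
) -> dict[str, str]:
    """Fast/slow classification from a designated calibration subset.

    The first ``n_calibration`` trials of each condition play the role of
    the practice block: participants with mean dominance < 3 s there are
    fast switchers.
    """
    cal = [
        tr
        for tr in clean_traces
        if int(tr.trial_id.rsplit("t", 1)[-1]) < n_calibration
    ]
    stats_df = dominance_stats(cal)
    return dict(zip(stats_df["participant_id"], stats_df["switcher"]))


def glmm_segment_table(seg_df: pd.DataFrame, conditions) -> pd.DataFrame:
    """Restrict a segment frame to the mixed-model analysis set.

    Keeps segments with defined onset congruency, no mixed-percept time,
    and at most one switch; adds the binary ``switched`` response.
    """
    df = seg_df[
        seg_df["condition"].isin(conditions)
        & seg_df["outcome"].isin([MAINTAINED, SWITCHED])
    ].copy()
    df["switched"] = (df["outcome"] == SWITCHED).astype(int)
    return df


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis on a freshly simulated dataset.

    Deterministic given ``config`` (the simulation seed drives the data,
    a derived stream drives the permutation tests).  Returns a
    JSON-serialisable report.
    """
    cfg = dataclasses.replace(config.sim, seed=config.seed)
    traces, events = simulate_dataset(cfg)
    clean = [clean_trace(tr, config.artifact_threshold_s) for tr in traces]
    profiles = classify_switchers(clean)
    segs = extract_all_segments(clean, events)
    seg_df = segments_to_frame(segs)
    outcome_table = tabulate_outcomes(segs)

    tc = participant_timecourses(clean, events, config.timecourse, profiles)
    conditions_present = set(seg_df["condition"].unique())

    report: dict = {
        "seed": config.seed,
        "n_participants": cfg.n_participants,
        "n_trials_per_condition": cfg.n_trials_per_condition,
        "switcher_profiles": profiles,
        "outcome_table": outcome_table.to_dict(orient="records"),
        "effects": {},
        "bin_tests": {},
    }

    for cond in sorted(conditions_present):
        tc_cond = tc[tc["condition"] == cond]
        bt = bin_tests(tc_cond, config.timecourse)
        report["bin_tests"][cond] = {
            "n_significant_bins": int(bt.significant.sum()),
            "significant_duration_s": bt.significant_duration_s,
            "significant_bins": [int(b) for b in np.where(bt.significant)[0]],
        }

    perm_rng = np.random.default_rng([config.seed, 104729])
    for effect, (cond_a, cond_b) in EFFECTS.items():
        if not {cond_a, cond_b} <= conditions_present:
            continue
        entry: dict = {"conditions": [cond_a, cond_b]}

        glmm_df = glmm_segment_table(seg_df, (cond_a, cond_b))
        full = fit_switch_model(glmm_df, include_interaction=True)
        reduced = fit_switch_model(glmm_df, include_interaction=False)
        lrt = lrt_interaction(full, reduced)
        contrasts = pairwise_contrasts(full, by="condition")
        entry["glmm"] = {
            "interaction_chi2": lrt.chi2,
            "interaction_df": lrt.df,
            "interaction_p": lrt.p,
            "random_intercept_var": full.random_intercept_var,
            "coefficients": dict(
                zip(full.param_names, full.coefficients.tolist())
            ),
            "contrasts": [_jsonable(c) for c in contrasts],
        }

        diff = difference_waveform(
            tc[tc["condition"] == cond_a], tc[tc["condition"] == cond_b]
        )
        ct = cluster_permutation_test(
            diff,
            n_perm=config.n_permutations,
            alpha=config.timecourse.alpha_bin,
            rng=perm_rng,
        )
        touch_end_bin = int(
            np.ceil(config.timecourse.touch_fraction * config.timecourse.n_bins)
        )
        entry["cluster_test"] = {
            "significance_limit": ct.significance_limit,
            "observed_clusters": [_jsonable(c) for c in ct.observed_clusters],
            "significant_clusters": [
                _jsonable(c) for c in ct.significant_clusters
            ],
            "positive_cluster_in_touch_window": any(
                c.sign > 0 and c.start_bin < touch_end_bin
                for c in ct.significant_clusters
            ),
        }

        lat = latency_table(
            clean, events, config.latency, profiles, (cond_a, cond_b)
        )
        anova = rm_anova_2x3(lat)
        entry["latency"] = {
            "anova": [_jsonable(a) for a in anova],
            "contrasts": {
                cond: paired_contrasts(lat, cond).to_dict(orient="records")
                for cond in (cond_a, cond_b)
            },
            "cell_means": {
                f"{c}|{k}": v
                for (c, k), v in lat.groupby(
                    ["condition", "kind"], observed=True
                )["latency_prop"]
                .mean()
                .items()
            },
        }
        report["effects"][effect] = entry

    return _jsonable(report)


def report_hash(report: Mapping) -> str:
    """Stable hash of a report for end-to-end determinism checks."""
    blob = json.dumps(report, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()
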