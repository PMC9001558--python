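"""Parameter-recovery and null-calibration suites.

Real participant recordings for this paradigm are not publicly deposited,
so the pipeline is validated by recovery: simulate cohorts with a known,
condition-gated congruency effect (or none), run the full analysis chain,
and check that each statistic flags (or does not flag) the effect.

The recovery cohort mirrors the study design: 14 participants (9 slow /
5 fast switchers), trials of 48 s with four tactile stimuli, and a strong
effect — incongruent-percept hazard tripled, congruent-percept hazard
multiplied by 0.4 during stimulation — active only in the parallel-axes,
spatially-aligned condition.  The orthogonal-axes condition serves as the
no-effect contrast.
"""

from __future__ import annotations

import dataclasses
from typing import Callable

import numpy as np

from .config import PipelineConfig, SimConfig, TimecourseSpec
from .glmm import fit_switch_model, lrt_interaction
from .latency import BIMODAL_CONGRUENT, BIMODAL_INCONGRUENT, UNIMODAL, latency_table
from .pipeline import classify_switchers, glmm_segment_table, run_pipeline
from .preprocess import clean_trace
from .segments import extract_all_segments, segments_to_frame
from .simulate import simulate_dataset
from .timecourse import (
    bin_tests,
    cluster_permutation_test,
    difference_waveform,
    participant_timecourses,
)

EFFECT_CONDITION = "parallel_aligned_visible"
CONTRAST_CONDITION = "orthogonal_aligned"

__all__ = [
    "recovery_sim_config",
    "null_sim_config",
    "run_recovery_replicate",
    "run_null_replicate",
    "recovery_suite",
    "null_suite",
]


def recovery_sim_config(seed: int, n_trials: int = 32) -> SimConfig:
    return SimConfig(
        n_participants=14,
        n_fast=5,
        n_trials_per_condition=n_trials,
        conditions=(EFFECT_CONDITION, CONTRAST_CONDITION),
        effect_conditions=frozenset({EFFECT_CONDITION}),
        hazard_mult_congruent=0.4,
        hazard_mult_incongruent=3.0,
        seed=seed,
    )


def null_sim_config(seed: int, n_trials: int = 8) -> SimConfig:
    return dataclasses.replace(
        recovery_sim_config(seed, n_trials),
        hazard_mult_congruent=1.0,
        hazard_mult_incongruent=1.0,
    )


def run_recovery_replicate(
    seed: int, n_trials: int = 32, n_perm: int = 1000
) -> dict:
    """One full-pipeline run on an effect-bearing cohort.

    Returns the interaction test, cluster detection, and latency ordering
    outcomes the recovery suite scores.
    """
    config = PipelineConfig(
        sim=recovery_sim_config(seed, n_trials),
        n_permutations=n_perm,
        seed=seed,
    )
    report = run_pipeline(config)
    eff = report["effects"]["direction_selectivity"]
    cells = eff["latency"]["cell_means"]
    congruent_onset = cells.get(f"{EFFECT_CONDITION}|{BIMODAL_CONGRUENT}")
    incongruent_onset = cells.get(f"{EFFECT_CONDITION}|{BIMODAL_INCONGRUENT}")
    baseline = cells.get(f"{EFFECT_CONDITION}|{UNIMODAL}")
    ordering = (
        congruent_onset is not None
        and baseline is not None
        and incongruent_onset is not None
        and congruent_onset > baseline > incongruent_onset
    )
    return {
        "interaction_chi2": eff["glmm"]["interaction_chi2"],
        "interaction_p": eff["glmm"]["interaction_p"],
        "cluster_detected": eff["cluster_test"][
            "positive_cluster_in_touch_window"
        ],
        "latency_ordering": bool(ordering),
        "latency_cells": {
            "switch_to_incongruence": congruent_onset,
            "baseline": baseline,
            "switch_to_congruence": incongruent_onset,
        },
        "significant_duration_s": report["bin_tests"][EFFECT_CONDITION][
            "significant_duration_s"
        ],
    }


def run_null_replicate(seed: int, n_trials: int = 8, n_perm: int = 1000) -> dict:
    """One no-effect run scored for type-I behaviour.

    Avoids the full pipeline report to keep 200-replicate calibration runs
    cheap: only the interaction LRT, the cluster test, and the raw per-bin
    t-tests are computed.
    """
    cfg = null_sim_config(seed, n_trials)
    traces, events = simulate_dataset(cfg)
    clean = [clean_trace(tr) for tr in traces]
    profiles = classify_switchers(clean)
    seg_df = segments_to_frame(extract_all_segments(clean, events))

    glmm_df = glmm_segment_table(seg_df, cfg.conditions)
    full = fit_switch_model(glmm_df, include_interaction=True)
    reduced = fit_switch_model(glmm_df, include_interaction=False)
    lrt = lrt_interaction(full, reduced)

    spec = TimecourseSpec()
    tc = participant_timecourses(clean, events, spec, profiles)
    raw_p = []
    for cond in cfg.conditions:
        bt = bin_tests(tc[tc["condition"] == cond], spec)
        raw_p.extend(bt.p[bt.tested].tolist())
    diff = difference_waveform(
        tc[tc["condition"] == EFFECT_CONDITION],
        tc[tc["condition"] == CONTRAST_CONDITION],
    )
    ct = cluster_permutation_test(
        diff,
        n_perm=n_perm,
        alpha=spec.alpha_bin,
        rng=np.random.default_rng([seed, 271828]),
    )
    return {
        "interaction_p": lrt.p,
        "any_significant_cluster": len(ct.significant_clusters) > 0,
        "raw_bin_p": raw_p,
        "alpha_bin": spec.alpha_bin,
    }


def _seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2**31 - 1)]


def recovery_suite(
    seed: int,
    n_replicates: int = 50,
    n_trials: int = 32,
    progress: Callable[[int], None] | None = None,
) -> dict:
    """Score the recovery criteria over seeded replicates."""
    reps = []
    for i, s in enumerate(_seeds(seed, n_replicates)):
        reps.append(run_recovery_replicate(s, n_trials))
        if progress:
            progress(i)
    return {
        "n_replicates": n_replicates,
        "interaction_detection_rate": float(
            np.mean([r["interaction_p"] < 0.05 for r in reps])
        ),
        "cluster_detection_rate": float(
            np.mean([r["cluster_detected"] for r in reps])
        ),
        "latency_ordering_rate": float(
            np.mean([r["latency_ordering"] for r in reps])
        ),
        "median_interaction_chi2": float(
            np.median([r["interaction_chi2"] for r in reps])
        ),
        "mean_latency_cells": {
            k: float(
                np.mean(
                    [
                        r["latency_cells"][k]
                        for r in reps
                        if r["latency_cells"][k] is not None
                    ]
                )
            )
            for k in ("switch_to_incongruence", "baseline",
                      "switch_to_congruence")
        },
    }


def null_suite(
    seed: int,
    n_replicates: int = 200,
    n_trials: int = 8,
    progress: Callable[[int], None] | None = None,
) -> dict:
    """Score type-I calibration over seeded no-effect replicates."""
    reps = []
    for i, s in enumerate(_seeds(seed + 1, n_replicates)):
        reps.append(run_null_replicate(s, n_trials))
        if progress:
            progress(i)
    raw_p = np.concatenate([r["raw_bin_p"] for r in reps])
    alpha = reps[0]["alpha_bin"]
    return {
        "n_replicates": n_replicates,
        "bin_rejection_rate": float(np.mean(raw_p < alpha)),
        "alpha_bin": alpha,
        "cluster_false_positive_rate": float(
            np.mean([r["any_significant_cluster"] for r in reps])
        ),
        "glmm_type1_rate": float(
            np.mean([r["interaction_p"] < 0.05 for r in reps])
        ),
    }
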