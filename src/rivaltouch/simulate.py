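"""Stochastic generator of rivalry button-press data with tactile stimuli.

Percept dynamics are an alternating renewal process: dominance durations
are gamma-distributed with a participant-specific mean, and transitions
pass through a mixed-percept (NONE) gap with configurable probability.
Tactile stimulation perturbs the process through multiplicative hazard
modulation: while a stimulus is active (and the condition carries the
effect), the current percept's switch hazard is scaled by a congruent or
incongruent multiplier.  Modulation is implemented by operational-time
rescaling — the renewal clock of the current dominance period advances at
the multiplier's rate during stimulation — which is exactly a
multiplicative perturbation of the instantaneous hazard.

Randomness derives from one dataset seed, split per trial by counter keys,
so changing the trial count never reshuffles earlier trials.
"""

from __future__ import annotations

import json
import math
import os
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .config import SimConfig, VERTICAL_AXIS_CONDITIONS
from .trace import (
    DOWN,
    LEFT,
    NONE,
    RIGHT,
    UP,
    PerceptTrace,
    TactileEvent,
)

__all__ = [
    "build_schedule",
    "simulate_trace",
    "simulate_dataset",
    "write_dataset",
    "read_dataset",
]


def trial_rng(
    seed: int, participant_idx: int, condition_idx: int, trial_idx: int
) -> np.random.Generator:
    """Independent, reproducible RNG stream for one trial."""
    return np.random.default_rng(
        [seed, participant_idx, condition_idx, trial_idx]
    )


def build_schedule(
    cfg: SimConfig, trial_id: str, n_sweeps: int, rng: np.random.Generator
) -> list[TactileEvent]:
    """Draw the tactile schedule for one trial.

    The first onset is fixed; each later onset follows the previous by
    ``inter_onset_mean_s`` plus a uniform jitter of ``±onset_jitter_s``.
    Sweep directions are counterbalanced within the trial (half LEFT,
    half RIGHT) and randomly ordered.
    """
    duration = cfg.stimulus_duration_s(n_sweeps)
    onsets = [cfg.first_onset_s]
    for _ in range(cfg.n_tactile_per_trial - 1):
        gap = cfg.inter_onset_mean_s + rng.uniform(
            -cfg.onset_jitter_s, cfg.onset_jitter_s
        )
        onsets.append(onsets[-1] + gap)
    if onsets[-1] + duration > cfg.trial_length_s:
        raise ValueError(
            f"trial {trial_id}: tactile schedule ends at "
            f"{onsets[-1] + duration:.2f}s, beyond the "
            f"{cfg.trial_length_s:.2f}s trial"
        )
    n = cfg.n_tactile_per_trial
    directions = [LEFT] * (n // 2) + [RIGHT] * (n - n // 2)
    rng.shuffle(directions)
    return [
        TactileEvent(
            trial_id=trial_id,
            index_in_trial=i + 1,
            onset_s=float(onset),
            direction=direction,
            n_sweeps=n_sweeps,
            duration_s=duration,
        )
        for i, (onset, direction) in enumerate(zip(onsets, directions))
    ]


def _hazard_mult(
    t: float,
    direction: str,
    events: Iterable[TactileEvent],
    cfg: SimConfig,
    effect_on: bool,
) -> float:
    if not effect_on:
        return 1.0
    for ev in events:
        if ev.onset_s <= t < ev.offset_s:
            return (
                cfg.hazard_mult_congruent
                if direction == ev.direction
                else cfg.hazard_mult_incongruent
            )
    return 1.0


def _warped_end(
    t0: float,
    budget: float,
    direction: str,
    events: list[TactileEvent],
    cfg: SimConfig,
    effect_on: bool,
) -> float:
    """Wall-clock time at which the operational-time ``budget`` is spent.

    Operational time accrues at the active hazard multiplier's rate, so
    the multiplier's timeline is walked breakpoint by breakpoint.
    """
    if not effect_on or (
        cfg.hazard_mult_congruent == 1.0 and cfg.hazard_mult_incongruent == 1.0
    ):
        return t0 + budget
    breakpoints = sorted(
        {b for ev in events for b in (ev.onset_s, ev.offset_s) if b > t0}
    )
    t = t0
    remaining = budget
    for bp in breakpoints:
        mult = _hazard_mult(t, direction, events, cfg, effect_on)
        span = bp - t
        if remaining <= mult * span:
            return t + remaining / mult
        remaining -= mult * span
        t = bp
    mult = _hazard_mult(t, direction, events, cfg, effect_on)
    return t + remaining / mult


def simulate_trace(
    cfg: SimConfig,
    events: list[TactileEvent],
    condition: str,
    rng: np.random.Generator,
    *,
    profile: str = "slow",
    trial_id: str = "trial",
    participant_id: str = "P01",
) -> PerceptTrace:
    """Simulate one trial's perceptual state path.

    Returns a normalized :class:`PerceptTrace` whose ``switch_times_s``
    carry the ground-truth dominance switch times.  On vertical-axis
    conditions the dominance states are relabelled UP/DOWN (internally the
    process runs on the LEFT/RIGHT congruency axis, matching the analysis
    remapping upward→leftward, downward→rightward).
    """
    if condition not in cfg.conditions:
        raise ValueError(f"unknown condition {condition!r}")
    effect_on = condition in cfg.effect_conditions
    mean = cfg.mean_dominance_s(profile)
    shape = cfg.gamma_shape
    scale = mean / shape
    mu_gap = math.log(cfg.mixed_duration_mean_s) - cfg.mixed_duration_sigma**2 / 2

    T = cfg.trial_length_s
    state = LEFT if rng.random() < 0.5 else RIGHT
    t = 0.0
    intervals: list[tuple[float, float, str]] = []
    switch_times: list[float] = []
    while t < T:
        budget = rng.gamma(shape, scale)
        end = min(_warped_end(t, budget, state, events, cfg, effect_on), T)
        intervals.append((t, end, state))
        t = end
        if t >= T:
            break
        switch_times.append(t)
        if rng.random() < cfg.p_mixed:
            gap = rng.lognormal(mu_gap, cfg.mixed_duration_sigma)
            gap_end = min(t + gap, T)
            intervals.append((t, gap_end, NONE))
            t = gap_end
        state = RIGHT if state == LEFT else LEFT

    axis = "vertical" if condition in VERTICAL_AXIS_CONDITIONS else "horizontal"
    if axis == "vertical":
        relabel = {LEFT: UP, RIGHT: DOWN, NONE: NONE}
        intervals = [(a, b, relabel[s]) for a, b, s in intervals]
    trace = PerceptTrace(
        trial_id=trial_id,
        participant_id=participant_id,
        condition=condition,
        axis=axis,
        trial_length_s=T,
        intervals=intervals,
        switch_times_s=switch_times,
    ).normalized()
    trace.validate()
    return trace


def simulate_dataset(
    cfg: SimConfig,
) -> tuple[list[PerceptTrace], dict[str, list[TactileEvent]]]:
    """Simulate the full multi-participant dataset defined by ``cfg``."""
    profiles = cfg.switcher_profile()
    traces: list[PerceptTrace] = []
    events: dict[str, list[TactileEvent]] = {}
    for p_idx, (pid, profile) in enumerate(profiles.items()):
        n_sweeps = cfg.n_sweeps(profile)
        for c_idx, condition in enumerate(cfg.conditions):
            for t_idx in range(cfg.n_trials_per_condition):
                rng = trial_rng(cfg.seed, p_idx, c_idx, t_idx)
                trial_id = f"{pid}|{condition}|t{t_idx:03d}"
                trial_events = build_schedule(cfg, trial_id, n_sweeps, rng)
                trace = simulate_trace(
                    cfg,
                    trial_events,
                    condition,
                    rng,
                    profile=profile,
                    trial_id=trial_id,
                    participant_id=pid,
                )
                traces.append(trace)
                events[trial_id] = trial_events
    return traces, events


def _trace_rows(traces: Iterable[PerceptTrace]) -> pd.DataFrame:
    rows = []
    for tr in traces:
        for start, end, state in tr.intervals:
            rows.append(
                {
                    "participant_id": tr.participant_id,
                    "condition": tr.condition,
                    "trial_id": tr.trial_id,
                    "axis": tr.axis,
                    "trial_length_s": tr.trial_length_s,
                    "start_s": start,
                    "end_s": end,
                    "state": state,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "condition",
            "trial_id",
            "axis",
            "trial_length_s",
            "start_s",
            "end_s",
            "state",
        ],
    )


def write_dataset(
    traces: list[PerceptTrace],
    events: Mapping[str, list[TactileEvent]],
    path: str,
    cfg: SimConfig | None = None,
) -> None:
    """Write a dataset as long-format CSVs plus a JSON provenance sidecar."""
    os.makedirs(path, exist_ok=True)
    _trace_rows(traces).to_csv(os.path.join(path, "traces.csv"), index=False)
    ev_rows = [
        {
            "trial_id": ev.trial_id,
            "index_in_trial": ev.index_in_trial,
            "onset_s": ev.onset_s,
            "direction": ev.direction,
            "n_sweeps": ev.n_sweeps,
            "duration_s": ev.duration_s,
        }
        for trial_events in events.values()
        for ev in trial_events
    ]
    pd.DataFrame(
        ev_rows,
        columns=[
            "trial_id",
            "index_in_trial",
            "onset_s",
            "direction",
            "n_sweeps",
            "duration_s",
        ],
    ).to_csv(os.path.join(path, "events.csv"), index=False)
    sw_rows = [
        {"trial_id": tr.trial_id, "switch_time_s": t}
        for tr in traces
        for t in tr.switch_times_s
    ]
    pd.DataFrame(sw_rows, columns=["trial_id", "switch_time_s"]).to_csv(
        os.path.join(path, "switch_times.csv"), index=False
    )
    sidecar = {"config": cfg.to_dict() if cfg is not None else None}
    with open(os.path.join(path, "dataset.json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)


class DatasetParseError(ValueError):
    """Malformed dataset file; message names the offending row/column."""


def traces_from_frame(df: pd.DataFrame) -> list[PerceptTrace]:
    """Assemble :class:`PerceptTrace` objects from a long-format table."""
    required = {
        "participant_id",
        "condition",
        "trial_id",
        "axis",
        "trial_length_s",
        "start_s",
        "end_s",
        "state",
    }
    missing = required - set(df.columns)
    if missing:
        raise DatasetParseError(f"traces table missing columns: {sorted(missing)}")
    traces = []
    for trial_id, grp in df.groupby("trial_id", sort=False):
        grp = grp.sort_values("start_s")
        for col in ("start_s", "end_s", "trial_length_s"):
            bad = grp[pd.to_numeric(grp[col], errors="coerce").isna()]
            if len(bad):
                raise DatasetParseError(
                    f"trial {trial_id}: non-numeric {col!r} at row "
                    f"{bad.index[0]}"
                )
        trace = PerceptTrace(
            trial_id=str(trial_id),
            participant_id=str(grp["participant_id"].iloc[0]),
            condition=str(grp["condition"].iloc[0]),
            axis=str(grp["axis"].iloc[0]),
            trial_length_s=float(grp["trial_length_s"].iloc[0]),
            intervals=[
                (float(r.start_s), float(r.end_s), str(r.state))
                for r in grp.itertuples()
            ],
        )
        trace.validate()
        traces.append(trace)
    return traces


def read_dataset(
    path: str,
) -> tuple[list[PerceptTrace], dict[str, list[TactileEvent]]]:
    """Read a dataset written by :func:`write_dataset` (lossless round trip)."""
    tdf = pd.read_csv(os.path.join(path, "traces.csv"),
                      float_precision="round_trip")
    edf = pd.read_csv(os.path.join(path, "events.csv"),
                      float_precision="round_trip")
    traces = traces_from_frame(tdf) if len(tdf) else []
    sw_path = os.path.join(path, "switch_times.csv")
    if os.path.exists(sw_path):
        sdf = pd.read_csv(sw_path, float_precision="round_trip")
        by_trial = (
            sdf.groupby("trial_id")["switch_time_s"].apply(list).to_dict()
            if len(sdf)
            else {}
        )
        for tr in traces:
            tr.switch_times_s = [float(t) for t in by_trial.get(tr.trial_id, [])]
    events: dict[str, list[TactileEvent]] = {}
    for trial_id, grp in edf.groupby("trial_id", sort=False):
        grp = grp.sort_values("index_in_trial")
        events[str(trial_id)] = [
            TactileEvent(
                trial_id=str(trial_id),
                index_in_trial=int(r.index_in_trial),
                onset_s=float(r.onset_s),
                direction=str(r.direction),
                n_sweeps=int(r.n_sweeps),
                duration_s=float(r.duration_s),
            )
            for r in grp.itertuples()
        ]
    return traces, events
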