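"""Cleaning of raw button-press traces.

Three steps turn a raw trace into an analysis-ready one:

* dominance reports lasting 180 ms or less are treated as motor artefacts
  and relabelled NONE (never merged into a neighbour, which would fabricate
  dominance time the participant did not report);
* on vertical-axis trials, upward/downward reports are remapped to the
  leftward/rightward congruency axis;
* per-participant dominance statistics classify each observer as a fast
  (mean dominance < 3 s) or slow switcher.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .trace import (
    DOMINANCE_STATES,
    NONE,
    VERTICAL_TO_HORIZONTAL,
    PerceptTrace,
)

log = logging.getLogger(__name__)

ARTIFACT_THRESHOLD_S = 0.18

__all__ = [
    "CleanTrace",
    "remove_artifacts",
    "remap_vertical",
    "clean_trace",
    "dominance_stats",
    "ARTIFACT_THRESHOLD_S",
]


@dataclass
class CleanTrace(PerceptTrace):
    """A preprocessed trace; state alphabet {LEFT, RIGHT, NONE}."""

    mapped_axis_note: bool = False
    removed_time_s: float = 0.0


def _as_clean(trace: PerceptTrace, **kw) -> CleanTrace:
    base = dict(
        trial_id=trace.trial_id,
        participant_id=trace.participant_id,
        condition=trace.condition,
        axis=trace.axis,
        trial_length_s=trace.trial_length_s,
        intervals=list(trace.intervals),
        switch_times_s=list(trace.switch_times_s),
    )
    if isinstance(trace, CleanTrace):
        base["mapped_axis_note"] = trace.mapped_axis_note
        base["removed_time_s"] = trace.removed_time_s
    base.update(kw)
    return CleanTrace(**base)


def remove_artifacts(
    trace: PerceptTrace, threshold_s: float = ARTIFACT_THRESHOLD_S
) -> CleanTrace:
    """Relabel dominance intervals of length <= ``threshold_s`` as NONE.

    The boundary case is inclusive: an interval of exactly the threshold
    length is an artefact.  Total time is conserved; only labels change.
    """
    intervals = []
    removed = 0.0
    for start, end, state in trace.intervals:
        if state != NONE and (end - start) <= threshold_s + 1e-12:
            intervals.append((start, end, NONE))
            removed += end - start
        else:
            intervals.append((start, end, state))
    prior = trace.removed_time_s if isinstance(trace, CleanTrace) else 0.0
    out = _as_clean(trace, intervals=intervals, removed_time_s=prior + removed)
    return _as_clean(out.normalized())


def remap_vertical(trace: CleanTrace) -> CleanTrace:
    """Map vertical reports onto the congruency axis (UP→LEFT, DOWN→RIGHT)."""
    if trace.axis != "vertical":
        log.info("trial %s: horizontal trace, remap is a no-op", trace.trial_id)
        return trace
    intervals = [
        (s, e, VERTICAL_TO_HORIZONTAL.get(state, state))
        for s, e, state in trace.intervals
    ]
    return _as_clean(trace, intervals=intervals, mapped_axis_note=True)


def clean_trace(
    trace: PerceptTrace, threshold_s: float = ARTIFACT_THRESHOLD_S
) -> CleanTrace:
    """Full preprocessing: remap the axis, then drop artefactual reports."""
    out = _as_clean(trace)
    if out.axis == "vertical":
        out = remap_vertical(out)
    return remove_artifacts(out, threshold_s)


def dominance_stats(traces: Iterable[PerceptTrace]) -> pd.DataFrame:
    """Per-participant dominance-duration summary and switcher class.

    Means are taken over exclusive-dominance intervals only (NONE time is
    excluded).  A participant is a fast switcher when the mean dominance
    duration is strictly below 3 s, otherwise slow.  Participants with no
    dominance intervals are excluded with a warning.
    """
    per_participant: dict[str, list[float]] = {}
    for tr in traces:
        durs = [
            e - s for s, e, state in tr.intervals if state in DOMINANCE_STATES
            or state in VERTICAL_TO_HORIZONTAL
        ]
        per_participant.setdefault(tr.participant_id, []).extend(durs)
    rows = []
    for pid, durs in per_participant.items():
        if not durs:
            log.warning("participant %s: no dominance intervals; excluded", pid)
            continue
        mean = float(np.mean(durs))
        rows.append(
            {
                "participant_id": pid,
                "mean_dominance_s": mean,
                "sd_dominance_s": float(np.std(durs, ddof=1))
                if len(durs) > 1
                else np.nan,
                "n_intervals": len(durs),
                "switcher": "fast" if mean < 3.0 else "slow",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "mean_dominance_s",
            "sd_dominance_s",
            "n_intervals",
            "switcher",
        ],
    )
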