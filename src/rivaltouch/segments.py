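"""Tactile-onset-locked segmentation and outcome classification.

Each trial contributes one segment per tactile stimulus, spanning the
stimulation window.  A segment's congruency is fixed at tactile onset by
comparing the dominant percept with the tactile direction; its outcome is
the number of dominance switches during stimulation.  Conventions:

* state at the onset instant uses half-open ``[start, end)`` intervals;
* a switch is a LEFT↔RIGHT change of the dominant percept, possibly via
  an intervening NONE gap — LEFT→NONE→LEFT is a return, not a switch;
* segments starting on a mixed percept have undefined congruency;
* segments containing any mixed-percept time are flagged so the
  switch-probability models can exclude them (the timecourse analysis
  keeps them).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .preprocess import CleanTrace
from .trace import DOMINANCE_STATES, NONE, TactileEvent

__all__ = [
    "Segment",
    "extract_segments",
    "segments_to_frame",
    "tabulate_outcomes",
    "count_switches",
]

MAINTAINED = "maintained"
SWITCHED = "switched"
MULTI_SWITCH = "multi_switch"
EXCLUDED_MIXED = "excluded_mixed"
EXCLUDED_NO_DOMINANCE = "excluded_no_dominance"

OUTCOME_CLASSES = (MAINTAINED, SWITCHED, MULTI_SWITCH)


@dataclass(frozen=True)
class Segment:
    trial_id: str
    participant_id: str
    condition: str
    onset_s: float
    window_s: float
    initial_state: str
    tactile_direction: str
    congruency_at_onset: str  # 'congruent' | 'incongruent' | 'undefined'
    n_switches_in_touch: int
    contains_mixed: bool
    outcome: str


def count_switches(
    intervals: Iterable[tuple[float, float, str]], start: float, end: float
) -> int:
    """Dominance switches (LEFT↔RIGHT, possibly through NONE) in [start, end].

    The dominant state entering the window counts as the reference; NONE
    time never contributes a switch by itself.
    """
    last_dom = None
    n = 0
    for s, e, state in intervals:
        if e <= start or s >= end:
            continue
        if state in DOMINANCE_STATES:
            if last_dom is not None and state != last_dom:
                n += 1
            last_dom = state
    return n


def _state_sequence_in(
    trace: CleanTrace, start: float, end: float
) -> list[tuple[float, float, str]]:
    out = []
    for s, e, state in trace.intervals:
        lo, hi = max(s, start), min(e, end)
        if hi > lo:
            out.append((lo, hi, state))
    return out


def extract_segments(
    trace: CleanTrace,
    events: Iterable[TactileEvent],
    window_s: float | None = None,
) -> list[Segment]:
    """One classified :class:`Segment` per tactile event of the trial.

    ``window_s`` defaults to each event's stimulation duration (the window
    the outcome classification is defined over).
    """
    segments = []
    for ev in events:
        w = ev.duration_s if window_s is None else window_s
        if ev.onset_s + w > trace.trial_length_s + 1e-9:
            raise ValueError(
                f"trial {trace.trial_id}: event at {ev.onset_s:.2f}s extends "
                "beyond the trace"
            )
        initial = trace.state_at(ev.onset_s)
        # reference for switch counting starts from the onset state; a
        # leading NONE defers the reference to the first dominance report
        window = _state_sequence_in(trace, ev.onset_s, ev.onset_s + w)
        n_switches = count_switches(window, ev.onset_s, ev.onset_s + w)
        contains_mixed = any(state == NONE for _, _, state in window)
        if initial == NONE:
            congruency = "undefined"
            outcome = EXCLUDED_NO_DOMINANCE
        else:
            congruency = (
                "congruent" if initial == ev.direction else "incongruent"
            )
            if contains_mixed:
                outcome = EXCLUDED_MIXED
            elif n_switches == 0:
                outcome = MAINTAINED
            elif n_switches == 1:
                outcome = SWITCHED
            else:
                outcome = MULTI_SWITCH
        segments.append(
            Segment(
                trial_id=trace.trial_id,
                participant_id=trace.participant_id,
                condition=trace.condition,
                onset_s=ev.onset_s,
                window_s=w,
                initial_state=initial,
                tactile_direction=ev.direction,
                congruency_at_onset=congruency,
                n_switches_in_touch=n_switches,
                contains_mixed=contains_mixed,
                outcome=outcome,
            )
        )
    return segments


def extract_all_segments(
    traces: Iterable[CleanTrace],
    events: Mapping[str, list[TactileEvent]],
) -> list[Segment]:
    out: list[Segment] = []
    for tr in traces:
        out.extend(extract_segments(tr, events[tr.trial_id]))
    return out


def segments_to_frame(segments: Iterable[Segment]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in segments])


def tabulate_outcomes(segments: Iterable[Segment]) -> pd.DataFrame:
    """Outcome probabilities per participant × condition × congruency.

    Counts maintained / switched-once / switched-multiple segments among
    those with defined onset congruency, classified purely by switch count
    (mixed-containing segments are included here; only the mixed-model path
    excludes them).  Probabilities in each cell sum to 1; empty cells are
    flagged with NaN probabilities.
    """
    df = segments_to_frame(list(segments))
    df = df[df["congruency_at_onset"] != "undefined"].copy()

    def classify(n: int) -> str:
        return MAINTAINED if n == 0 else (SWITCHED if n == 1 else MULTI_SWITCH)

    df["outcome_class"] = df["n_switches_in_touch"].map(classify)
    counts = (
        df.groupby(
            ["participant_id", "condition", "congruency_at_onset"],
            observed=True,
        )["outcome_class"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=list(OUTCOME_CLASSES), fill_value=0)
    )
    total = counts.sum(axis=1)
    probs = counts.div(total, axis=0)
    probs.columns = [f"p_{c}" for c in probs.columns]
    out = pd.concat([counts, probs], axis=1).reset_index()
    out["n_segments"] = total.values
    out["empty_cell"] = out["n_segments"] == 0
    return out
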