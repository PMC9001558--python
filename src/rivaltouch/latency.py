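"""Time to the first perceptual switch in visual-only vs bimodal segments.

For every tactile event two equal-length segments are formed: a unimodal
(visual-only) segment ending exactly at tactile onset and a bimodal
segment starting at it (4.25 s slow switchers / 2.95 s fast, so the
stimulus again fills a comparable fraction of the segment).  Bimodal
segments are split by onset congruency; unimodal segments pool both onset
states.  Only segments containing exactly one dominance switch contribute
a latency, expressed as a proportion of segment length so the two switch
groups can be aggregated.

Participant-level mean latencies per condition × segment type feed a
2 × 3 repeated-measures ANOVA with Mauchly's sphericity test,
Greenhouse–Geisser correction when sphericity is violated, and generalized
eta squared effect sizes; follow-up paired t-tests are Bonferroni-corrected
by the three segment-type pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

from .config import LatencySpec
from .preprocess import CleanTrace
from .segments import count_switches
from .trace import DOMINANCE_STATES, NONE, TactileEvent

log = logging.getLogger(__name__)

__all__ = [
    "LatencySegment",
    "build_latency_segments",
    "latency_table",
    "rm_anova_2x3",
    "paired_contrasts",
    "AnovaResult",
]

UNIMODAL = "unimodal"
BIMODAL_CONGRUENT = "bimodal_congruent"
BIMODAL_INCONGRUENT = "bimodal_incongruent"
SEGMENT_KINDS = (UNIMODAL, BIMODAL_CONGRUENT, BIMODAL_INCONGRUENT)


@dataclass(frozen=True)
class LatencySegment:
    trial_id: str
    participant_id: str
    condition: str
    kind: str
    start_s: float
    length_s: float
    n_switches: int
    first_switch_latency_prop: float | None  # None unless exactly one switch


def _first_switch_latency(
    trace: CleanTrace, start: float, end: float
) -> float | None:
    """Time of the first LEFT↔RIGHT dominance change within [start, end)."""
    last_dom = None
    for s, e, state in trace.intervals:
        if e <= start or s >= end:
            continue
        if state in DOMINANCE_STATES:
            if last_dom is not None and state != last_dom:
                return max(s, start) - start
            last_dom = state
    return None


def build_latency_segments(
    trace: CleanTrace,
    events: Iterable[TactileEvent],
    length_s: float,
) -> list[LatencySegment]:
    """Paired unimodal/bimodal segments for every tactile event.

    Pairs whose unimodal window would start before the trial, or whose
    bimodal window would run past its end, are dropped with a log entry.
    Bimodal segments with a mixed percept at onset carry no congruency and
    are dropped too.
    """
    out: list[LatencySegment] = []
    for ev in events:
        uni_start = ev.onset_s - length_s
        if uni_start < -1e-9 or ev.onset_s + length_s > trace.trial_length_s + 1e-9:
            log.info(
                "trial %s: latency pair at onset %.2fs outside trial; dropped",
                trace.trial_id,
                ev.onset_s,
            )
            continue
        onset_state = trace.state_at(ev.onset_s)
        for kind, start in ((UNIMODAL, uni_start), ("bimodal", ev.onset_s)):
            if kind == "bimodal":
                if onset_state == NONE:
                    continue
                kind = (
                    BIMODAL_CONGRUENT
                    if onset_state == ev.direction
                    else BIMODAL_INCONGRUENT
                )
            end = start + length_s
            n_sw = count_switches(trace.intervals, start, end)
            latency = (
                _first_switch_latency(trace, start, end) if n_sw == 1 else None
            )
            out.append(
                LatencySegment(
                    trial_id=trace.trial_id,
                    participant_id=trace.participant_id,
                    condition=trace.condition,
                    kind=kind,
                    start_s=start,
                    length_s=length_s,
                    n_switches=n_sw,
                    first_switch_latency_prop=(
                        latency / length_s if latency is not None else None
                    ),
                )
            )
    return out


def latency_table(
    traces: Iterable[CleanTrace],
    events: Mapping[str, list[TactileEvent]],
    spec: LatencySpec,
    profiles: Mapping[str, str],
    conditions: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Participant × condition × segment-kind mean latency proportions.

    Only single-switch segments contribute.  If ``conditions`` is given the
    table is restricted (and ordered) accordingly.
    """
    segs: list[LatencySegment] = []
    for tr in traces:
        if conditions is not None and tr.condition not in conditions:
            continue
        L = spec.segment_length_s(profiles[tr.participant_id])
        segs.extend(build_latency_segments(tr, events[tr.trial_id], L))
    rows = [
        {
            "participant_id": s.participant_id,
            "condition": s.condition,
            "kind": s.kind,
            "latency_prop": s.first_switch_latency_prop,
        }
        for s in segs
        if s.first_switch_latency_prop is not None
    ]
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    return (
        df.groupby(["participant_id", "condition", "kind"], observed=True)[
            "latency_prop"
        ]
        .mean()
        .reset_index()
    )


@dataclass(frozen=True)
class AnovaResult:
    effect: str
    F: float
    df_num: float
    df_den: float
    p: float
    gg_epsilon: float
    gg_applied: bool
    eta_g_sq: float
    mauchly_p: float


def rm_anova_2x3(participant_means: pd.DataFrame) -> list[AnovaResult]:
    """2 (condition) × 3 (segment kind) repeated-measures ANOVA.

    ``participant_means`` is the tidy output of :func:`latency_table`.
    Participants with incomplete cells are dropped listwise (logged).
    For each within-subject effect, Mauchly's test decides whether the
    Greenhouse–Geisser correction is applied (threshold .05); epsilon is
    reported either way and the corrected degrees of freedom are used for
    the p-value when sphericity fails.  Effect sizes are generalized eta
    squared.
    """
    df = participant_means.copy()
    conds = sorted(df["condition"].unique())
    kinds = [k for k in SEGMENT_KINDS if k in set(df["kind"])]
    if len(conds) != 2 or len(kinds) != 3:
        raise ValueError("expected 2 conditions × 3 segment kinds")
    cell_counts = df.groupby("participant_id", observed=True).size()
    complete = cell_counts[cell_counts == 6].index
    dropped = set(df["participant_id"]) - set(complete)
    if dropped:
        log.info("listwise-deleted incomplete participants: %s", sorted(dropped))
    df = df[df["participant_id"].isin(complete)]
    if df["participant_id"].nunique() < 3:
        raise ValueError("need at least 3 complete participants")

    aov = pg.rm_anova(
        data=df,
        dv="latency_prop",
        within=["condition", "kind"],
        subject="participant_id",
        correction=True,
        effsize="ng2",
        detailed=True,
    )
    results = []
    for _, row in aov.iterrows():
        source = str(row["Source"])
        eps = float(row["eps"]) if not pd.isna(row["eps"]) else 1.0
        if source == "condition":
            eps = 1.0  # two-level factor: sphericity holds trivially
        # Mauchly's test on the cells the effect averages over
        mauchly_p = 1.0
        if source == "kind":
            spher = pg.sphericity(
                data=df.groupby(["participant_id", "kind"], observed=True)[
                    "latency_prop"
                ]
                .mean()
                .reset_index(),
                dv="latency_prop",
                within="kind",
                subject="participant_id",
            )
            mauchly_p = float(spher.pval)
        elif "*" in source:
            spher = pg.sphericity(
                data=df,
                dv="latency_prop",
                within=["condition", "kind"],
                subject="participant_id",
            )
            mauchly_p = float(spher.pval)
        apply_gg = mauchly_p < 0.05 and eps < 1.0
        df1, df2 = float(row["ddof1"]), float(row["ddof2"])
        if apply_gg:
            df1, df2 = df1 * eps, df2 * eps
            p = float(row["p_GG_corr"])
        else:
            p = float(row["p_unc"])
        results.append(
            AnovaResult(
                effect=source,
                F=float(row["F"]),
                df_num=df1,
                df_den=df2,
                p=p,
                gg_epsilon=eps,
                gg_applied=apply_gg,
                eta_g_sq=float(row["ng2"]),
                mauchly_p=mauchly_p,
            )
        )
    return results


def paired_contrasts(
    participant_means: pd.DataFrame,
    condition: str,
    correction_factor: int = 3,
) -> pd.DataFrame:
    """Paired t-tests between segment kinds within one condition.

    Raw two-sided p-values are Bonferroni-corrected by the number of
    segment-type pairs (3), capped at 1.
    """
    df = participant_means[participant_means["condition"] == condition]
    wide = df.pivot(index="participant_id", columns="kind", values="latency_prop")
    rows = []
    for a, b in combinations([k for k in SEGMENT_KINDS if k in wide.columns], 2):
        paired = wide[[a, b]].dropna()
        d = paired[a] - paired[b]
        if np.allclose(d, 0.0):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(paired[a], paired[b])
        rows.append(
            {
                "condition": condition,
                "pair": f"{a} vs {b}",
                "mean_a": paired[a].mean(),
                "mean_b": paired[b].mean(),
                "t": float(t),
                "df": len(paired) - 1,
                "p_raw": float(p),
                "p_adj": float(min(1.0, correction_factor * p)),
            }
        )
    return pd.DataFrame(rows)
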