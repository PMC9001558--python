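"""Normalized tactile-onset-locked congruent-probability timecourses.

Each tactile event yields a segment running from its onset for a
group-specific length (9 s slow / 5.91 s fast switchers, so that the
stimulus occupies the same 0.36 fraction of normalized time in both
groups).  Per segment, normalized time is split into 36 bins and each bin
scores the fraction of dominance time spent congruent with the tactile
direction; mixed-percept time is excluded by time weighting, and bins
without dominance time are missing.  Segments enter regardless of their
onset congruency, so a null trace sits at chance (0.5).

Averaging order is fixed: segments → participant mean trace → group-level
tests.  Per-bin one-sample t-tests against chance (two-tailed, alpha .025)
are corrected with Benjamini–Hochberg FDR across the 36 bins.  Condition
differences are assessed with a cluster-mass permutation test in the
standard paired-design form: participant-wise sign flipping of difference
traces, clusters of adjacent same-sign supra-threshold t-values scored by
their summed t, and the 95th percentile of the permutation maxima as the
significance limit.  (The literal shuffle of responses across bins and
conditions is available as an alternative scheme for comparison.)
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import TimecourseSpec
from .preprocess import CleanTrace
from .trace import DOMINANCE_STATES, TactileEvent

log = logging.getLogger(__name__)

__all__ = [
    "congruency_trace",
    "participant_timecourses",
    "bin_tests",
    "difference_waveform",
    "cluster_permutation_test",
    "BinTestResult",
    "Cluster",
    "ClusterTestResult",
]


def congruency_trace(
    trace: CleanTrace,
    event: TactileEvent,
    segment_length_s: float,
    n_bins: int = 36,
) -> np.ndarray:
    """Per-bin probability of the dominant percept being tactile-congruent.

    Returns ``n_bins`` values in [0, 1]; bins with no dominance time are
    NaN.  Raises if the segment is truncated by the trial end.
    """
    start = event.onset_s
    end = start + segment_length_s
    if end > trace.trial_length_s + 1e-9:
        raise ValueError(
            f"trial {trace.trial_id}: segment at {start:.2f}s truncated by "
            "trial end"
        )
    edges = start + np.linspace(0.0, segment_length_s, n_bins + 1)
    dom = np.zeros(n_bins)
    congr = np.zeros(n_bins)
    for s, e, state in trace.intervals:
        if e <= start or s >= end or state not in DOMINANCE_STATES:
            continue
        overlap = np.clip(
            np.minimum(e, edges[1:]) - np.maximum(s, edges[:-1]), 0.0, None
        )
        dom += overlap
        if state == event.direction:
            congr += overlap
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = np.where(dom > 0, congr / np.maximum(dom, 1e-300), np.nan)
    return probs


def participant_timecourses(
    traces: Iterable[CleanTrace],
    events: Mapping[str, list[TactileEvent]],
    spec: TimecourseSpec,
    profiles: Mapping[str, str],
) -> pd.DataFrame:
    """Average segment traces into one 36-bin trace per participant × condition.

    Returns a tidy frame indexed by (participant_id, condition) with columns
    ``bin00..bin35`` and ``n_segments``.  Segments truncated by the trial
    end are dropped with a log entry.
    """
    acc: dict[tuple[str, str], list[np.ndarray]] = {}
    n_dropped = 0
    for tr in traces:
        L = spec.segment_length_s(profiles[tr.participant_id])
        for ev in events[tr.trial_id]:
            if ev.onset_s + L > tr.trial_length_s + 1e-9:
                n_dropped += 1
                continue
            probs = congruency_trace(tr, ev, L, spec.n_bins)
            acc.setdefault((tr.participant_id, tr.condition), []).append(probs)
    if n_dropped:
        log.info("dropped %d truncated segments", n_dropped)
    rows = []
    for (pid, cond), seg_list in sorted(acc.items()):
        arr = np.vstack(seg_list)
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(arr, axis=0)
        row = {"participant_id": pid, "condition": cond,
               "n_segments": len(seg_list)}
        row.update({f"bin{i:02d}": mean[i] for i in range(spec.n_bins)})
        rows.append(row)
    return pd.DataFrame(rows)


def _bin_matrix(tc: pd.DataFrame, n_bins: int) -> tuple[np.ndarray, list[str]]:
    cols = [f"bin{i:02d}" for i in range(n_bins)]
    return tc[cols].to_numpy(dtype=float), list(tc["participant_id"])


@dataclass
class BinTestResult:
    t: np.ndarray
    p: np.ndarray
    p_fdr: np.ndarray
    significant: np.ndarray  # post-FDR mask at alpha_bin
    tested: np.ndarray  # bins that entered testing
    n_per_bin: np.ndarray
    significant_duration_s: dict[str, float]  # per switcher group


def bin_tests(
    timecourse: pd.DataFrame, spec: TimecourseSpec
) -> BinTestResult:
    """Per-bin one-sample t-tests against chance with BH-FDR over bins.

    ``timecourse`` holds one condition's participant traces (the output of
    :func:`participant_timecourses` filtered to one condition).  Bins with
    fewer than two contributing participants, or zero variance, are masked
    out of testing.  The significant duration converts the count of
    significant bins back to seconds of each group's real segment length.
    """
    data, _ = _bin_matrix(timecourse, spec.n_bins)
    n_bins = spec.n_bins
    n = np.sum(~np.isnan(data), axis=0)
    t = np.full(n_bins, np.nan)
    p = np.full(n_bins, np.nan)
    tested = np.zeros(n_bins, dtype=bool)
    for b in range(n_bins):
        vals = data[:, b]
        vals = vals[~np.isnan(vals)]
        if len(vals) < 2 or np.allclose(np.var(vals), 0.0):
            continue
        res = stats.ttest_1samp(vals, spec.chance)
        t[b], p[b] = res.statistic, res.pvalue
        tested[b] = True
    p_fdr = np.full(n_bins, np.nan)
    significant = np.zeros(n_bins, dtype=bool)
    if tested.any():
        rej, p_adj, _, _ = multipletests(
            p[tested], alpha=spec.alpha_bin, method="fdr_bh"
        )
        p_fdr[tested] = p_adj
        significant[tested] = rej
    n_sig = int(significant.sum())
    durations = {
        "slow": n_sig * spec.segment_length_slow_s / n_bins,
        "fast": n_sig * spec.segment_length_fast_s / n_bins,
    }
    return BinTestResult(
        t=t,
        p=p,
        p_fdr=p_fdr,
        significant=significant,
        tested=tested,
        n_per_bin=n,
        significant_duration_s=durations,
    )


def difference_waveform(
    cond_a: pd.DataFrame, cond_b: pd.DataFrame, n_bins: int = 36
) -> pd.DataFrame:
    """Per-participant elementwise (a − b) traces for paired conditions.

    Participants missing from either condition are dropped; missing bins
    propagate as NaN.
    """
    cols = [f"bin{i:02d}" for i in range(n_bins)]
    a = cond_a.set_index("participant_id")[cols]
    b = cond_b.set_index("participant_id")[cols]
    shared = a.index.intersection(b.index)
    diff = a.loc[shared] - b.loc[shared]
    return diff.reset_index()


@dataclass(frozen=True)
class Cluster:
    start_bin: int  # inclusive
    end_bin: int  # inclusive
    sign: int
    mass: float


@dataclass
class ClusterTestResult:
    t_obs: np.ndarray
    threshold_t: np.ndarray  # per-bin critical t (df follows available n)
    observed_clusters: list[Cluster]
    perm_distribution: np.ndarray  # max |mass| per permutation
    significance_limit: float  # 95th percentile of perm_distribution
    significant_clusters: list[Cluster]
    cluster_p: list[float]
    n_permutations: int


def find_clusters(
    t: np.ndarray, threshold: np.ndarray, tested: np.ndarray
) -> list[Cluster]:
    """Maximal runs of adjacent same-sign supra-threshold bins.

    Untested (masked) bins break adjacency.
    """
    clusters: list[Cluster] = []
    start = None
    sign = 0
    mass = 0.0
    for b in range(len(t)):
        supra = tested[b] and abs(t[b]) > threshold[b]
        s = int(np.sign(t[b])) if supra else 0
        if supra and s == sign and start is not None:
            mass += t[b]
        else:
            if start is not None and sign != 0:
                clusters.append(Cluster(start, b - 1, sign, mass))
            if supra:
                start, sign, mass = b, s, t[b]
            else:
                start, sign, mass = None, 0, 0.0
    if start is not None and sign != 0:
        clusters.append(Cluster(start, len(t) - 1, sign, mass))
    return clusters


def _nan_t(data: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """NaN-aware per-bin one-sample t against 0 with per-bin df."""
    mask = ~np.isnan(data)
    n = mask.sum(axis=0)
    filled = np.where(mask, data, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = filled.sum(axis=0) / n
        var = (
            (filled**2).sum(axis=0) - n * mean**2
        ) / np.maximum(n - 1, 1)
        t = mean / np.sqrt(var / n)
    tested = (n >= 2) & (var > 1e-300)
    t = np.where(tested, t, np.nan)
    return t, n, tested


def _perm_t(
    data: np.ndarray, signs: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """t statistics for all sign-flipped datasets at once.

    ``signs`` is (n_perm, n_participants) of ±1.  Sign flips leave per-bin
    second moments unchanged, so variance follows from the flipped mean.
    Returns (t, tested) of shape (n_perm, n_bins).
    """
    mask = ~np.isnan(data)
    n = mask.sum(axis=0)
    filled = np.where(mask, data, 0.0)
    sumsq = (filled**2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = (signs @ filled) / n
        var = (sumsq - n * mean**2) / np.maximum(n - 1, 1)
        var = np.maximum(var, 0.0)
        t = mean / np.sqrt(var / n)
    tested = (n >= 2) & (var > 1e-300)
    return t, tested


def cluster_permutation_test(
    diff_traces: pd.DataFrame,
    n_perm: int = 1000,
    alpha: float = 0.025,
    rng: np.random.Generator | None = None,
    *,
    n_bins: int = 36,
    exhaustive: bool = False,
) -> ClusterTestResult:
    """Cluster-mass permutation test on paired difference traces.

    Observed stage: per-bin one-sample t against zero; bins with
    ``|t| > t_{1-alpha, n-1}`` are clustered by temporal adjacency and
    sign, each scored by its summed t.  Permutation stage: each
    participant's difference trace is sign-flipped at random, the max
    absolute cluster mass recorded per permutation; clusters whose
    |mass| exceeds the 95th percentile of those maxima are significant.
    With ``exhaustive=True`` all 2^n sign assignments are enumerated
    instead of sampled.
    """
    data, _ = _bin_matrix(diff_traces, n_bins)
    n_participants = data.shape[0]
    if n_participants < 2:
        raise ValueError("need at least 2 participants")
    if np.all(np.isnan(data)):
        raise ValueError("all bins missing")
    if n_perm < 100:
        log.warning("n_perm=%d is small; permutation quantiles will be noisy",
                    n_perm)

    t_obs, n, tested = _nan_t(data)
    threshold = np.where(
        n >= 2, stats.t.ppf(1.0 - alpha, np.maximum(n - 1, 1)), np.inf
    )
    observed = find_clusters(
        np.where(tested, t_obs, 0.0), threshold, tested
    )

    if exhaustive:
        signs = np.array(
            list(itertools.product((1.0, -1.0), repeat=n_participants))
        )
    else:
        if rng is None:
            rng = np.random.default_rng()
        signs = rng.choice((-1.0, 1.0), size=(n_perm, n_participants))
    t_perm, tested_perm = _perm_t(data, signs)
    maxima = np.zeros(len(signs))
    for r in range(len(signs)):
        tr = np.where(tested_perm[r], t_perm[r], 0.0)
        clusters = find_clusters(tr, threshold, tested_perm[r])
        if clusters:
            maxima[r] = max(abs(c.mass) for c in clusters)
    limit = float(np.percentile(maxima, 95.0))
    significant = [c for c in observed if abs(c.mass) > limit]
    cluster_p = [
        float((1 + np.sum(maxima >= abs(c.mass))) / (len(signs) + 1))
        for c in observed
    ]
    return ClusterTestResult(
        t_obs=t_obs,
        threshold_t=threshold,
        observed_clusters=observed,
        perm_distribution=maxima,
        significance_limit=limit,
        significant_clusters=significant,
        cluster_p=cluster_p,
        n_permutations=len(signs),
    )


def cluster_permutation_test_shuffle(
    cond_a: pd.DataFrame,
    cond_b: pd.DataFrame,
    n_perm: int = 1000,
    alpha: float = 0.025,
    rng: np.random.Generator | None = None,
    *,
    n_bins: int = 36,
) -> ClusterTestResult:
    """Literal shuffling variant: per permutation each participant's
    responses are shuffled across bins and conditions before the
    difference is reformed.  Provided for comparison with the standard
    sign-flip scheme; exchangeability across bins is a stronger assumption
    than across conditions only.
    """
    if rng is None:
        rng = np.random.default_rng()
    cols = [f"bin{i:02d}" for i in range(n_bins)]
    a = cond_a.set_index("participant_id")[cols]
    b = cond_b.set_index("participant_id")[cols]
    shared = a.index.intersection(b.index)
    A = a.loc[shared].to_numpy(float)
    B = b.loc[shared].to_numpy(float)
    diff = A - B
    t_obs, n, tested = _nan_t(diff)
    threshold = np.where(
        n >= 2, stats.t.ppf(1.0 - alpha, np.maximum(n - 1, 1)), np.inf
    )
    observed = find_clusters(np.where(tested, t_obs, 0.0), threshold, tested)
    maxima = np.zeros(n_perm)
    stacked = np.concatenate([A, B], axis=1)  # participant × (2·n_bins)
    for r in range(n_perm):
        perm = np.empty_like(stacked)
        for i in range(stacked.shape[0]):
            perm[i] = rng.permutation(stacked[i])
        d = perm[:, :n_bins] - perm[:, n_bins:]
        t_r, _, tested_r = _nan_t(d)
        clusters = find_clusters(
            np.where(tested_r, t_r, 0.0), threshold, tested_r
        )
        if clusters:
            maxima[r] = max(abs(c.mass) for c in clusters)
    limit = float(np.percentile(maxima, 95.0))
    significant = [c for c in observed if abs(c.mass) > limit]
    cluster_p = [
        float((1 + np.sum(maxima >= abs(c.mass))) / (n_perm + 1))
        for c in observed
    ]
    return ClusterTestResult(
        t_obs=t_obs,
        threshold_t=threshold,
        observed_clusters=observed,
        perm_distribution=maxima,
        significance_limit=limit,
        significant_clusters=significant,
        cluster_p=cluster_p,
        n_permutations=n_perm,
    )
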