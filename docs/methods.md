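# Methods

This note documents the models, conventions, and design choices behind
`rivaltouch`; the README covers usage.

## The generative model

Perceptual alternation in one trial is an alternating renewal process.
Dominance durations are drawn from a gamma distribution — the standard
empirical model for rivalry phase durations, which are unimodal,
right-skewed, and have coefficient of variation near 0.5–0.6. The shape
parameter defaults to 3.5 (`gamma_shape`, dimensionless) and the mean is
participant-specific: 2.2 s for fast switchers, 3.5 s for slow ones
(`mean_dominance_fast_s` / `mean_dominance_slow_s`), matching the group
means the analysis geometry is built around. With probability `p_mixed`
(default 0.3) a transition passes through a mixed-percept (NONE) gap with
lognormal duration (mean 0.4 s, log-sd 0.5); real rivalry transitions
frequently pass through such piecemeal states, and the preprocessing path
must be exercised by them.

Tactile stimulation perturbs the process by **multiplicative hazard
modulation**: while a stimulus is active, the current percept's switch
hazard is multiplied by `hazard_mult_congruent` (< 1 stabilises) when the
percept matches the tactile direction, else by `hazard_mult_incongruent`
(> 1 curtails the suppression of the congruent percept). The modulation
is implemented by operational-time rescaling — the renewal clock of the
current dominance period advances at the multiplier's rate during
stimulation — which is exactly a multiplicative perturbation of the
instantaneous hazard and is memoryless across stimulus boundaries. The
multipliers apply only in conditions listed in `effect_conditions`
(default: the parallel-axes, spatially-aligned conditions, with hand
visibility irrelevant), which encodes the scientific claim under test.

Trial structure: 48-s trials, four tactile stimuli, the first at 8 s,
subsequent onsets every 10 s plus a uniform ±1-s jitter (read as uniform;
the source design states only "1 s jitter"). Each stimulus is 2 sweeps
(fast switchers) or 3 sweeps (slow) of 1 s with 100-ms inter-sweep
pauses, hence 2.1 s or 3.2 s total. Sweep directions are counterbalanced
within trial (2 left, 2 right, shuffled) and all sweeps of one stimulus
share a direction — the congruency analyses presuppose a single direction
per stimulus. Trials in the orthogonal-axes condition are generated on
the vertical response axis (UP/DOWN) and remapped during preprocessing.
The configuration validator requires the worst-case schedule (maximal
jitter, 3 sweeps) to fit inside the trial.

Randomness: one dataset seed, split per (participant, condition, trial)
by counter keys, so extending the trial count never reshuffles earlier
trials, and identical configurations give bitwise-identical dataset
files. The switcher profile is configured as a fast-participant count
(`n_fast`; fast participants come first) rather than a free mapping — a
deliberate simplification that keeps configurations serialisable.

**What the simulator does not emulate:** neural adaptation/inhibition
dynamics, sequential dependence between successive dominance durations,
onset rivalry, eye dominance, blinks, reaction-time lags between a
perceptual switch and the button report, and response errors. Passing
recovery tests therefore shows that the analysis chain detects (and does
not hallucinate) effects of the assumed hazard-modulation form in
renewal-like data; it does not certify behaviour on real recordings with
motor noise or non-renewal structure.

## Preprocessing

Dominance reports of ≤ 180 ms (threshold inclusive) are motor artefacts
and are relabelled NONE rather than merged into a neighbour — merging
would fabricate dominance time the participant never reported. The
relabelling is idempotent and conserves total time; `removed_time_s`
accounts for the relabelled span. Vertical-axis reports are remapped
UP→LEFT, DOWN→RIGHT so congruency is defined on a common axis.
Fast/slow classification (mean dominance < 3 s → fast, ties slow) is
computed from a designated calibration subset — the first four trials of
each condition — standing in for the practice block that preceded the
real experiment. Means include intervals truncated by trial boundaries,
which biases them a few percent below the generating gamma mean; this is
immaterial to classification because the group means sit far from the
3-s boundary.

## Segmentation conventions

* State at the onset instant uses half-open `[start, end)` intervals.
* A switch is a LEFT↔RIGHT change of dominance, possibly through a NONE
  gap; LEFT→NONE→LEFT is a return, not a switch. Any dominance state
  overlapping the touch window by a positive amount enters the switch
  count.
* Segments with NONE at onset have undefined congruency and are excluded
  everywhere. Segments containing mixed time with a defined onset state
  are excluded from the switch-probability model only; the timecourse
  keeps them (mixed time is excluded by time weighting instead), and the
  outcome tabulation classifies them by switch count.

## Switch-probability mixed model

No maintained Python package fits binomial random-intercept GLMMs, so the
fitter is implemented here: the random intercept is integrated out by
adaptive Gauss–Hermite quadrature (25 nodes, recentred at each group's
posterior mode found by Newton iteration and rescaled by its curvature),
and the marginal likelihood is maximised by L-BFGS-B over (β, log σ) from
a pooled-logistic start plus jittered restarts (guarding against local
optima). Accuracy contract, test-pinned: the default log-likelihood
agrees with a 40-node reference to 10⁻³, and with σ pinned near zero the
coefficients agree with a plain logistic fit to 10⁻³. Standard errors
come from the numerical Hessian at the optimum; when the variance sits on
its boundary (σ ≈ 0) the Hessian is singular in log σ and the
fixed-effects block is inverted instead, with the fit flagged
`boundary`. Coefficients above 15 in absolute value raise a separation
flag — near-deterministic cells are expected under strong simulated
effects at small sample sizes.

The interaction is tested by a 1-df likelihood-ratio test (χ² clipped at
zero). Follow-up contrasts are differences of inverse-link cell means
with the random intercept at its zero population mean — the "response
scale" convention — with delta-method standard errors and two-sided
z-tests; no multiplicity correction across the two follow-up contrasts.

## Timecourse analysis

Segment geometry is fixed by the design: 9 s (slow) / 5.91 s (fast) from
tactile onset, 36 bins on normalized time, so stimulation occupies 0.36
of either segment (3.2/9 and 2.1/5.91 both round to 0.36; 5.91 is the
proportion-matched value 2.1 × 9 / 3.2 as printed in the design, not
recomputed). Per bin the congruent probability is the fraction of
dominance time congruent with the tactile direction — NONE time is
excluded by time weighting (its handling is otherwise unspecified, and
time-weighted exclusion is the convention adopted here); a bin with no
dominance time is missing. Averaging order is fixed and test-pinned:
segments → participant trace → group tests. Segments truncated by the
trial end are dropped.

Per-bin one-sample t-tests against 0.5 (two-tailed, α = .025) are
BH-FDR-corrected across the 36 bins of one timecourse; bins with fewer
than two contributing participants or zero variance are masked rather
than producing infinite t. Significant durations convert bin counts back
to seconds of each group's real segment length.

Condition effects use difference waveforms and a cluster-mass permutation
test. The permutation scheme is participant-wise **sign flipping** of
difference traces — the standard paired-design scheme in the
Maris–Oostenveld framework; a literal shuffle of responses across bins
and conditions is also implemented (`cluster_permutation_test_shuffle`)
for comparison, but bin-wise exchangeability is a much stronger null than
condition exchangeability, so sign flipping is the default. Clusters are
maximal runs of temporally adjacent supra-threshold bins of one sign
(threshold: 97.5th Student-t quantile at the per-bin df), scored by
summed t; missing bins break adjacency (conservative); significance is
|mass| above the 95th percentile of the per-permutation maximal absolute
masses (1 000 permutations; exact enumeration available and test-verified
at n = 5). Per-cluster Monte-Carlo p-values use the add-one convention.

## Latency analysis

Per tactile event, a unimodal segment `[onset − L, onset)` and a bimodal
segment `[onset, onset + L)` with L = 4.25 s (slow) / 2.95 s (fast) —
taken verbatim from the design, which prints 4.25 rather than the exact
half of 9/2 — so segment pairs never overlap and counts match before
filtering. Bimodal segments split by onset congruency; note the naming
duality: a *congruent-onset* segment can only contain a switch *to
incongruence* and vice versa. Unimodal segments pool both onset states.
Only segments with exactly one switch contribute a latency, expressed as
a proportion of L.

Participant × condition × segment-kind means feed a 2 × 3
repeated-measures ANOVA (pingouin), with Mauchly's test (conventional
.05 threshold; unstated in the source design) deciding whether
Greenhouse–Geisser-corrected degrees of freedom are used, and generalized
eta squared as effect size; ε is cross-checked in the tests against the
covariance-eigenvalue definition and the F-values against an independent
implementation (statsmodels AnovaRM). Paired contrasts are two-sided
paired t-tests with Bonferroni correction ×3, capped at 1.

## Recovery and calibration suites

Recovery cohorts: 14 participants (9 slow / 5 fast), 32 trials × 4
events per condition, hazard multipliers 3.0 / 0.4 gated to the
parallel-aligned condition, orthogonal axes as contrast. The suite
scores, across seeded replicates: the interaction LRT (p < .05), a
significant positive cluster inside the touch window of the
parallel − orthogonal difference, and the latency ordering
congruent-onset > baseline > incongruent-onset. Null cohorts set both
multipliers to 1 and use 8 trials per condition — the calibration
questions (type-I rates) do not need the full trial count, and the
reduced size keeps 200-replicate suites cheap; scored are the raw
per-bin rejection rate against α, the rate of datasets with any
significant cluster against the 5% the two-tailed .025 threshold
implies, and the GLMM interaction type-I rate against 5%. The test suite
runs 50 recovery and 200 null replicates; `scripts/acceptance.py` uses
15 and 80 for a faster stand-alone reproduction with the same
constructions.

## Known limitations

* The GLMM supports exactly two two-level fixed factors with a scalar
  random intercept — the design of interest — not a formula interface.
* No random slopes (by design: intercept-only models are the target),
  no Bayesian alternative.
* The simulator's null is fully exchangeable across directions; real
  observers show eye and direction biases that would load the random
  intercept and could make the boundary-variance path rarer than in
  simulation.
* Latency ANOVA requires at least three participants with complete
  2 × 3 cells; incomplete participants are dropped listwise.
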