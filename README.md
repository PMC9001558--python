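# rivaltouch

Event-locked analysis of how tactile motion perturbs binocular rivalry,
packaged as a reusable Python pipeline with a stochastic generator of
rivalry button-press data.

## The problem

In binocular rivalry, two incompatible images (e.g. gratings drifting left
and right) are shown one to each eye and perception alternates between
them every few seconds. A tactile motion stimulus swept across the
fingerpad during rivalry can stabilise the visual percept that moves in
the same direction and destabilise the opposite one — but only when the
visual and tactile motion axes are parallel and the stimuli are spatially
aligned. Testing that claim requires an event-locked analysis of
button-press records around each tactile onset:

* **Segments** — each trial contains four tactile stimuli; each stimulus
  defines a segment classified by *congruency at onset* (dominant percept
  matches the tactile direction or not) and *outcome* (percept maintained,
  switched once, or switched more than once during stimulation).
* **Switch-probability model** — segment-level switch outcomes (0/1) are
  modelled with a binomial random-intercept GLMM,
  `logit P(switch) = β₀ + β_cond + β_congr + β_cond×congr + u_i`,
  `u_i ~ N(0, σ²)` per participant. The congruency × condition interaction
  is tested with a 1-df likelihood-ratio test, followed by pairwise
  contrasts of estimated marginal means on the probability scale.
* **Timecourse** — the probability that the dominant percept is
  tactile-congruent is tracked over a normalized post-onset window
  (9 s for slow switchers, 5.91 s for fast ones, so the stimulus occupies
  0.36 of both), binned into 36 bins, tested against chance (0.5) per bin
  with Benjamini–Hochberg FDR, and condition differences assessed with a
  cluster-mass permutation test (sign flipping, 1 000 permutations, 95th
  percentile of maximal cluster masses as the significance limit).
* **Latency** — time to the first perceptual switch in visual-only
  segments preceding each tactile onset vs. tactile segments following it,
  as a proportion of segment length, analysed with a 2 × 3
  repeated-measures ANOVA (Greenhouse–Geisser corrected when Mauchly's
  test fails) and Bonferroni-corrected paired contrasts.

Because raw participant recordings for this paradigm are not publicly
deposited, the package ships a simulator (`rivaltouch.simulate`) that
generates the same kind of data: gamma-distributed dominance durations
(fast ≈ 2.2 s / slow ≈ 3.5 s switchers), mixed-percept gaps, 48-s trials
with four tactile stimuli (first at 8 s, then every 10 ± 1 s; 2 or 3
one-second sweeps with 100-ms pauses), and an optional condition-gated
congruency effect implemented as multiplicative switch-hazard modulation
during stimulation. The analyses are validated by parameter recovery
against the simulator's ground truth.

## Worked example

```python
from rivaltouch import PipelineConfig, SimConfig, run_pipeline

sim = SimConfig(
    n_participants=14, n_fast=5, n_trials_per_condition=32,
    conditions=("parallel_aligned_visible", "orthogonal_aligned"),
    effect_conditions=frozenset({"parallel_aligned_visible"}),
    hazard_mult_congruent=0.4,   # congruent percepts stabilised
    hazard_mult_incongruent=3.0, # incongruent percepts destabilised
)
report = run_pipeline(PipelineConfig(sim=sim, seed=3))
eff = report["effects"]["direction_selectivity"]
print(round(eff["glmm"]["interaction_chi2"], 1), eff["glmm"]["interaction_p"])
print(eff["cluster_test"]["positive_cluster_in_touch_window"])
print({k: round(v, 2) for k, v in eff["latency"]["cell_means"].items()})
```

prints

```
614.0 1.4769482150077893e-135
True
{'orthogonal_aligned|bimodal_congruent': 0.51,
 'orthogonal_aligned|bimodal_incongruent': 0.52,
 'orthogonal_aligned|unimodal': 0.52,
 'parallel_aligned_visible|bimodal_congruent': 0.79,
 'parallel_aligned_visible|bimodal_incongruent': 0.21,
 'parallel_aligned_visible|unimodal': 0.52}
```

The interaction LRT flags the condition-gated congruency effect; a
significant positive cluster sits inside the touch window of the
parallel − orthogonal difference waveform; and first-switch latencies in
the effect-bearing condition show the expected ordering — congruent-onset
percepts (whose only possible switch is *to incongruence*) switch late
(0.79), incongruent-onset percepts (switching *to congruence*) early
(0.21), visual-only baseline in between (0.52) — while the orthogonal
condition stays flat at the baseline.

The same pipeline is available from the shell:

```bash
rivaltouch simulate --config cfg.yaml --seed 3 --out raw/
rivaltouch preprocess --in raw/ --out clean/
rivaltouch segment --in clean/ --out segments.csv
rivaltouch reproduce --config cfg.yaml --seed 3 --out report.json
```

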