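"""Configuration objects for simulation and analysis.

All durations are in seconds. Defaults reproduce the trial structure of a
binocular-rivalry experiment with intermittent tactile motion stimuli:
48-s trials containing four tactile sweeps-stimuli, the first at 8 s and
the rest every 10 s with a uniform 1-s onset jitter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import yaml

#: Condition labels. The congruency effect is expected only when the visual
#: and tactile motion axes are parallel AND the stimuli are spatially aligned;
#: hand visibility is not expected to matter.
CONDITIONS = (
    "parallel_aligned_visible",
    "parallel_aligned_invisible",
    "orthogonal_aligned",
    "parallel_misaligned",
)

#: Conditions whose visual motion axis is orthogonal to the tactile axis.
#: Button presses on these trials are recorded as UP/DOWN and remapped to
#: LEFT/RIGHT during preprocessing.
VERTICAL_AXIS_CONDITIONS = frozenset({"orthogonal_aligned"})

DEFAULT_EFFECT_CONDITIONS = frozenset(
    {"parallel_aligned_visible", "parallel_aligned_invisible"}
)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic rivalry-with-touch generator.

    Dominance durations follow a gamma distribution (the standard empirical
    model for rivalry phase durations) whose mean depends on the
    participant's switcher profile: fast switchers alternate roughly every
    2.2 s and receive 2-sweep tactile stimuli, slow switchers every 3.5 s
    and receive 3-sweep stimuli.  While a tactile stimulus is on and the
    condition is in ``effect_conditions``, the instantaneous switch hazard
    of the current percept is multiplied by ``hazard_mult_congruent`` when
    the percept matches the tactile direction (<1 stabilises) and by
    ``hazard_mult_incongruent`` otherwise (>1 curtails suppression).
    """

    n_participants: int = 14
    n_fast: int = 5  # remaining participants are slow switchers
    gamma_shape: float = 3.5
    mean_dominance_fast_s: float = 2.2
    mean_dominance_slow_s: float = 3.5
    p_mixed: float = 0.3
    mixed_duration_mean_s: float = 0.4
    mixed_duration_sigma: float = 0.5  # log-scale sd of the lognormal gap law
    trial_length_s: float = 48.0
    n_tactile_per_trial: int = 4
    first_onset_s: float = 8.0
    inter_onset_mean_s: float = 10.0
    onset_jitter_s: float = 1.0
    sweep_duration_s: float = 1.0
    inter_sweep_pause_s: float = 0.1
    hazard_mult_congruent: float = 1.0
    hazard_mult_incongruent: float = 1.0
    effect_conditions: frozenset[str] = DEFAULT_EFFECT_CONDITIONS
    conditions: tuple[str, ...] = CONDITIONS
    n_trials_per_condition: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        durations = (
            self.mean_dominance_fast_s,
            self.mean_dominance_slow_s,
            self.trial_length_s,
            self.first_onset_s,
            self.inter_onset_mean_s,
            self.sweep_duration_s,
            self.inter_sweep_pause_s,
            self.mixed_duration_mean_s,
        )
        if any(d <= 0 for d in durations):
            raise ValueError("all durations must be positive")
        if not 0.0 <= self.p_mixed <= 1.0:
            raise ValueError("p_mixed must be a probability")
        if self.hazard_mult_congruent <= 0 or self.hazard_mult_incongruent <= 0:
            raise ValueError("hazard multipliers must be positive")
        if self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive")
        if not 0 <= self.n_fast <= self.n_participants:
            raise ValueError("n_fast must lie in [0, n_participants]")
        if self.onset_jitter_s < 0 or self.onset_jitter_s > self.inter_onset_mean_s:
            raise ValueError("onset jitter must lie in [0, inter_onset_mean_s]")
        # worst case: latest possible last onset + longest stimulus
        last_onset = self.first_onset_s + (self.n_tactile_per_trial - 1) * (
            self.inter_onset_mean_s + self.onset_jitter_s
        )
        if last_onset + self.stimulus_duration_s(3) > self.trial_length_s:
            raise ValueError(
                "tactile schedule can exceed trial length; shorten the schedule "
                "or lengthen the trial"
            )
        unknown = set(self.effect_conditions) - set(self.conditions)
        if unknown:
            raise ValueError(f"effect_conditions not in conditions: {unknown}")

    def stimulus_duration_s(self, n_sweeps: int) -> float:
        """Duration of one tactile stimulus of ``n_sweeps`` sweeps."""
        return (
            n_sweeps * self.sweep_duration_s
            + (n_sweeps - 1) * self.inter_sweep_pause_s
        )

    def switcher_profile(self) -> dict[str, str]:
        """Participant id -> 'fast' | 'slow' (fast participants come first)."""
        return {
            f"P{i + 1:02d}": ("fast" if i < self.n_fast else "slow")
            for i in range(self.n_participants)
        }

    def mean_dominance_s(self, profile: str) -> float:
        return (
            self.mean_dominance_fast_s
            if profile == "fast"
            else self.mean_dominance_slow_s
        )

    def n_sweeps(self, profile: str) -> int:
        return 2 if profile == "fast" else 3

    def to_dict(self) -> dict:
        d = asdict(self)
        d["effect_conditions"] = sorted(self.effect_conditions)
        d["conditions"] = list(self.conditions)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        if "effect_conditions" in d:
            d["effect_conditions"] = frozenset(d["effect_conditions"])
        if "conditions" in d:
            d["conditions"] = tuple(d["conditions"])
        return cls(**d)


@dataclass(frozen=True)
class TimecourseSpec:
    """Geometry of the normalized tactile-onset-locked timecourse.

    Segment lengths are chosen so that the tactile stimulus occupies the
    same fraction of the normalized segment in both switch groups:
    3.2 s / 9 s for slow switchers and 2.1 s / 5.91 s for fast switchers,
    both 0.36 to two decimals.
    """

    segment_length_slow_s: float = 9.0
    segment_length_fast_s: float = 5.91
    n_bins: int = 36
    touch_fraction: float = 0.36
    alpha_bin: float = 0.025
    chance: float = 0.5

    def segment_length_s(self, profile: str) -> float:
        return (
            self.segment_length_fast_s
            if profile == "fast"
            else self.segment_length_slow_s
        )


@dataclass(frozen=True)
class LatencySpec:
    """Geometry of the first-switch latency segments.

    Unimodal (visual-only) segments end exactly at each tactile onset and
    bimodal segments start at it; both have the same group-specific length,
    approximately half the timecourse segment length (values as used in the
    original design: 4.25 s slow, 2.95 s fast).
    """

    segment_length_slow_s: float = 4.25
    segment_length_fast_s: float = 2.95

    def segment_length_s(self, profile: str) -> float:
        return (
            self.segment_length_fast_s
            if profile == "fast"
            else self.segment_length_slow_s
        )


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration (YAML-serialisable)."""

    sim: SimConfig = field(default_factory=SimConfig)
    timecourse: TimecourseSpec = field(default_factory=TimecourseSpec)
    latency: LatencySpec = field(default_factory=LatencySpec)
    artifact_threshold_s: float = 0.18
    n_permutations: int = 1000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig.from_dict(raw.get("sim", {}))
        tc = TimecourseSpec(**raw.get("timecourse", {}))
        lat = LatencySpec(**raw.get("latency", {}))
        return cls(
            sim=sim,
            timecourse=tc,
            latency=lat,
            artifact_threshold_s=raw.get("artifact_threshold_s", 0.18),
            n_permutations=raw.get("n_permutations", 1000),
            seed=raw.get("seed", 0),
        )

    def to_yaml(self, path) -> None:
        raw = {
            "sim": self.sim.to_dict(),
            "timecourse": asdict(self.timecourse),
            "latency": asdict(self.latency),
            "artifact_threshold_s": self.artifact_threshold_s,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)
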