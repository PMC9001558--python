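"""Core data containers: perceptual state traces and tactile events.

A :class:`PerceptTrace` is a piecewise-constant path over one trial: an
ordered, contiguous, non-overlapping list of ``(start, end, state)``
intervals covering ``[0, trial_length]``.  States are button reports:
LEFT/RIGHT (or UP/DOWN on vertical-axis trials) for exclusive dominance and
NONE for mixed percepts / no press.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

LEFT = "LEFT"
RIGHT = "RIGHT"
UP = "UP"
DOWN = "DOWN"
NONE = "NONE"

DOMINANCE_STATES = (LEFT, RIGHT)
RAW_STATES = (LEFT, RIGHT, UP, DOWN, NONE)

#: Vertical responses mapped onto the horizontal congruency axis
#: (upward ~ leftward, downward ~ rightward).
VERTICAL_TO_HORIZONTAL = {UP: LEFT, DOWN: RIGHT}


@dataclass(frozen=True)
class TactileEvent:
    """One tactile motion stimulus within a trial."""

    trial_id: str
    index_in_trial: int  # 1-based
    onset_s: float
    direction: str  # LEFT or RIGHT
    n_sweeps: int
    duration_s: float

    @property
    def offset_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass
class PerceptTrace:
    """One trial's reported perceptual state path."""

    trial_id: str
    participant_id: str
    condition: str
    axis: str  # 'horizontal' or 'vertical'
    trial_length_s: float
    intervals: list[tuple[float, float, str]] = field(default_factory=list)
    #: ground-truth dominance switch times (simulation only; empty for data)
    switch_times_s: list[float] = field(default_factory=list)

    def validate(self) -> None:
        if not self.intervals:
            raise ValueError(f"trial {self.trial_id}: empty trace")
        t = 0.0
        for start, end, state in self.intervals:
            if abs(start - t) > 1e-9:
                raise ValueError(
                    f"trial {self.trial_id}: gap/overlap at t={start:.6f}"
                )
            if end <= start:
                raise ValueError(f"trial {self.trial_id}: empty interval at {start}")
            if state not in RAW_STATES:
                raise ValueError(f"trial {self.trial_id}: unknown state {state!r}")
            t = end
        if abs(t - self.trial_length_s) > 1e-9:
            raise ValueError(
                f"trial {self.trial_id}: trace ends at {t}, expected "
                f"{self.trial_length_s}"
            )

    def normalized(self) -> "PerceptTrace":
        """Merge adjacent intervals sharing a state."""
        merged: list[tuple[float, float, str]] = []
        for start, end, state in self.intervals:
            if merged and merged[-1][2] == state:
                merged[-1] = (merged[-1][0], end, state)
            else:
                merged.append((start, end, state))
        return replace(self, intervals=[tuple(iv) for iv in merged])

    def state_at(self, t: float) -> str:
        """State at time ``t`` under the half-open [start, end) convention.

        The final interval is closed at the trial end.
        """
        for start, end, state in self.intervals:
            if start <= t < end:
                return state
        last = self.intervals[-1]
        if abs(t - last[1]) <= 1e-9:
            return last[2]
        raise ValueError(
            f"trial {self.trial_id}: t={t} outside [0, {self.trial_length_s}]"
        )

    def dominance_durations(self) -> list[float]:
        return [
            end - start
            for start, end, state in self.intervals
            if state in (LEFT, RIGHT, UP, DOWN)
        ]
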