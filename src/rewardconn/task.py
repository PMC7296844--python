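"""Probabilistic reward task: configuration, trial records and schedule generation.

The task is a two-armed probabilistic reward learning game: on every trial a
cue announces whether the participant chooses freely between the two stimuli
("choice" trial) or must follow the computer's selection ("no-choice" trial).
The high-probability stimulus pays out on 80% of selections, the
low-probability stimulus on 20%, with a fixed number of points per win.
Trial phases (cue, decision, outcome) are separated by jittered gaps so that
event-related BOLD responses can be disambiguated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

CHOICE = "choice"
NO_CHOICE = "no_choice"
HIGH = "high"
LOW = "low"


class ScheduleError(ValueError):
    """Raised when a trial schedule cannot fit into the scanning session."""


@dataclass(frozen=True)
class TaskConfig:
    """Design parameters of the probabilistic reward task.

    Defaults reproduce the published design: 66 trials split evenly into
    choice and no-choice conditions, 80%/20% reward probabilities, 100
    points per win, and a TR of 1.56 s.
    """

    n_trials: int = 66
    n_choice_trials: int = 33
    p_reward_high: float = 0.8
    p_reward_low: float = 0.2
    win_points: int = 100
    cue_duration: float = 2.0
    decision_duration: float = 3.0
    outcome_duration: float = 1.5
    jitter_range: tuple[float, float] = (2.0, 6.0)
    tr: float = 1.56
    n_scans: int = 840

    def __post_init__(self) -> None:
        if not (0 <= self.n_choice_trials <= self.n_trials):
            raise ValueError("n_choice_trials must be between 0 and n_trials")
        for p in (self.p_reward_high, self.p_reward_low):
            if not 0.0 <= p <= 1.0:
                raise ValueError("reward probabilities must lie in [0, 1]")
        for d in (self.cue_duration, self.decision_duration, self.outcome_duration):
            if d <= 0:
                raise ValueError("durations must be positive")
        lo, hi = self.jitter_range
        if lo < 0 or hi < lo:
            raise ValueError("jitter_range must satisfy 0 <= lo <= hi")
        if self.tr <= 0 or self.n_scans <= 0:
            raise ValueError("tr and n_scans must be positive")

    @classmethod
    def compact(cls, n_scans: int = 500, **kwargs) -> "TaskConfig":
        """Tightly paced variant that fits 66 trials into a 500-scan session.

        Same phase durations, inter-phase jitter U(1, 2) s. Used for
        imaging-length sessions where the default pacing would overrun the
        scan window.
        """
        kwargs.setdefault("jitter_range", (1.0, 2.0))
        return cls(n_scans=n_scans, **kwargs)

    @property
    def session_length(self) -> float:
        """Total scan time in seconds."""
        return self.n_scans * self.tr

    def arm_probability(self, action: str) -> float:
        return self.p_reward_high if action == HIGH else self.p_reward_low


@dataclass
class TrialRecord:
    """One trial of the task: condition, event onsets, action and outcome."""

    index: int
    condition: str
    cue_onset: float
    response_onset: float
    outcome_onset: float
    action: Optional[str] = None
    forced_action: Optional[str] = None
    outcome: Optional[int] = None
    missed: bool = False

    def __post_init__(self) -> None:
        if self.condition not in (CHOICE, NO_CHOICE):
            raise ValueError(f"unknown condition {self.condition!r}")
        if not self.cue_onset < self.response_onset < self.outcome_onset:
            raise ValueError("trial phases must be strictly ordered")
        if self.missed and self.outcome is not None:
            raise ValueError("missed trials carry no outcome")
        if (
            self.condition == NO_CHOICE
            and self.action is not None
            and self.forced_action is not None
            and self.action != self.forced_action
        ):
            raise ValueError("no-choice action must equal forced_action")


@dataclass
class SubjectRecord:
    """A subject's session plus covariates and simulation ground truth."""

    subject_id: str
    trials: list[TrialRecord] = field(default_factory=list)
    qids: int = 0
    hads_a: int = 0
    age: float = 60.0
    sex: str = "F"
    site: str = "A"
    mde: str = "never"
    true_params: Optional[object] = None  # rl.RLParams during simulation
    true_dcm: Optional[np.ndarray] = None  # full DCM parameter vector

    def __post_init__(self) -> None:
        if not 0 <= self.qids <= 27:
            raise ValueError("QIDS must lie in 0..27")
        if not 0 <= self.hads_a <= 21:
            raise ValueError("HADS-A must lie in 0..21")
        if self.sex not in ("F", "M"):
            raise ValueError("sex must be F or M")
        if self.site not in ("A", "B"):
            raise ValueError("site must be A or B")
        if self.mde not in ("never", "past", "current"):
            raise ValueError("mde must be never/past/current")


def generate_schedule(
    config: TaskConfig, seed: int | np.random.Generator | None = None
) -> list[TrialRecord]:
    """Generate conditions, forced actions and jittered event onsets.

    Choice and no-choice trials are interleaved in random order. Gaps
    between the cue, decision and outcome phases (and between trials) are
    drawn uniformly from ``config.jitter_range``. Forced actions on
    no-choice trials are assigned to each arm with equal probability.

    Raises
    ------
    ScheduleError
        If the resulting session would run past ``n_scans * tr`` seconds.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    conditions = np.array(
        [CHOICE] * config.n_choice_trials
        + [NO_CHOICE] * (config.n_trials - config.n_choice_trials)
    )
    rng.shuffle(conditions)

    lo, hi = config.jitter_range
    trials: list[TrialRecord] = []
    t = float(rng.uniform(lo, hi))
    for i, cond in enumerate(conditions):
        cue_onset = t
        response_onset = cue_onset + config.cue_duration + float(rng.uniform(lo, hi))
        outcome_onset = response_onset + config.decision_duration + float(rng.uniform(lo, hi))
        forced = HIGH if rng.uniform() < 0.5 else LOW
        trials.append(
            TrialRecord(
                index=i,
                condition=str(cond),
                cue_onset=cue_onset,
                response_onset=response_onset,
                outcome_onset=outcome_onset,
                forced_action=forced if cond == NO_CHOICE else None,
            )
        )
        t = outcome_onset + config.outcome_duration + float(rng.uniform(lo, hi))

    if t > config.session_length:
        raise ScheduleError(
            f"schedule ends at {t:.1f} s but the session is only "
            f"{config.session_length:.1f} s ({config.n_scans} scans at TR {config.tr})"
        )
    return trials


def sample_outcome(
    action: str, config: TaskConfig, rng: np.random.Generator
) -> int:
    """Draw a Bernoulli win/no-win outcome for the selected stimulus."""
    return int(rng.uniform() < config.arm_probability(action))


def copy_schedule(trials: list[TrialRecord]) -> list[TrialRecord]:
    """Deep-ish copy of a schedule (fresh TrialRecord objects)."""
    return [replace(t) for t in trials]
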