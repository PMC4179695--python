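"""Passive associative reward-learning task (Potts slot-machine paradigm).

Each trial presents two visual stimuli in sequence (S1 then S2, each either a
gold bar or lemons) followed by an outcome screen.  S1 predicts S2 with 80%
validity; S2 determines the outcome with 100% reliability (gold bar at S2 is
always rewarded, lemons never).  Crossing the two stimulus identities yields
four trial classes:

* ``PR``  predicted reward      (S1 = S2 = gold)
* ``PNR`` predicted non-reward  (S1 = S2 = lemons)
* ``UR``  unpredicted reward    (S1 = lemons, S2 = gold)
* ``UNR`` unpredicted non-reward (S1 = gold, S2 = lemons)

The task requires no overt responses, so it is represented purely as
time-indexed square-wave input signals: one binary drive per stimulus identity
and one primary-reward drive active during the outcome screen of rewarded
trials.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Stimulus",
    "TrialType",
    "TimingConfig",
    "TrialSchedule",
    "StimulusTimeline",
    "DEFAULT_COUNTS",
    "build_schedule",
    "trial_timeline",
]

#: Trial counts used in the default session: 196 predicted reward, 196
#: predicted non-reward, 48 unpredicted reward, 48 unpredicted non-reward
#: (488 trials; 80/20 S1->S2 contingency for both S1 identities).
DEFAULT_COUNTS: dict[str, int] = {"PR": 196, "PNR": 196, "UR": 48, "UNR": 48}


class Stimulus(enum.Enum):
    GOLD = "gold"
    LEMON = "lemon"


class TrialType(enum.Enum):
    """The four trial classes of the task."""

    PR = "PR"
    PNR = "PNR"
    UR = "UR"
    UNR = "UNR"

    @property
    def s1_stimulus(self) -> Stimulus:
        return {
            TrialType.PR: Stimulus.GOLD,
            TrialType.PNR: Stimulus.LEMON,
            TrialType.UR: Stimulus.LEMON,
            TrialType.UNR: Stimulus.GOLD,
        }[self]

    @property
    def s2_stimulus(self) -> Stimulus:
        return {
            TrialType.PR: Stimulus.GOLD,
            TrialType.PNR: Stimulus.LEMON,
            TrialType.UR: Stimulus.GOLD,
            TrialType.UNR: Stimulus.LEMON,
        }[self]

    @property
    def rewarded(self) -> bool:
        """Reward is delivered iff the S2 stimulus is the gold bar."""
        return self.s2_stimulus is Stimulus.GOLD


@dataclass(frozen=True)
class TimingConfig:
    """Screen durations and analysis-window layout of one trial (seconds).

    The trial runs fixation -> S1 -> gap -> S2 -> gap -> outcome -> ITI.
    Analysis windows are expressed relative to an event onset: the default S2
    window is the first 300 ms after S2 onset, referenced to the 100 ms
    immediately preceding S2, in 20 ms bins.
    """

    dt: float = 0.001
    fixation: float = 0.5
    s1_duration: float = 0.5
    gap1: float = 0.5
    s2_duration: float = 0.5
    gap2: float = 0.5
    outcome: float = 1.0
    iti: float = 2.0
    bin_width: float = 0.020
    analysis_window: tuple[float, float] = (0.0, 0.300)
    baseline_window: tuple[float, float] = (-0.100, 0.0)

    def __post_init__(self) -> None:
        durations = {
            "dt": self.dt,
            "fixation": self.fixation,
            "s1_duration": self.s1_duration,
            "gap1": self.gap1,
            "s2_duration": self.s2_duration,
            "gap2": self.gap2,
            "outcome": self.outcome,
            "iti": self.iti,
            "bin_width": self.bin_width,
        }
        for name, value in durations.items():
            if not value > 0:
                raise ValueError(f"{name} must be > 0, got {value}")
        for name, (lo, hi) in (
            ("analysis_window", self.analysis_window),
            ("baseline_window", self.baseline_window),
        ):
            if not lo < hi:
                raise ValueError(f"{name} must be an increasing interval")
            for edge in (lo, hi):
                ratio = edge / self.bin_width
                if abs(ratio - round(ratio)) > 1e-9:
                    raise ValueError(
                        f"{name} edges must be multiples of bin_width"
                    )
        if self.baseline_window[0] < -(self.gap1 + self.s1_duration):
            raise ValueError("baseline window extends before the trial")
        if self.analysis_window[1] > self.s2_duration + self.gap2 + self.outcome:
            raise ValueError("analysis window extends beyond the trial")

    # -- event onsets (seconds from trial start) --------------------------
    @property
    def s1_onset(self) -> float:
        return self.fixation

    @property
    def s2_onset(self) -> float:
        return self.fixation + self.s1_duration + self.gap1

    @property
    def reward_onset(self) -> float:
        return self.s2_onset + self.s2_duration + self.gap2

    @property
    def trial_duration(self) -> float:
        return self.reward_onset + self.outcome + self.iti

    @property
    def n_steps(self) -> int:
        return int(round(self.trial_duration / self.dt))

    @property
    def n_bins(self) -> int:
        return int(math.floor(self.trial_duration / self.bin_width + 1e-9))


@dataclass(frozen=True)
class TrialSchedule:
    """A seeded, shuffled ordering of the trial-type multiset."""

    trials: tuple[TrialType, ...]
    counts: dict[str, int]
    rng_seed: int

    def __len__(self) -> int:
        return len(self.trials)

    def contingency(self, s1: Stimulus) -> float:
        """P(S2 identity == S1 identity | S1 identity) under these counts."""
        same = sum(
            self.counts[t.value]
            for t in TrialType
            if t.s1_stimulus is s1 and t.s2_stimulus is s1
        )
        total = sum(self.counts[t.value] for t in TrialType if t.s1_stimulus is s1)
        if total == 0:
            raise ValueError(f"no trials with S1 = {s1.value}")
        return same / total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial_index": np.arange(len(self.trials)),
                "trial_type": [t.value for t in self.trials],
            }
        )


def build_schedule(
    counts: dict[str, int] | None = None,
    seed: int = 0,
    shuffle: bool = True,
) -> TrialSchedule:
    """Build a trial schedule as a seeded uniform shuffle of the multiset.

    Parameters
    ----------
    counts
        Number of trials per trial-type label; defaults to the standard
        196/196/48/48 session.
    seed
        Shuffle seed; the same seed always yields the same order.
    shuffle
        If False, return the trials in blocked label order instead.
    """
    counts = dict(DEFAULT_COUNTS if counts is None else counts)
    for label in counts:
        if label not in TrialType.__members__:
            raise ValueError(f"unknown trial type {label!r}")
        if not isinstance(counts[label], (int, np.integer)) or counts[label] < 0:
            raise ValueError(f"count for {label} must be a non-negative integer")
    for t in TrialType:  # missing labels mean zero trials of that type
        counts.setdefault(t.value, 0)
    trials = [t for t in TrialType for _ in range(counts[t.value])]
    if shuffle:
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(trials))
        trials = [trials[i] for i in order]
    return TrialSchedule(trials=tuple(trials), counts=counts, rng_seed=seed)


@dataclass(frozen=True)
class StimulusTimeline:
    """Square-wave input signals for one trial, sampled every ``dt``.

    ``i_gold`` and ``i_lemon`` are 1 exactly while the physical stimulus is on
    screen; ``reward`` is ``r_amp`` during the outcome screen of rewarded
    trials and 0 otherwise.
    """

    trial_type: TrialType
    dt: float
    i_gold: np.ndarray
    i_lemon: np.ndarray
    reward: np.ndarray
    events: dict[str, float] = field(default_factory=dict)

    @property
    def n_steps(self) -> int:
        return self.i_gold.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_steps) * self.dt

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.times,
                "I_gold": self.i_gold,
                "I_lemon": self.i_lemon,
                "R": self.reward,
                "trial_type": self.trial_type.value,
            }
        )


def trial_timeline(
    trial: TrialType,
    timing: TimingConfig,
    r_amp: float = 1.0,
) -> StimulusTimeline:
    """Render one trial as square-wave stimulus and reward drives."""
    n = timing.n_steps
    t = np.arange(n) * timing.dt
    signals = {Stimulus.GOLD: np.zeros(n), Stimulus.LEMON: np.zeros(n)}

    def _on(signal: np.ndarray, start: float, duration: float) -> None:
        signal[(t >= start - 1e-12) & (t < start + duration - 1e-12)] = 1.0

    _on(signals[trial.s1_stimulus], timing.s1_onset, timing.s1_duration)
    _on(signals[trial.s2_stimulus], timing.s2_onset, timing.s2_duration)
    reward = np.zeros(n)
    if trial.rewarded:
        _on(reward, timing.reward_onset, timing.outcome)
        reward *= r_amp
    return StimulusTimeline(
        trial_type=trial,
        dt=timing.dt,
        i_gold=signals[Stimulus.GOLD],
        i_lemon=signals[Stimulus.LEMON],
        reward=reward,
        events={
            "S1": timing.s1_onset,
            "S2": timing.s2_onset,
            "REW": timing.reward_onset,
        },
    )


def mini_timing(dt: float = 0.001) -> TimingConfig:
    """A shortened trial layout for quick tests (same structure, ~60% length)."""
    return TimingConfig(
        dt=dt,
        fixation=0.3,
        s1_duration=0.3,
        gap1=0.3,
        s2_duration=0.3,
        gap2=0.3,
        outcome=0.6,
        iti=2.0,
    )
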