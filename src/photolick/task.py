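"""Task configuration for the four reward-contingency paradigms.

All four tasks share the same skeleton: trials are separated by an
inter-trial interval (ITI) followed by a "No lick" period during which any
lick aborts the attempt; a completed attempt opens a 1 s reporting window
(optionally delayed by 1 s) in which the first lick may trigger the reward
valve.

=====================  =========  =========  ======  ==================
task                   ITI (s)    No-lick(s) delay   reward rule
=====================  =========  =========  ======  ==================
free_licking           0.5-0.6    3.5-4.5    0       lick rewarded p=0.5
whisker_detection      8-13       4.5-5.5    0       lick after stimulus
delayed_reward         8-13       4.5-5.5    1.0     lick in delayed window
reward_omission        8-13       4.5-5.5    1.0     50 warm-up trials all
                                                     rewarded, then p=0.5
=====================  =========  =========  ======  ==================

Stimulus/no-stimulus trials are drawn randomly with at most three
consecutive trials of the same type.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["TaskConfig", "TASK_KINDS"]

TASK_KINDS = ("free_licking", "whisker_detection", "delayed_reward", "reward_omission")


@dataclass
class TaskConfig:
    """Parameters of one behavioral task.

    Use :meth:`for_task` for the standard configuration of each paradigm.

    Attributes
    ----------
    task_kind : str
        One of :data:`TASK_KINDS`.
    iti_range : (float, float)
        Uniform range of the inter-trial interval, seconds.
    nolick_range : (float, float)
        Uniform range of the pre-trial No-lick period, seconds.  A lick in
        this period aborts the attempt.
    report_window : float
        Length of the reporting window, seconds.
    delay : float
        Delay between trial onset (stimulus time) and the reporting window,
        seconds.  Non-zero only for delayed_reward and reward_omission.
    reward_prob_on_lick : float
        Free licking only: probability that a reporting-window lick is
        rewarded.
    omission_prob : float
        Reward omission only: probability that a post-warm-up Hit goes
        unrewarded.
    n_warmup_trials : int
        Reward omission only: number of initial trials (stimulus and
        no-stimulus together) during which every Hit is rewarded.
    stim_trial_fraction : float
        Fraction of trials carrying a whisker stimulus.
    max_consecutive_same_type : int
        Cap on runs of identical stimulus/no-stimulus labels.
    reward_volume_ul : float
        Nominal drop size in microliters; metadata only.
    """

    task_kind: str
    iti_range: tuple[float, float] = (8.0, 13.0)
    nolick_range: tuple[float, float] = (4.5, 5.5)
    report_window: float = 1.0
    delay: float = 0.0
    reward_prob_on_lick: float = 0.5
    omission_prob: float = 0.5
    n_warmup_trials: int = 50
    stim_trial_fraction: float = 0.5
    max_consecutive_same_type: int = 3
    reward_volume_ul: float = 5.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.task_kind not in TASK_KINDS:
            raise ValueError(f"unknown task_kind {self.task_kind!r}")
        for name in ("iti_range", "nolick_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must satisfy 0 < lo <= hi, got {(lo, hi)}")
        if self.report_window <= 0:
            raise ValueError("report_window must be positive")
        for name in ("reward_prob_on_lick", "omission_prob", "stim_trial_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.delay < 0:
            raise ValueError("delay must be non-negative")
        if self.delay > 0 and self.task_kind in ("free_licking", "whisker_detection"):
            raise ValueError(f"{self.task_kind} does not use a reward delay")
        if self.max_consecutive_same_type < 1:
            raise ValueError("max_consecutive_same_type must be >= 1")
        if self.n_warmup_trials < 0:
            raise ValueError("n_warmup_trials must be non-negative")

    @classmethod
    def for_task(cls, task_kind: str, **overrides) -> "TaskConfig":
        """Standard configuration for one of the four paradigms."""
        base: dict
        if task_kind == "free_licking":
            base = dict(
                iti_range=(0.5, 0.6),
                nolick_range=(3.5, 4.5),
                delay=0.0,
                stim_trial_fraction=0.0,
            )
        elif task_kind == "whisker_detection":
            base = dict(delay=0.0)
        elif task_kind == "delayed_reward":
            base = dict(delay=1.0)
        elif task_kind == "reward_omission":
            base = dict(delay=1.0, omission_prob=0.5, n_warmup_trials=50)
        else:
            raise ValueError(f"unknown task_kind {task_kind!r}")
        base.update(overrides)
        return cls(task_kind=task_kind, **base)

    def to_dict(self) -> dict:
        return {
            "task_kind": self.task_kind,
            "iti_range": list(self.iti_range),
            "nolick_range": list(self.nolick_range),
            "report_window": self.report_window,
            "delay": self.delay,
            "reward_prob_on_lick": self.reward_prob_on_lick,
            "omission_prob": self.omission_prob,
            "n_warmup_trials": self.n_warmup_trials,
            "stim_trial_fraction": self.stim_trial_fraction,
            "max_consecutive_same_type": self.max_consecutive_same_type,
            "reward_volume_ul": self.reward_volume_ul,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TaskConfig":
        d = dict(d)
        for key in ("iti_range", "nolick_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)
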