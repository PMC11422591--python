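"""Lick detection, trial parsing and signal-detection performance.

The behavioral record of a session consists of the piezo film voltage (the
spout-mounted lick sensor, sampled on the 1 kHz analysis clock), lick contact
times, whisker stimulus times, reward valve openings, and the logged trial
onsets and aborted attempts.  :func:`parse_trials` reconstructs the per-trial
outcome labels from those event streams for any of the four tasks, and
:func:`performance_metrics` summarises detection performance with the
loglinear-corrected d'.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .task import TaskConfig

__all__ = [
    "SessionEvents",
    "TrialTable",
    "Performance",
    "ConsistencyError",
    "licking_power",
    "detect_lick_onsets",
    "parse_trials",
    "performance_metrics",
]

logger = logging.getLogger(__name__)

#: all recognised trial outcome labels
TRIAL_TYPES = (
    "Hit",
    "Miss",
    "FA",
    "CR",
    "RewardedLick",
    "UnrewardedLick",
    "NoLick",
    "HitPlus",
    "HitMinus",
)

#: labels that count as a hit (stimulus trial with a reporting-window lick)
HIT_TYPES = ("Hit", "HitPlus", "HitMinus")

#: labels of trials in which the reporting-window lick went unrewarded
UNREWARDED_LICK_TYPES = ("FA", "UnrewardedLick", "HitMinus")

#: labels of trials in which a reward was delivered
REWARDED_TYPES = ("Hit", "HitPlus", "RewardedLick")

TRIAL_COLUMNS = [
    "trial",
    "onset_time",
    "stim",
    "type",
    "first_report_lick_time",
    "reward_time",
    "aborted_attempt_count",
]


class ConsistencyError(ValueError):
    """Raised when the event streams contradict the task rules."""


@dataclass
class SessionEvents:
    """Behavioral event streams of one session.

    ``lick_times`` are tongue-spout contact onsets (strictly increasing);
    ``trial_start_times`` mark the onset of every *completed* trial
    (stimulus time, or the virtual onset of a no-stimulus trial);
    ``abort_times`` mark licks that aborted a trial attempt during the
    No-lick period.
    """

    piezo: np.ndarray
    lick_times: np.ndarray
    stim_times: np.ndarray
    valve_times: np.ndarray
    trial_start_times: np.ndarray
    abort_times: np.ndarray
    session_t_end: float
    fs: float = 1000.0

    def __post_init__(self) -> None:
        self.piezo = np.asarray(self.piezo, dtype=float)
        for name in (
            "lick_times",
            "stim_times",
            "valve_times",
            "trial_start_times",
            "abort_times",
        ):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.size and (arr.min() < 0 or arr.max() > self.session_t_end):
                raise ValueError(f"{name} outside [0, session_t_end]")
        if self.lick_times.size > 1 and np.any(np.diff(self.lick_times) <= 0):
            raise ValueError("lick_times must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        """Long-format events table (time_s, event_type, value)."""
        parts = []
        for name, kind in [
            ("lick_times", "lick"),
            ("stim_times", "stim"),
            ("valve_times", "valve"),
            ("trial_start_times", "trial_start"),
            ("abort_times", "abort"),
        ]:
            t = getattr(self, name)
            parts.append(
                pd.DataFrame({"time_s": t, "event_type": kind, "value": np.ones(t.size)})
            )
        df = pd.concat(parts, ignore_index=True)
        return df.sort_values(["time_s", "event_type"], kind="mergesort").reset_index(
            drop=True
        )

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, piezo: np.ndarray, session_t_end: float, fs: float = 1000.0
    ) -> "SessionEvents":
        def times(kind: str) -> np.ndarray:
            return df.loc[df["event_type"] == kind, "time_s"].to_numpy(dtype=float)

        return cls(
            piezo=piezo,
            lick_times=times("lick"),
            stim_times=times("stim"),
            valve_times=times("valve"),
            trial_start_times=times("trial_start"),
            abort_times=times("abort"),
            session_t_end=session_t_end,
            fs=fs,
        )


@dataclass
class TrialTable:
    """Per-trial outcome records.

    Wraps a DataFrame with columns ``trial, onset_time, stim, type,
    first_report_lick_time, reward_time, aborted_attempt_count`` (times in
    seconds; NaN where no lick/reward occurred).  The simulator attaches
    extra latent columns (hit probability, satiety level, ...) which
    round-trip untouched.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in TRIAL_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"TrialTable missing columns {missing}")
        bad = set(self.df["type"]) - set(TRIAL_TYPES)
        if bad:
            raise ValueError(f"unknown trial types {sorted(bad)}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def of_type(self, *types: str) -> pd.DataFrame:
        return self.df[self.df["type"].isin(types)]

    @property
    def n_stim(self) -> int:
        return int(self.df["stim"].sum())

    @property
    def n_nostim(self) -> int:
        return int((~self.df["stim"]).sum())

    def count(self, *types: str) -> int:
        return int(self.df["type"].isin(types).sum())


@dataclass
class Performance:
    """Signal-detection summary of a go/no-go session."""

    hit_rate: float
    fa_rate: float
    dprime: float
    n_stim: int
    n_nostim: int


def licking_power(piezo: np.ndarray) -> np.ndarray:
    """Instantaneous licking power: the pointwise square of the piezo voltage."""
    piezo = np.asarray(piezo, dtype=float)
    return piezo * piezo


def detect_lick_onsets(
    piezo: np.ndarray,
    fs: float = 1000.0,
    threshold_k: float = 4.0,
    refractory: float = 0.05,
    min_duration: float = 0.003,
) -> np.ndarray:
    """Detect tongue-spout contact onsets from the piezo voltage.

    A contact is an upward crossing of ``|piezo|`` above ``threshold_k``
    robust noise standard deviations (1.4826 * median absolute deviation)
    that stays above threshold for at least ``min_duration`` seconds --
    tongue contacts load the film for tens of milliseconds, whereas
    single-sample noise excursions do not.  Successive onsets must be
    separated by at least ``refractory`` seconds (inter-lick intervals run
    ~100 ms at the ~10 Hz lick rhythm).
    """
    if threshold_k <= 0:
        raise ValueError("threshold_k must be positive")
    if refractory < 0 or min_duration < 0:
        raise ValueError("refractory and min_duration must be non-negative")
    piezo = np.asarray(piezo, dtype=float)
    mag = np.abs(piezo - np.median(piezo))
    sigma = 1.4826 * np.median(mag)
    thresh = threshold_k * sigma
    above = mag > thresh
    rising = np.flatnonzero(above & ~np.r_[False, above[:-1]])
    n_sustain = max(1, int(round(min_duration * fs)))
    if n_sustain > 1 and rising.size:
        ok = [
            idx + n_sustain <= above.size and bool(above[idx : idx + n_sustain].all())
            for idx in rising
        ]
        rising = rising[np.asarray(ok, dtype=bool)]
    if rising.size == 0:
        return np.empty(0)
    keep = [rising[0]]
    min_gap = refractory * fs
    for idx in rising[1:]:
        if idx - keep[-1] >= min_gap:
            keep.append(idx)
    return np.asarray(keep, dtype=float) / fs


def _report_licks(lick_times: np.ndarray, start: float, end: float) -> np.ndarray:
    """Licks inside the half-open reporting window [start, end)."""
    return lick_times[(lick_times >= start) & (lick_times < end)]


def parse_trials(events: SessionEvents, config: TaskConfig) -> TrialTable:
    """Reconstruct per-trial outcome labels from the event streams.

    Every logged trial onset opens a half-open reporting window
    ``[onset + delay, onset + delay + report_window)``.  The first lick in
    that window is the report lick; a valve opening inside the window marks
    the trial rewarded.  Labels follow the task:

    * free_licking: RewardedLick / UnrewardedLick / NoLick,
    * whisker_detection and delayed_reward: Hit / Miss / FA / CR
      (delay-period licks are neither rewarded nor counted as reports),
    * reward_omission: HitPlus (rewarded Hit) / HitMinus (omitted reward) /
      Miss / FA / CR.

    Aborted attempts are attributed to the completed trial that follows
    them.  A valve opening that falls in no reporting window, or in a window
    with no preceding report lick, raises :class:`ConsistencyError`.
    """
    onsets = np.sort(events.trial_start_times)
    rows = []
    valve_used = np.zeros(events.valve_times.size, dtype=bool)
    prev_boundary = -np.inf
    for i, onset in enumerate(onsets):
        win_start = onset + config.delay
        win_end = win_start + config.report_window
        rep_licks = _report_licks(events.lick_times, win_start, win_end)
        first_lick = rep_licks[0] if rep_licks.size else np.nan
        in_win = (events.valve_times >= win_start) & (events.valve_times < win_end)
        valve_idx = np.flatnonzero(in_win)
        reward_time = np.nan
        if valve_idx.size:
            if not rep_licks.size or events.valve_times[valve_idx[0]] < first_lick:
                raise ConsistencyError(
                    "valve opening at "
                    f"t={events.valve_times[valve_idx[0]]:.3f} s has no preceding "
                    "reporting-window lick"
                )
            reward_time = events.valve_times[valve_idx[0]]
            valve_used[valve_idx] = True
        has_stim = bool(
            np.any(np.abs(events.stim_times - onset) < 0.5 / events.fs)
        )
        licked = rep_licks.size > 0
        rewarded = np.isfinite(reward_time)

        if config.task_kind == "free_licking":
            ttype = ("RewardedLick" if rewarded else "UnrewardedLick") if licked else "NoLick"
        elif config.task_kind == "reward_omission":
            if has_stim:
                ttype = ("HitPlus" if rewarded else "HitMinus") if licked else "Miss"
            else:
                ttype = "FA" if licked else "CR"
        else:
            if has_stim:
                ttype = "Hit" if licked else "Miss"
            else:
                ttype = "FA" if licked else "CR"

        n_aborts = int(
            np.sum((events.abort_times > prev_boundary) & (events.abort_times <= onset))
        )
        prev_boundary = win_end
        rows.append(
            {
                "trial": i,
                "onset_time": onset,
                "stim": has_stim,
                "type": ttype,
                "first_report_lick_time": first_lick,
                "reward_time": reward_time,
                "aborted_attempt_count": n_aborts,
            }
        )
    if not np.all(valve_used):
        orphan = events.valve_times[~valve_used]
        raise ConsistencyError(
            f"valve openings outside any reporting window at t={orphan.tolist()}"
        )
    df = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    return TrialTable(df)


def loglinear_rates(n_hit: int, n_stim: int, n_fa: int, n_nostim: int) -> tuple[float, float]:
    """Hit and false-alarm rates with the loglinear correction.

    Half a success and a full trial are added to each rate, keeping the
    inverse-normal transform finite at 0% and 100% performance.
    """
    return (n_hit + 0.5) / (n_stim + 1.0), (n_fa + 0.5) / (n_nostim + 1.0)


def performance_metrics(trials: TrialTable) -> Performance:
    """Detection performance: raw rates plus loglinear-corrected d'.

    ``d' = Z(hit rate) - Z(false alarm rate)`` with Z the inverse normal
    CDF; the rates entering d' carry the loglinear correction so extreme
    sessions stay finite.
    """
    n_stim = trials.n_stim
    n_nostim = trials.n_nostim
    if n_stim == 0 or n_nostim == 0:
        raise ValueError("need at least one stimulus and one no-stimulus trial")
    n_hit = trials.count(*HIT_TYPES)
    n_fa = trials.count("FA")
    h_corr, f_corr = loglinear_rates(n_hit, n_stim, n_fa, n_nostim)
    dprime = float(norm.ppf(h_corr) - norm.ppf(f_corr))
    return Performance(
        hit_rate=n_hit / n_stim,
        fa_rate=n_fa / n_nostim,
        dprime=dprime,
        n_stim=n_stim,
        n_nostim=n_nostim,
    )
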