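"""Across-day and within-session learning dynamics.

Within a session, the first 51 whisker-stimulus trials are averaged in 17
non-overlapping blocks of 3; the block series of the early sensory dLight
response and of the Hit indicator are correlated with trial number
(Pearson), summarised by ordinary least-squares slopes, and mice with a
significant positive Hit-rate correlation are flagged as within-session
learners.  Across days, paired per-mouse values are compared with Wilcoxon
signed-rank tests at the Bonferroni-corrected level alpha = 0.05 / 3 ~
0.017 for the three day pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .align import paired_signed_rank

__all__ = [
    "BlockSeries",
    "LearnerFlag",
    "block_series",
    "pearson_with_p",
    "learning_slope",
    "select_learners",
    "day_comparisons",
]

#: default within-session analysis extent: first 51 whisker trials in
#: blocks of 3 -> 17 blocks
N_TRIALS_DEFAULT = 51
BLOCK_DEFAULT = 3


@dataclass
class BlockSeries:
    """Block-averaged within-session series.

    ``trial_center`` holds the 1-based center trial number of each block
    (2, 5, ..., 50 for 51 trials in blocks of 3) and is the x-coordinate
    for slopes and correlations.
    """

    block_index: np.ndarray
    trial_center: np.ndarray
    dlight: np.ndarray
    hit_rate: np.ndarray
    block_size: int
    n_trials_used: int
    flagged_short: bool = False

    def __post_init__(self) -> None:
        for name in ("block_index", "trial_center", "dlight", "hit_rate"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.block_index.size
        if not all(
            getattr(self, name).size == n for name in ("trial_center", "dlight", "hit_rate")
        ):
            raise ValueError("block arrays must have equal lengths")
        if np.any((self.hit_rate < 0) | (self.hit_rate > 1)):
            raise ValueError("hit_rate outside [0, 1]")

    @property
    def n_blocks(self) -> int:
        return self.block_index.size


def block_series(
    per_trial_values: np.ndarray,
    hit_indicator: np.ndarray,
    block: int = BLOCK_DEFAULT,
    n_trials: int = N_TRIALS_DEFAULT,
) -> BlockSeries:
    """Average a per-whisker-trial series in consecutive blocks.

    ``per_trial_values`` is the early sensory response of each whisker
    trial in session order and ``hit_indicator`` the binary Hit outcome.
    Sessions with fewer than ``n_trials`` whisker trials are truncated to
    the largest whole number of blocks and flagged.
    """
    values = np.asarray(per_trial_values, dtype=float)
    hits = np.asarray(hit_indicator, dtype=float)
    if values.shape != hits.shape or values.ndim != 1:
        raise ValueError("per-trial values and hit indicator must match in length")
    if n_trials % block != 0:
        raise ValueError(f"n_trials={n_trials} is not a multiple of block={block}")
    flagged = values.size < n_trials
    n_used = min(values.size, n_trials) // block * block
    if n_used < block:
        raise ValueError("fewer trials than one block")
    n_blocks = n_used // block
    shape = (n_blocks, block)
    dlight = values[:n_used].reshape(shape).mean(axis=1)
    hit_rate = hits[:n_used].reshape(shape).mean(axis=1)
    centers = np.arange(n_blocks) * block + (block + 1) / 2.0  # 1-based trial numbers
    return BlockSeries(
        block_index=np.arange(n_blocks),
        trial_center=centers,
        dlight=dlight,
        hit_rate=hit_rate,
        block_size=block,
        n_trials_used=n_used,
        flagged_short=flagged,
    )


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson product-moment correlation with a two-sided p-value.

    p comes from the t transform ``t = r sqrt((n-2)/(1-r^2))`` with
    ``n - 2`` degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def learning_slope(series: BlockSeries, field: str = "dlight") -> float:
    """OLS slope of a block series against block-center trial number.

    Units: signal change per trial-index unit.
    """
    y = getattr(series, field)
    if series.n_blocks < 2:
        raise ValueError("need at least 2 blocks for a slope")
    slope, _ = np.polyfit(series.trial_center, y, 1)
    return float(slope)


@dataclass
class LearnerFlag:
    """Within-session learner selection outcome for one session."""

    evaluable: bool
    is_learner: bool
    r: float
    p: float
    reason: str = ""


def select_learners(
    hit_indicator: np.ndarray, n_trials: int = N_TRIALS_DEFAULT
) -> LearnerFlag:
    """Flag a session as showing within-session learning.

    A session is a learner if the Pearson correlation of the per-trial Hit
    indicator with trial number over the first ``n_trials`` whisker trials
    has p < 0.05 *and* positive r.  Sessions with too few whisker trials
    or a constant hit pattern are not evaluable.
    """
    hits = np.asarray(hit_indicator, dtype=float)
    if hits.size < n_trials:
        return LearnerFlag(
            evaluable=False, is_learner=False, r=np.nan, p=np.nan,
            reason=f"only {hits.size} whisker trials (< {n_trials})",
        )
    hits = hits[:n_trials]
    trial_number = np.arange(1, n_trials + 1, dtype=float)
    try:
        r, p = pearson_with_p(trial_number, hits)
    except ValueError as exc:
        return LearnerFlag(
            evaluable=False, is_learner=False, r=np.nan, p=np.nan, reason=str(exc)
        )
    return LearnerFlag(evaluable=True, is_learner=bool(p < 0.05 and r > 0), r=r, p=p)


def day_comparisons(
    day_values: pd.DataFrame, alpha_family: float = 0.05
) -> pd.DataFrame:
    """Pairwise signed-rank comparisons of per-mouse values across days.

    ``day_values`` has one row per mouse and one column per day.  Each day
    pair is tested with the two-sided Wilcoxon signed-rank test on the
    mice that have both days (others are dropped pairwise and counted);
    significance uses the Bonferroni-corrected level
    ``alpha_family / n_pairs`` (0.05 / 3 ~ 0.017 for three days).
    """
    days = list(day_values.columns)
    pairs = list(combinations(days, 2))
    if not pairs:
        raise ValueError("need at least two days")
    alpha = alpha_family / len(pairs)
    rows = []
    for d1, d2 in pairs:
        sub = day_values[[d1, d2]].dropna()
        n_dropped = len(day_values) - len(sub)
        try:
            p = paired_signed_rank(sub[d1].to_numpy(), sub[d2].to_numpy())
        except ValueError:
            # degenerate pair (e.g. identical values): undefined test, not
            # a significant difference
            p = float("nan")
        rows.append(
            {
                "day_a": d1,
                "day_b": d2,
                "n": len(sub),
                "n_dropped": n_dropped,
                "p": p,
                "alpha": alpha,
                "significant": bool(p < alpha),
            }
        )
    return pd.DataFrame(rows)
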