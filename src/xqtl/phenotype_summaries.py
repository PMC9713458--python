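"""Small phenotype computations: pool survival, death-time imputation, Welch t."""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
import scipy.stats


@dataclass(frozen=True)
class SurvivalCount:
    group: str
    survivors: int
    total: int

    def __post_init__(self):
        if self.total <= 0:
            raise ValueError("total must be > 0")
        if not 0 <= self.survivors <= self.total:
            raise ValueError("survivors must be in [0, total]")


@dataclass
class DeathTimeSeries:
    """Periodic cumulative death counts plus a final censored-alive count."""

    times: list[float]  # observation times, minutes, strictly increasing
    cumulative_dead: list[int]
    final_alive: int = 0

    def __post_init__(self):
        if len(self.times) != len(self.cumulative_dead) or not self.times:
            raise ValueError("times and cumulative_dead must be equal-length, non-empty")
        if any(t2 <= t1 for t1, t2 in zip(self.times, self.times[1:])):
            raise ValueError("observation times must be strictly increasing")
        if any(c2 < c1 for c1, c2 in zip(self.cumulative_dead, self.cumulative_dead[1:])):
            raise ValueError("cumulative death counts must be non-decreasing")
        if self.cumulative_dead[0] < 0 or self.final_alive < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.cumulative_dead[-1] + self.final_alive


def survival_percent(survivors: int, total: int) -> float:
    """100 * survivors / total, half-up rounded to one decimal."""
    if total <= 0:
        raise ValueError("total must be > 0")
    if not 0 <= survivors <= total:
        raise ValueError("survivors must be in [0, total]")
    pct = Decimal(100 * survivors) / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def impute_death_times(series: DeathTimeSeries) -> pd.DataFrame:
    """Per-individual death times under the midpoint rule.

    Deaths recorded between consecutive counts at t_k and t_{k+1} are placed
    at their midpoint; deaths at the first count at midpoint of (0, t_1).
    Individuals alive at the final count are censored at that time. Returns a
    DataFrame with columns time, censored.
    """
    times: list[float] = []
    censored: list[bool] = []
    prev_t, prev_c = 0.0, 0
    for t, c in zip(series.times, series.cumulative_dead):
        new_deaths = c - prev_c
        times.extend([(prev_t + t) / 2] * new_deaths)
        censored.extend([False] * new_deaths)
        prev_t, prev_c = t, c
    times.extend([series.times[-1]] * series.final_alive)
    censored.extend([True] * series.final_alive)
    return pd.DataFrame({"time": times, "censored": censored})


def welch_t(x, y) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test; returns (t, df, two-sided p).

    Both samples with zero variance and equal means return (0, df, 1); zero
    variance in both with different means is an error (the statistic is
    undefined).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs >= 2 observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return 0.0, float(len(x) + len(y) - 2), 1.0
        raise ValueError("zero variance in both samples with unequal means")
    res = scipy.stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def summarize_survival(counts: pd.DataFrame) -> pd.DataFrame:
    """Survival percentages for a table with columns group, survivors, total."""
    rows = []
    for row in counts.itertuples(index=False):
        sc = SurvivalCount(str(row.group), int(row.survivors), int(row.total))
        rows.append((sc.group, sc.survivors, sc.total, survival_percent(sc.survivors, sc.total)))
    return pd.DataFrame(rows, columns=["group", "survivors", "total", "percent"])
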