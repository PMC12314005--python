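"""Day-ranked climate-exposure strata.

Correlations between weather and behavior are diluted by nonlinearity and by
cumulative stress: one hot day moves behavior less than a run of hot days.
The ranking scheme works around this by (1) ranking every trial day — both
trials merged — by its daily maximum CCI, rank 1 being the coldest day;
(2) averaging day ranks within each trial week; (3) ranking the eight weeks
by that average; and (4) pairing adjacent weeks of the week ranking into
four groups, group 1 the coolest pair, group 4 the warmest.  Groups 1 and 4
are the "low CCI" and "high CCI" strata for the correlation analysis.

Ties receive average ranks, which makes every step invariant to permutation
of the input and to any strictly monotone transform of the CCI.
"""

from __future__ import annotations

import pandas as pd
from scipy.stats import rankdata

from .config import DEFAULT_CONFIG, PipelineConfig

__all__ = ["rank_days", "weekly_average_rank", "pair_weeks",
           "make_groups", "group_weather_summary"]


def rank_days(daily_cci: pd.DataFrame,
              config: PipelineConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """Rank merged-trial days by daily maximum CCI (1 = coldest).

    ``daily_cci`` needs ``date`` and ``max_cci`` covering both trials.
    Ties get the average of their rank positions.  Adds ``trial_id``,
    ``week_in_trial`` and global ``week`` from the trial calendar.
    """
    if len(daily_cci) == 0:
        raise ValueError("cannot rank an empty day set")
    out = daily_cci.copy()
    out["rank"] = rankdata(out["max_cci"].to_numpy(), method="average")
    trials = [config.trial_of(d) for d in out["date"]]
    if any(t is None for t in trials):
        missing = [d for d, t in zip(out["date"], trials) if t is None]
        raise ValueError(f"date(s) outside every trial window: {missing[:3]}")
    out["trial_id"] = [t.trial_id for t in trials]
    out["week_in_trial"] = [t.week_of(d) for t, d in zip(trials, out["date"])]
    out["week"] = [config.global_week(t.trial_id, w)
                   for t, w in zip(trials, out["week_in_trial"])]
    return out


def weekly_average_rank(day_ranks: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean of member-day ranks per global week.

    Every calendar day of the week participates — the Monday exclusion is a
    behavioral rule, not a ranking rule.
    """
    if len(day_ranks) == 0:
        raise ValueError("a week has no days")
    out = (day_ranks.groupby(["week", "trial_id"], observed=True)["rank"]
           .mean().reset_index(name="avg_rank"))
    return out.sort_values("week").reset_index(drop=True)


def pair_weeks(weekly: pd.DataFrame) -> pd.DataFrame:
    """Pair weeks into exposure groups by ascending average rank.

    With 2k weeks sorted by ``avg_rank``, group g (1-based) contains the
    (2g-1)-th and 2g-th weeks of that order: group 1 is the coolest pair,
    the last group the warmest.  Requires an even week count.

    Returns the weekly table with a ``group_id`` column.
    """
    n = len(weekly)
    if n % 2 != 0:
        raise ValueError(
            f"cannot pair an odd number of weeks ({n}); supply an explicit "
            "grouping configuration instead")
    ordered = weekly.sort_values(["avg_rank", "week"], kind="mergesort").reset_index(drop=True)
    ordered["group_id"] = ordered.index // 2 + 1
    return ordered.sort_values("week").reset_index(drop=True)


def make_groups(daily_cci: pd.DataFrame,
                config: PipelineConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """Convenience: rank days, average per week, pair into groups."""
    return pair_weeks(weekly_average_rank(rank_days(daily_cci, config)))


def group_weather_summary(weather: pd.DataFrame, groups: pd.DataFrame,
                          day_ranks: pd.DataFrame) -> pd.DataFrame:
    """Per-group weather statistics summarized from daily values.

    For each group: maximum of daily maximum temperature, minimum of daily
    minimum temperature, mean of daily mean temperature, total rainfall,
    mean of daily mean wind speed (reported in km/h, the customary reporting
    unit) and mean of daily mean solar radiation.
    """
    w = weather.copy()
    w["date"] = pd.to_datetime(w["t"]).dt.date
    daily = w.groupby("date").agg(
        tmax=("ta", "max"), tmin=("ta", "min"), tmean=("ta", "mean"),
        rain=("rain", "sum"), wind=("ws", "mean"), solar=("rad", "mean"),
    ).reset_index()
    daily = daily.merge(day_ranks[["date", "week"]], on="date", how="inner")
    daily = daily.merge(groups[["week", "group_id"]], on="week", how="inner")
    out = daily.groupby("group_id").agg(
        temp_max=("tmax", "max"), temp_min=("tmin", "min"),
        temp_mean=("tmean", "mean"), rain_total=("rain", "sum"),
        wind_mean_kmh=("wind", "mean"), solar_mean=("solar", "mean"),
    ).reset_index()
    out["wind_mean_kmh"] = out["wind_mean_kmh"] * 3.6
    return out
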