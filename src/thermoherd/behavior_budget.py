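"""Ethogram time budgets.

Collar behavior labels (one per 5-second interval, six classes) are summed
into hourly budgets, tagged with a daypart (daytime 05:00-18:00 local,
nighttime the remaining 11 hours of the same calendar date), and rolled up
to per-animal daily summaries carrying shade use, travel distance and the
date's peak CCI.  Weighing Mondays are excluded from behavioral summaries
because mustering distorts the time budgets.
"""

from __future__ import annotations

import datetime as dt
import logging

import numpy as np
import pandas as pd

from .config import BEHAVIOR_CLASSES, DEFAULT_CONFIG, PipelineConfig
from .errors import SchemaError

logger = logging.getLogger(__name__)

__all__ = [
    "hourly_budget", "split_daypart", "exclude_weighing_days",
    "build_daily_summaries",
]


def hourly_budget(records: pd.DataFrame, dt_s: float = 5.0) -> pd.DataFrame:
    """Hours spent per behavior class per (animal, clock hour).

    Each label contributes ``dt_s`` seconds to its class.  ``coverage`` is
    the labelled fraction of the hour (<= 1 for a 5-s cadence without
    duplicates).  Hours with no records are absent from the output.

    Raises
    ------
    SchemaError
        On duplicate (animal_id, t) records, naming the timestamp.
    """
    cols = ["animal_id", "hour", *BEHAVIOR_CLASSES, "coverage"]
    if len(records) == 0:
        return pd.DataFrame(columns=cols)
    dup = records.duplicated(subset=["animal_id", "t"])
    if dup.any():
        r = records[dup].iloc[0]
        raise SchemaError(
            f"duplicate behavior record for animal {r['animal_id']} at {r['t']}")
    df = records.copy()
    df["hour"] = pd.to_datetime(df["t"]).dt.floor("h")
    counts = (
        df.groupby(["animal_id", "hour", "label"], observed=True)
        .size()
        .unstack("label", fill_value=0)
        .reindex(columns=list(BEHAVIOR_CLASSES), fill_value=0)
    )
    hours = counts * (dt_s / 3600.0)
    hours["coverage"] = hours.sum(axis=1)
    return hours.reset_index()[cols]


def split_daypart(hourly: pd.DataFrame,
                  config: PipelineConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """Tag hourly rows with ``date`` and ``daypart`` (day/night).

    Daytime is the half-open local window [day_start, day_end).  By default
    a date's night is that same date's evening (18:00-24:00) plus its
    pre-dawn block (00:00-05:00); with ``config.night_spans_midnight`` the
    pre-dawn block is instead attributed to the previous date's night.
    """
    out = hourly.copy()
    h = pd.to_datetime(out["hour"])
    hod = h.dt.hour
    is_day = (hod >= config.day_start) & (hod < config.day_end)
    out["daypart"] = np.where(is_day, "day", "night")
    date = h.dt.date
    if config.night_spans_midnight:
        predawn = hod < config.day_start
        date = pd.Series(date, index=out.index).where(
            ~predawn, h.dt.date - dt.timedelta(days=1))
    out["date"] = date
    return out


def exclude_weighing_days(daily: pd.DataFrame, weekday: int = 0) -> pd.DataFrame:
    """Drop rows whose date falls on the weigh day (Monday by default).

    Applies to behavioral summaries only — weigh records themselves are kept
    elsewhere.  Idempotent.
    """
    if len(daily) == 0:
        return daily
    wd = pd.to_datetime(daily["date"]).dt.weekday
    out = daily[wd != weekday].reset_index(drop=True)
    if len(out) == 0:
        logger.warning("all rows fell on weighing days; result is empty")
    return out


def build_daily_summaries(
    hourly: pd.DataFrame,
    movement: pd.DataFrame | None,
    daily_cci: pd.DataFrame | None,
    profiles: pd.DataFrame | None = None,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Per (animal, date, daypart in {full, day, night}) daily summary.

    Class-hours are summed per daypart; the full-day row is the exact sum of
    its day and night rows.  The date's *full-day* maximum CCI is attached
    unchanged to all three dayparts (peak exposure is the stressor).  Travel
    distance and time-in-open come from the movement summaries when given;
    time-in-open is reported for the daytime rows only, since shade seeking
    is meaningless at night.  Rows whose daypart has behavior records in
    fewer than ``config.coverage_threshold`` of its hours are flagged
    ``incomplete`` (they stay in the table; the correlation layer drops
    them).
    """
    tagged = split_daypart(hourly, config)
    by = ["animal_id", "date", "daypart"]
    parts = tagged.groupby(by, observed=True).agg(
        **{c: (c, "sum") for c in BEHAVIOR_CLASSES},
        n_hours=("hour", "size"),
    ).reset_index()
    full = parts.groupby(["animal_id", "date"], observed=True).agg(
        **{c: (c, "sum") for c in BEHAVIOR_CLASSES},
        n_hours=("n_hours", "sum"),
    ).reset_index().assign(daypart="full")
    out = pd.concat([parts, full], ignore_index=True)

    plen = out["daypart"].map(config.daypart_length)
    out["incomplete"] = out["n_hours"] < config.coverage_threshold * plen

    if movement is not None and len(movement):
        mv = movement[["animal_id", "date", "daypart", "time_in_open",
                       "time_in_shade", "distance", "excluded"]]
        out = out.merge(mv, on=by, how="left")
        out.loc[out["daypart"] != "day", ["time_in_open", "time_in_shade"]] = np.nan
        # propagate the implausible-distance flag across the animal-day
        excl = (out.groupby(["animal_id", "date"], observed=True)["excluded"]
                .transform(lambda s: bool(s.fillna(False).any())))
        out["excluded"] = excl.astype(bool)
    else:
        out["time_in_open"] = np.nan
        out["time_in_shade"] = np.nan
        out["distance"] = np.nan
        out["excluded"] = False

    if daily_cci is not None and len(daily_cci):
        out = out.merge(daily_cci[["date", "max_cci"]], on="date", how="left")
        n_orphan = int(out["max_cci"].isna().sum())
        if n_orphan:
            logger.info("%d summary row(s) have no CCI for their date", n_orphan)
    else:
        out["max_cci"] = np.nan

    trials = [config.trial_of(d) for d in out["date"]]
    out["trial_id"] = [t.trial_id if t else None for t in trials]
    out["week_in_trial"] = [t.week_of(d) if t else np.nan
                            for t, d in zip(trials, out["date"])]
    out["week"] = [config.global_week(t.trial_id, w) if t else np.nan
                   for t, w in zip(trials, out["week_in_trial"])]
    return out.sort_values(by).reset_index(drop=True)
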