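"""End-to-end orchestration: raw streams to correlation tables.

The stages, in order: CCI from weather and its daily maxima; 10-minute
median positions, open/canopy classification and movement summaries; hourly
behavior budgets rolled into daily daypart summaries (weigh-Monday rows
dropped); day-rank exposure groups; weekly weight gains; and the per-group,
per-daypart correlation suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .behavior_budget import (build_daily_summaries, exclude_weighing_days,
                              hourly_budget)
from .climate_index import cci_series, daily_max_cci
from .config import DEFAULT_CONFIG, PipelineConfig
from .correlation_stats import (correlation_suite, weekly_weight_gain)
from .exposure_ranking import (group_weather_summary, make_groups, rank_days)
from .trajectory import classify_open, median_positions, movement_summary

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    """Bundle of every intermediate and final table of one pipeline run."""

    daily_cci: pd.DataFrame
    positions: pd.DataFrame
    movement: pd.DataFrame
    summaries: pd.DataFrame
    day_ranks: pd.DataFrame
    groups: pd.DataFrame
    weather_summary: pd.DataFrame
    gains: pd.DataFrame
    correlations: pd.DataFrame


def run_pipeline(streams: dict,
                 config: PipelineConfig = DEFAULT_CONFIG) -> PipelineResult:
    """Run the whole analysis on a stream bundle.

    ``streams`` is the dict produced by :func:`thermoherd.io_formats.
    read_streams` or :func:`thermoherd.synthetic_data.generate_all`:
    keys ``behavior, gnss, weather, canopy, profiles, weights``.
    """
    weather = streams["weather"]
    cci = weather if "cci" in weather.columns else cci_series(weather)
    daily_cci = daily_max_cci(cci)

    positions = classify_open(median_positions(streams["gnss"]), streams["canopy"])
    movement = movement_summary(positions, config)

    hourly = hourly_budget(streams["behavior"], dt_s=config.label_dt_s)
    summaries = build_daily_summaries(hourly, movement, daily_cci,
                                      streams["profiles"], config)
    summaries = exclude_weighing_days(summaries)

    day_ranks = rank_days(daily_cci, config)
    groups = make_groups(daily_cci, config)
    weather_stats = group_weather_summary(weather, groups, day_ranks)

    gains = weekly_weight_gain(streams["weights"], config)
    correlations = correlation_suite(summaries, gains, streams["profiles"],
                                     groups, config)
    return PipelineResult(
        daily_cci=daily_cci, positions=positions, movement=movement,
        summaries=summaries, day_ranks=day_ranks, groups=groups,
        weather_summary=weather_stats, gains=gains, correlations=correlations)
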