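"""Day-rank exposure grouping against brute-force oracles."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from thermoherd.config import PipelineConfig, TrialWindow
from thermoherd.exposure_ranking import (group_weather_summary, make_groups,
                                         pair_weeks, rank_days,
                                         weekly_average_rank)

CFG = PipelineConfig()  # two 28-day trials starting 2022-11-21 / 2023-11-20


def _daily(max_ccis, start=dt.date(2022, 11, 21)):
    return pd.DataFrame({
        "date": [start + dt.timedelta(days=i) for i in range(len(max_ccis))],
        "max_cci": max_ccis,
    })


def _merged_56(rng, low=36.0, high=52.0):
    vals = rng.uniform(low, high, 56)
    d1 = _daily(vals[:28], CFG.trial_windows[0].start)
    d2 = _daily(vals[28:], CFG.trial_windows[1].start)
    return pd.concat([d1, d2], ignore_index=True)


def test_rank_examples():
    out = rank_days(_daily([40.0, 36.0, 52.0]), CFG)
    assert list(out["rank"]) == [2.0, 1.0, 3.0]
    tied = rank_days(_daily([40.0, 40.0]), CFG)
    assert list(tied["rank"]) == [1.5, 1.5]


def test_rank_permutation_invariance(rng):
    daily = _merged_56(rng)
    shuffled = daily.sample(frac=1.0, random_state=3).reset_index(drop=True)
    a = rank_days(daily, CFG).set_index("date")["rank"]
    b = rank_days(shuffled, CFG).set_index("date")["rank"]
    assert a.sort_index().equals(b.sort_index())


def test_rank_monotone_transform_invariance(rng):
    daily = _merged_56(rng)
    transformed = daily.assign(max_cci=np.exp(daily["max_cci"] / 10.0))
    a = rank_days(daily, CFG)["rank"]
    b = rank_days(transformed, CFG)["rank"]
    assert list(a) == list(b)


def test_rank_empty_input_rejected():
    with pytest.raises(ValueError):
        rank_days(_daily([]), CFG)


def _brute_force_ranks(values):
    """Independent oracle: average-of-positions rank from a sorted scan."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def test_ranks_match_brute_force(rng):
    daily = _merged_56(rng)
    # plant some exact ties
    daily.loc[5, "max_cci"] = daily.loc[40, "max_cci"]
    got = list(rank_days(daily, CFG)["rank"])
    want = _brute_force_ranks(list(daily["max_cci"]))
    assert got == pytest.approx(want)


def test_weekly_average_examples():
    daily = _daily(list(range(7)))
    ranked = rank_days(daily, CFG)
    out = weekly_average_rank(ranked)
    assert out["avg_rank"].iloc[0] == pytest.approx(4.0)


def test_weekly_average_matches_brute_force(rng):
    daily = _merged_56(rng)
    ranked = rank_days(daily, CFG)
    out = weekly_average_rank(ranked).set_index("week")["avg_rank"]
    for week, sub in ranked.groupby("week"):
        assert out.loc[week] == pytest.approx(sum(sub["rank"]) / len(sub))


def test_degenerate_equal_weeks():
    daily = pd.concat([
        _daily([40.0] * 28, CFG.trial_windows[0].start),
        _daily([40.0] * 28, CFG.trial_windows[1].start)], ignore_index=True)
    weekly = weekly_average_rank(rank_days(daily, CFG))
    assert weekly["avg_rank"].nunique() == 1


def test_pair_weeks_examples():
    weekly = pd.DataFrame({"week": range(1, 9), "trial_id": "trial1",
                           "avg_rank": [10, 20, 30, 40, 50, 60, 70, 80]})
    out = pair_weeks(weekly).set_index("week")["group_id"]
    assert list(out) == [1, 1, 2, 2, 3, 3, 4, 4]
    permuted = pair_weeks(weekly.sample(frac=1.0, random_state=4))
    assert permuted.set_index("week")["group_id"].sort_index().tolist() == list(out)


def test_pair_weeks_groups_partition():
    weekly = pd.DataFrame({"week": range(1, 9), "trial_id": "trial1",
                           "avg_rank": [33, 11, 77, 55, 22, 88, 44, 66]})
    out = pair_weeks(weekly)
    sizes = out.groupby("group_id").size()
    assert list(sizes) == [2, 2, 2, 2]
    # group order follows ascending average rank
    means = out.groupby("group_id")["avg_rank"].mean()
    assert means.is_monotonic_increasing


def test_pair_weeks_odd_count_rejected():
    weekly = pd.DataFrame({"week": [1, 2, 3], "trial_id": "trial1",
                           "avg_rank": [1.0, 2.0, 3.0]})
    with pytest.raises(ValueError, match="odd|grouping"):
        pair_weeks(weekly)


def test_planted_week_ordering_recovered():
    # plant strictly separated weekly CCI levels; pairing must recover them
    hits = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        levels = rng.permutation(np.arange(8) * 2.0 + 37.0)
        days = np.repeat(levels, 7) + rng.uniform(-0.4, 0.4, 56)
        daily = pd.concat([
            _daily(days[:28], CFG.trial_windows[0].start),
            _daily(days[28:], CFG.trial_windows[1].start)], ignore_index=True)
        groups = make_groups(daily, CFG).set_index("week")["group_id"]
        want = pd.Series(np.argsort(np.argsort(levels)) // 2 + 1,
                         index=range(1, 9))
        hits += int((groups.sort_index() == want).all())
    assert hits == 20


def test_warm_trial_dominates_top_group():
    rng = np.random.default_rng(11)
    cool = rng.uniform(36, 42, 28)
    warm = rng.uniform(46, 52, 28)
    daily = pd.concat([
        _daily(cool, CFG.trial_windows[0].start),
        _daily(warm, CFG.trial_windows[1].start)], ignore_index=True)
    groups = make_groups(daily, CFG)
    top = groups[groups["group_id"] == 4]
    assert set(top["trial_id"]) == {"trial2"}


def test_group_weather_summary_against_brute_force(rng, tiny_streams):
    weather = tiny_streams["weather"]
    cfg = PipelineConfig(trial_windows=[
        TrialWindow(trial_id="trial1", start=dt.date(2022, 11, 21), n_days=7),
        TrialWindow(trial_id="trial2", start=dt.date(2023, 11, 20), n_days=7),
    ])
    ranked = rank_days(tiny_streams["daily_cci"], cfg)
    groups = pair_weeks(weekly_average_rank(ranked))
    out = group_weather_summary(weather, groups, ranked).set_index("group_id")

    w = weather.copy()
    w["date"] = pd.to_datetime(w["t"]).dt.date
    week_of = dict(zip(ranked["date"], ranked["week"]))
    group_of = dict(zip(groups["week"], groups["group_id"]))
    for gid in out.index:
        dates = [d for d in w["date"].unique()
                 if group_of[week_of[d]] == gid]
        sub = w[w["date"].isin(dates)]
        daily_max = sub.groupby("date")["ta"].max().max()
        daily_min = sub.groupby("date")["ta"].min().min()
        daily_mean = sub.groupby("date")["ta"].mean().mean()
        assert out.loc[gid, "temp_max"] == pytest.approx(daily_max)
        assert out.loc[gid, "temp_min"] == pytest.approx(daily_min)
        assert out.loc[gid, "temp_mean"] == pytest.approx(daily_mean)
        assert out.loc[gid, "rain_total"] == pytest.approx(sub["rain"].sum())
        assert out.loc[gid, "wind_mean_kmh"] == pytest.approx(
            sub.groupby("date")["ws"].mean().mean() * 3.6)


def test_constant_weather_summary():
    t = pd.date_range("2022-11-21", periods=7 * 144, freq="10min")
    weather = pd.DataFrame({"t": t, "ta": 25.0, "rh": 50.0, "ws": 2.0,
                            "rad": 300.0, "rain": 0.0})
    cfg = PipelineConfig(trial_windows=[
        TrialWindow(trial_id="trial1", start=dt.date(2022, 11, 21), n_days=7)])
    daily = pd.DataFrame({"date": sorted(set(t.date)), "max_cci": 40.0})
    ranked = rank_days(daily, cfg)
    groups = weekly_average_rank(ranked).assign(group_id=1)
    out = group_weather_summary(weather, groups, ranked)
    assert out["temp_max"].iloc[0] == out["temp_min"].iloc[0] == 25.0
    assert out["temp_mean"].iloc[0] == 25.0
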