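"""GNSS trajectory processing.

Raw collar fixes (nominally 1 Hz) are reduced to one median position per
10-minute interval, each median is classified as lying in the open or under
tree canopy, and consecutive medians are chained into great-circle travel
distances.  The median-to-median distance deliberately underestimates the
true path length; it is the estimator used throughout and its bias is
documented rather than corrected.
"""

from __future__ import annotations

import datetime as dt
import logging

import numpy as np
import pandas as pd
import shapely

from .config import DEFAULT_CONFIG, PipelineConfig

__all__ = [
    "EARTH_RADIUS_KM", "haversine_km", "median_positions", "classify_open",
    "movement_summary",
]

logger = logging.getLogger(__name__)

#: Mean Earth radius used by the haversine estimator.
EARTH_RADIUS_KM = 6371.0


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray | float:
    """Great-circle distance in km on a sphere of radius 6371.0 km.

    Accepts scalars or arrays (broadcast).  Symmetric, zero iff the points
    coincide.
    """
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(h)))
    return float(d) if d.ndim == 0 else d


def median_positions(fixes: pd.DataFrame) -> pd.DataFrame:
    """Collapse raw fixes to component-wise medians on the 10-minute grid.

    ``fixes`` needs columns ``animal_id, t, lat, lon``.  Each output row is
    one (animal, interval) with at least one fix; empty intervals are simply
    absent.  Latitude and longitude medians are taken independently (the
    usual convention: the median point need not be an observed fix).
    """
    if len(fixes) == 0:
        return pd.DataFrame(columns=["animal_id", "interval_start", "lat", "lon"])
    t = pd.to_datetime(fixes["t"])
    interval = t.dt.floor("10min")
    med = (
        fixes.assign(interval_start=interval)
        .groupby(["animal_id", "interval_start"], sort=True, observed=True)[["lat", "lon"]]
        .median()
        .reset_index()
    )
    return med


def classify_open(positions: pd.DataFrame, canopy_map) -> pd.DataFrame:
    """Flag each median position as open, canopy, and in/out of paddock.

    A position is *open* iff it lies inside the paddock and inside no canopy
    polygon.  A point exactly on a canopy boundary counts as canopy — the
    conservative convention for shade estimates.  Points outside the paddock
    are still classified (never open) but flagged ``out_of_paddock`` with a
    logged warning.

    Returns a copy of ``positions`` with boolean columns ``in_canopy``,
    ``in_open`` and ``out_of_paddock``.
    """
    out = positions.copy()
    if len(out) == 0:
        for col in ("in_canopy", "in_open", "out_of_paddock"):
            out[col] = pd.Series(dtype=bool)
        return out
    pts = shapely.points(out["lon"].to_numpy(), out["lat"].to_numpy())
    shapely.prepare(canopy_map.paddock)
    in_paddock = shapely.covers(canopy_map.paddock, pts)
    in_canopy = np.zeros(len(out), dtype=bool)
    for poly in canopy_map.canopies:
        shapely.prepare(poly)
        # intersects (not contains) so boundary points count as canopy
        in_canopy |= shapely.intersects(poly, pts)
    out["in_canopy"] = in_canopy
    out["in_open"] = in_paddock & ~in_canopy
    out["out_of_paddock"] = ~in_paddock
    n_out = int(out["out_of_paddock"].sum())
    if n_out:
        logger.warning("%d median position(s) outside the paddock", n_out)
    return out


def _daypart_of_hours(hours: np.ndarray, config: PipelineConfig) -> np.ndarray:
    day = (hours >= config.day_start) & (hours < config.day_end)
    return np.where(day, "day", "night")


def movement_summary(
    positions: pd.DataFrame,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Daily daypart summaries of shade use and travel distance.

    For every (animal, date, daypart in {full, day, night}) with at least one
    classified median position:

    * ``time_in_open`` / ``time_in_shade`` — number of 10-min intervals whose
      median is open / not open, divided by 6 (hours).  They partition the
      daypart's observed interval count exactly.
    * ``distance`` — sum of haversine segments between consecutive medians of
      the same animal and calendar date, skipping any segment across a gap
      longer than ``config.gap_limit_min``.  A segment belongs to a daypart
      only when both endpoints do; segments straddling the day/night boundary
      count toward the full day alone, so
      full = day + night + boundary segments, exactly, on gap-free tracks.
    * ``excluded`` — True when the full-day distance falls outside
      ``config.distance_range_km`` (implausible for a small enclosed
      paddock); the flag is propagated to all three dayparts of that
      animal-day.
    """
    cols = ["animal_id", "date", "daypart", "n_intervals", "time_in_open",
            "time_in_shade", "distance", "excluded"]
    if len(positions) == 0:
        return pd.DataFrame(columns=cols)

    df = positions.sort_values(["animal_id", "interval_start"]).reset_index(drop=True)
    ts = pd.to_datetime(df["interval_start"])
    df["date"] = ts.dt.date
    hours = ts.dt.hour.to_numpy()
    df["daypart"] = _daypart_of_hours(hours, config)

    # occupancy: count intervals per (animal, date, daypart) and open subset
    occ = (
        df.groupby(["animal_id", "date", "daypart"], observed=True)
        .agg(n_intervals=("in_open", "size"), n_open=("in_open", "sum"))
        .reset_index()
    )
    occ_full = (
        occ.groupby(["animal_id", "date"], observed=True)[["n_intervals", "n_open"]]
        .sum()
        .reset_index()
        .assign(daypart="full")
    )
    occ = pd.concat([occ, occ_full], ignore_index=True)
    occ["time_in_open"] = occ["n_open"] / 6.0
    occ["time_in_shade"] = (occ["n_intervals"] - occ["n_open"]) / 6.0

    # distances: consecutive segments within an animal, same date, small gap
    same_animal = df["animal_id"].to_numpy()[1:] == df["animal_id"].to_numpy()[:-1]
    same_date = df["date"].to_numpy()[1:] == df["date"].to_numpy()[:-1]
    gap_min = (ts.to_numpy()[1:] - ts.to_numpy()[:-1]) / np.timedelta64(60, "s")
    ok = same_animal & same_date & (gap_min <= config.gap_limit_min)
    seg_km = haversine_km(
        df["lat"].to_numpy()[:-1], df["lon"].to_numpy()[:-1],
        df["lat"].to_numpy()[1:], df["lon"].to_numpy()[1:],
    )
    seg_km = np.where(ok, seg_km, 0.0)
    part_prev = df["daypart"].to_numpy()[:-1]
    part_next = df["daypart"].to_numpy()[1:]
    seg_part = np.where(part_prev == part_next, part_prev, "boundary")
    seg = pd.DataFrame({
        "animal_id": df["animal_id"].to_numpy()[1:],
        "date": df["date"].to_numpy()[1:],
        "daypart": seg_part,
        "km": seg_km,
    })[ok]

    dist = (
        seg.groupby(["animal_id", "date", "daypart"], observed=True)["km"]
        .sum()
        .unstack(fill_value=0.0)
    )
    for p in ("day", "night", "boundary"):
        if p not in dist.columns:
            dist[p] = 0.0
    dist["full"] = dist["day"] + dist["night"] + dist["boundary"]
    dist = (
        dist[["full", "day", "night"]]
        .reset_index()
        .melt(id_vars=["animal_id", "date"], var_name="daypart", value_name="distance")
    )

    out = occ.merge(dist, on=["animal_id", "date", "daypart"], how="left")
    out["distance"] = out["distance"].fillna(0.0)

    lo, hi = config.distance_range_km
    full = out[out["daypart"] == "full"][["animal_id", "date", "distance"]]
    bad = full[(full["distance"] < lo) | (full["distance"] > hi)][["animal_id", "date"]]
    out["excluded"] = False
    if len(bad):
        key = out.set_index(["animal_id", "date"]).index
        badkey = pd.MultiIndex.from_frame(bad)
        out.loc[key.isin(badkey), "excluded"] = True
    return out[cols].sort_values(["animal_id", "date", "daypart"]).reset_index(drop=True)
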