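"""Trajectory processing: haversine closed forms, medians, occupancy, distances."""

import numpy as np
import pandas as pd
import pytest
from shapely import Point

from thermoherd.config import PipelineConfig
from thermoherd.io_formats import CanopyMap
from thermoherd.trajectory import (EARTH_RADIUS_KM, classify_open,
                                   haversine_km, median_positions,
                                   movement_summary)

# ---------------------------------------------------------------------------
# haversine


def test_haversine_closed_forms():
    assert haversine_km(12.3, 45.6, 12.3, 45.6) == 0.0
    # antipodal along the equator: half the circumference
    assert haversine_km(0.0, 0.0, 0.0, 180.0) == pytest.approx(
        np.pi * EARTH_RADIUS_KM, abs=1e-6)
    # one degree of meridian arc
    assert haversine_km(0.0, 0.0, 1.0, 0.0) == pytest.approx(
        EARTH_RADIUS_KM * np.pi / 180.0, abs=1e-6)


def test_haversine_symmetry_and_positivity(rng):
    a = rng.uniform(-80, 80, (50, 2))
    b = rng.uniform(-80, 80, (50, 2))
    d_ab = haversine_km(a[:, 0], a[:, 1], b[:, 0], b[:, 1])
    d_ba = haversine_km(b[:, 0], b[:, 1], a[:, 0], a[:, 1])
    np.testing.assert_allclose(d_ab, d_ba, atol=1e-12)
    assert np.all(d_ab > 0)


# ---------------------------------------------------------------------------
# medians


def _fixes(lats, lons=None, animal="A", start="2022-11-21 08:00:00"):
    lons = lons if lons is not None else [150.0] * len(lats)
    t0 = pd.Timestamp(start)
    return pd.DataFrame({
        "animal_id": animal,
        "t": [t0 + pd.Timedelta(seconds=i) for i in range(len(lats))],
        "lat": lats, "lon": lons,
    })


def test_median_identical_fixes():
    med = median_positions(_fixes([-27.55] * 600, [152.33] * 600))
    assert len(med) == 1
    assert med["lat"].iloc[0] == -27.55
    assert med["lon"].iloc[0] == 152.33


def test_median_odd_and_even_conventions():
    med = median_positions(_fixes([1.0, 2.0, 100.0]))
    assert med["lat"].iloc[0] == 2.0
    med = median_positions(_fixes([1.0, 2.0, 3.0, 10.0]))
    assert med["lat"].iloc[0] == 2.5


def test_median_outlier_robustness(rng):
    # one wild outlier moves the median by at most the remaining spread
    base = rng.uniform(-27.551, -27.549, 9)
    clean = median_positions(_fixes(list(base)))["lat"].iloc[0]
    dirty = median_positions(_fixes(list(base) + [35.0]))["lat"].iloc[0]
    assert abs(dirty - clean) <= np.ptp(base)


def test_median_empty_input():
    assert len(median_positions(pd.DataFrame(
        columns=["animal_id", "t", "lat", "lon"]))) == 0


def test_median_interval_alignment():
    fixes = _fixes([1.0] * 1200, start="2022-11-21 08:03:20")
    med = median_positions(fixes)
    starts = pd.to_datetime(med["interval_start"])
    assert (starts.dt.minute % 10 == 0).all()
    assert (starts.dt.second == 0).all()


# ---------------------------------------------------------------------------
# open/canopy classification


def _positions(latlons, start="2022-11-21 08:00:00"):
    t0 = pd.Timestamp(start)
    return pd.DataFrame({
        "animal_id": "A",
        "interval_start": [t0 + pd.Timedelta(minutes=10 * i)
                           for i in range(len(latlons))],
        "lat": [p[0] for p in latlons], "lon": [p[1] for p in latlons],
    })


def test_classify_centroid_edge_and_open(square_map):
    pos = _positions([
        (0.0003, 0.0003),   # canopy centroid
        (0.0008, 0.0008),   # open, far from canopy
        (0.0002, 0.0003),   # exactly on canopy edge
        (0.0002, 0.0002),   # canopy corner vertex
        (0.0050, 0.0050),   # outside the paddock
    ])
    out = classify_open(pos, square_map)
    assert list(out["in_open"]) == [False, True, False, False, False]
    assert list(out["in_canopy"]) == [True, False, True, True, False]
    assert list(out["out_of_paddock"]) == [False, False, False, False, True]


def _winding_number(px, py, ring):
    """Independent point-in-polygon oracle (nonzero winding rule)."""
    wn = 0
    for (x0, y0), (x1, y1) in zip(ring, ring[1:]):
        if y0 <= py:
            if y1 > py and (x1 - x0) * (py - y0) - (px - x0) * (y1 - y0) > 0:
                wn += 1
        elif y1 <= py and (x1 - x0) * (py - y0) - (px - x0) * (y1 - y0) < 0:
            wn -= 1
    return wn != 0


def _random_convex_polygon(rng, cx, cy, r):
    n = int(rng.integers(4, 9))
    gaps = rng.gamma(1.0, 1.0, n) + 0.05
    angles = 2 * np.pi * np.cumsum(gaps) / gaps.sum()
    radii = rng.uniform(0.4 * r, r, n)
    pts = [(cx + rr * np.cos(a), cy + rr * np.sin(a))
           for a, rr in zip(angles, radii)]
    return pts + [pts[0]]


def test_classification_matches_winding_number_oracle(rng):
    n_checked = 0
    for _ in range(10):
        ring = _random_convex_polygon(rng, 0.5, 0.5, 0.3)  # (lon, lat) ring
        cmap = CanopyMap.from_latlon(
            paddock=[(-2, -2), (-2, 2), (2, 2), (2, -2), (-2, -2)],
            canopies=[[(lat, lon) for lon, lat in ring]],
        )
        px = rng.uniform(0, 1, 100)
        py = rng.uniform(0, 1, 100)
        pos = _positions(list(zip(py, px)))
        got = ~classify_open(pos, cmap)["in_open"].to_numpy()
        want = np.array([_winding_number(x, y, ring) for x, y in zip(px, py)])
        # skip points within a hair of the boundary (conventions differ there)
        edge = np.array([abs(cmap.canopies[0].exterior.distance(
            Point(x, y))) < 1e-9 for x, y in zip(px, py)])
        assert np.array_equal(got[~edge], want[~edge])
        n_checked += int((~edge).sum())
    assert n_checked >= 1000


# ---------------------------------------------------------------------------
# movement summaries


def _step_north_deg(km):
    return km / EARTH_RADIUS_KM * 180.0 / np.pi


def _classified(latlons, start, in_open=None):
    pos = _positions(latlons, start=start)
    pos["in_open"] = in_open if in_open is not None else [True] * len(latlons)
    return pos


def test_time_in_open_counts_intervals():
    flags = [True] * 9 + [False] * 3
    pos = _classified([(0.0, 0.0)] * 12, "2022-11-21 08:00:00", flags)
    out = movement_summary(pos)
    day = out[out["daypart"] == "day"].iloc[0]
    assert day["time_in_open"] == pytest.approx(1.5)
    assert day["time_in_shade"] == pytest.approx(0.5)
    # partition: open + shade = observed intervals / 6
    assert day["time_in_open"] + day["time_in_shade"] == pytest.approx(
        day["n_intervals"] / 6.0)


def test_stationary_animal_zero_distance_not_excluded():
    pos = _classified([(0.0, 0.0)] * 144, "2022-11-21 00:00:00")
    out = movement_summary(pos)
    full = out[out["daypart"] == "full"].iloc[0]
    assert full["distance"] == 0.0
    assert not full["excluded"]


def test_zigzag_track_distance():
    # 30 northward segments of exactly 100 m -> 3.0 km
    step = _step_north_deg(0.1)
    lats = [i * step for i in range(31)]
    pos = _classified([(lat, 0.0) for lat in lats], "2022-11-21 08:00:00")
    out = movement_summary(pos)
    day = out[out["daypart"] == "day"].iloc[0]
    assert day["distance"] == pytest.approx(3.0, abs=1e-9)


def test_gap_rule_skips_long_gaps():
    t0 = pd.Timestamp("2022-11-21 08:00:00")
    pos = pd.DataFrame({
        "animal_id": "A",
        "interval_start": [t0, t0 + pd.Timedelta(minutes=10),
                           t0 + pd.Timedelta(minutes=90)],
        "lat": [0.0, _step_north_deg(0.1), _step_north_deg(0.2)],
        "lon": 0.0, "in_open": True,
    })
    out = movement_summary(pos)
    day = out[out["daypart"] == "day"].iloc[0]
    # only the first 100 m segment counts; the 80-min gap is skipped
    assert day["distance"] == pytest.approx(0.1, abs=1e-9)


def test_daypart_distance_partition():
    # hourly positions across a whole day: full = day + night + boundary
    t0 = pd.Timestamp("2022-11-21 00:00:00")
    step = _step_north_deg(0.05)
    pos = pd.DataFrame({
        "animal_id": "A",
        "interval_start": [t0 + pd.Timedelta(minutes=10 * i) for i in range(144)],
        "lat": [i * step for i in range(144)], "lon": 0.0, "in_open": True,
    })
    out = movement_summary(pos).set_index("daypart")
    full = out.loc["full", "distance"]
    day = out.loc["day", "distance"]
    night = out.loc["night", "distance"]
    # 143 segments of 50 m; 2 of them straddle the 05:00 and 18:00 boundaries
    assert full == pytest.approx(143 * 0.05, abs=1e-9)
    assert full - day - night == pytest.approx(2 * 0.05, abs=1e-9)


def test_implausible_distance_excluded_and_propagated():
    # 144 10-min steps of 100 m -> 14.3 km, outside the 0-10 km range
    t0 = pd.Timestamp("2022-11-21 00:00:00")
    step = _step_north_deg(0.1)
    pos = pd.DataFrame({
        "animal_id": "A",
        "interval_start": [t0 + pd.Timedelta(minutes=10 * i) for i in range(144)],
        "lat": [i * step for i in range(144)], "lon": 0.0, "in_open": True,
    })
    out = movement_summary(pos)
    assert out["excluded"].all()
    assert out[out["daypart"] == "full"]["distance"].iloc[0] > 10.0


def test_custom_distance_range():
    pos = _classified([(0.0, 0.0)] * 6, "2022-11-21 08:00:00")
    cfg = PipelineConfig(distance_range_km=(0.5, 10.0))
    out = movement_summary(pos, cfg)
    assert out["excluded"].all()  # 0 km is below the configured floor
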