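"""Readers, writers and stream synchronization.

All tabular inputs are comma-separated with a header row and ISO-8601
timestamps.  Timestamps are normalized on read to naive local trial time at
the configured fixed UTC offset (Queensland: UTC+10, no DST).  The canopy
map travels as a GeoJSON FeatureCollection whose features carry a ``role``
property (``paddock`` or ``canopy``); GeoJSON stores vertices lon,lat per
the standard while the in-memory API speaks lat,lon — the converters here
own that swap.

Round-trip guarantee: write-then-read is lossless at the declared precision
(timestamps to whole seconds, coordinates to 1e-7 degrees).
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon, mapping, shape

from .config import BEHAVIOR_CLASSES, DEFAULT_CONFIG, PipelineConfig
from .errors import GeometryError, RowError, SchemaError

logger = logging.getLogger(__name__)

TIME_FORMAT = "%Y-%m-%dT%H:%M:%S"
COORD_FORMAT = "%.7f"


# ---------------------------------------------------------------------------
# canopy map

@dataclass
class CanopyMap:
    """Paddock boundary plus tree-canopy polygons (shapely, x=lon, y=lat)."""

    paddock: Polygon
    canopies: list[Polygon] = field(default_factory=list)

    @staticmethod
    def _check_ring(coords, role: str) -> None:
        # closed rings repeat the first vertex; require >=3 distinct
        distinct = {tuple(c) for c in coords}
        if len(distinct) < 3:
            raise GeometryError(f"{role} ring has fewer than 3 distinct vertices")

    @classmethod
    def from_latlon(cls, paddock: list[tuple[float, float]],
                    canopies: list[list[tuple[float, float]]]) -> "CanopyMap":
        """Build from (lat, lon) vertex lists."""
        def poly(vertices, role):
            cls._check_ring(vertices, role)
            p = Polygon([(lon, lat) for lat, lon in vertices])
            if not p.is_valid:
                raise GeometryError(f"{role} ring is not simple")
            return p
        return cls(poly(paddock, "paddock"),
                   [poly(c, "canopy") for c in canopies])

    @classmethod
    def from_geojson(cls, path: str | Path) -> "CanopyMap":
        with open(path) as fh:
            fc = json.load(fh)
        paddock = None
        canopies = []
        for feat in fc.get("features", []):
            role = feat.get("properties", {}).get("role")
            geom = feat.get("geometry", {})
            coords = geom.get("coordinates", [[]])[0]
            cls._check_ring(coords, role or "unknown")
            poly = shape(geom)
            if not poly.is_valid:
                raise GeometryError(f"{role} ring is not simple")
            if role == "paddock":
                paddock = poly
            elif role == "canopy":
                canopies.append(poly)
            else:
                raise SchemaError(f"feature role {role!r} not in {{paddock, canopy}}")
        if paddock is None:
            raise SchemaError("canopy map has no feature with role 'paddock'")
        return cls(paddock, canopies)

    def to_geojson(self, path: str | Path) -> None:
        def feat(poly, role):
            geom = mapping(poly)
            # round coordinates to declared precision for byte-stable output
            geom = json.loads(json.dumps(geom), parse_float=lambda s: round(float(s), 7))
            return {"type": "Feature", "properties": {"role": role}, "geometry": geom}
        fc = {"type": "FeatureCollection",
              "features": [feat(self.paddock, "paddock")]
              + [feat(c, "canopy") for c in self.canopies]}
        with open(path, "w") as fh:
            json.dump(fc, fh, indent=1)
            fh.write("\n")


# ---------------------------------------------------------------------------
# CSV helpers

def _require_columns(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table is missing column(s): {', '.join(missing)}")


def _parse_times(raw: pd.Series, config: PipelineConfig, what: str) -> pd.Series:
    """ISO-8601 to naive local time; bad rows raise with their line number."""
    t = pd.to_datetime(raw, errors="coerce", format="ISO8601", utc=False)
    bad = t.isna() & raw.notna()
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise RowError(f"unparseable timestamp {raw.iloc[i]!r} in {what} table",
                       line=i + 2)  # header is line 1
    if isinstance(t.dtype, pd.DatetimeTZDtype):
        t = t.dt.tz_convert(dt.timezone(dt.timedelta(hours=config.utc_offset_hours)))
        t = t.dt.tz_localize(None)
    return t


def read_behavior_csv(path: str | Path,
                      config: PipelineConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """Behavior-label stream: columns ``animal_id, t, label``.

    Labels outside the six-class ethogram are rejected.
    """
    df = pd.read_csv(path, dtype={"animal_id": str})
    _require_columns(df, ["animal_id", "t", "label"], "behavior")
    df["t"] = _parse_times(df["t"], config, "behavior")
    bad = ~df["label"].isin(BEHAVIOR_CLASSES)
    if bad.any():
        culprit = df.loc[bad, "label"].iloc[0]
        raise SchemaError(
            f"unknown behavior label {culprit!r}; expected one of {BEHAVIOR_CLASSES}")
    return df


def read_gnss_csv(path: str | Path,
                  config: PipelineConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """GNSS fixes: columns ``animal_id, t, lat, lon`` (WGS84 degrees)."""
    df = pd.read_csv(path, dtype={"animal_id": str})
    _require_columns(df, ["animal_id", "t", "lat", "lon"], "gnss")
    df["t"] = _parse_times(df["t"], config, "gnss")
    lat, lon = df["lat"], df["lon"]
    if not (np.isfinite(lat).all() and np.isfinite(lon).all()):
        raise SchemaError("non-finite coordinate in gnss table")
    if ((lat < -90) | (lat > 90)).any() or ((lon < -180) | (lon > 180)).any():
        raise SchemaError("coordinate outside valid degree range in gnss table")
    return df


def read_weather_csv(path: str | Path,
                     config: PipelineConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """Weather records: ``t, ta, rh, ws, rad, rain``.

    Wind speed is stored internally in m/s; if ``config.wind_unit`` declares
    the file's column as km/h it is converted (divided by 3.6) on read.
    """
    df = pd.read_csv(path)
    _require_columns(df, ["t", "ta", "rh", "ws", "rad", "rain"], "weather")
    df["t"] = _parse_times(df["t"], config, "weather")
    if config.wind_unit == "km/h":
        df["ws"] = df["ws"] / 3.6
    if ((df["rh"] < 0) | (df["rh"] > 100)).any():
        raise SchemaError("relative humidity outside [0, 100] in weather table")
    if (df["rad"] < 0).any() or (df["rain"] < 0).any():
        raise SchemaError("negative radiation or rainfall in weather table")
    return df


def read_animals_csv(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Animal table.

    Fixed columns ``animal_id, trial_id, initial_weight, bos_indicus`` plus
    one ``weight_YYYY-MM-DD`` column per Monday weigh date.

    Returns
    -------
    (profiles, weights)
        ``profiles``: one row per animal.  ``weights``: long table
        ``animal_id, date, weight`` (NaN weigh entries dropped).
    """
    df = pd.read_csv(path, dtype={"animal_id": str})
    _require_columns(df, ["animal_id", "trial_id", "initial_weight", "bos_indicus"],
                     "animals")
    if ((df["bos_indicus"] < 0) | (df["bos_indicus"] > 1)).any():
        raise SchemaError("bos_indicus outside [0, 1] in animals table")
    if (df["initial_weight"] <= 0).any():
        raise SchemaError("non-positive initial weight in animals table")
    wcols = [c for c in df.columns if c.startswith("weight_")]
    weights = df.melt(id_vars=["animal_id"], value_vars=wcols,
                      var_name="date", value_name="weight")
    weights["date"] = pd.to_datetime(
        weights["date"].str.removeprefix("weight_")).dt.date
    weights = weights.dropna(subset=["weight"]).sort_values(
        ["animal_id", "date"]).reset_index(drop=True)
    if (weights["weight"] <= 0).any():
        raise SchemaError("non-positive weigh-day weight in animals table")
    profiles = df[["animal_id", "trial_id", "initial_weight", "bos_indicus"]].copy()
    return profiles, weights


# writers ------------------------------------------------------------------

def write_behavior_csv(df: pd.DataFrame, path: str | Path) -> None:
    out = df[["animal_id", "t", "label"]].copy()
    out["t"] = pd.to_datetime(out["t"]).dt.strftime(TIME_FORMAT)
    out.to_csv(path, index=False)


def write_gnss_csv(df: pd.DataFrame, path: str | Path) -> None:
    out = df[["animal_id", "t", "lat", "lon"]].copy()
    out["t"] = pd.to_datetime(out["t"]).dt.strftime(TIME_FORMAT)
    out.to_csv(path, index=False, float_format=COORD_FORMAT)


def write_weather_csv(df: pd.DataFrame, path: str | Path) -> None:
    out = df[["t", "ta", "rh", "ws", "rad", "rain"]].copy()
    out["t"] = pd.to_datetime(out["t"]).dt.strftime(TIME_FORMAT)
    out.to_csv(path, index=False, float_format="%.4f")


def write_animals_csv(profiles: pd.DataFrame, weights: pd.DataFrame,
                      path: str | Path) -> None:
    wide = weights.copy()
    wide["date"] = "weight_" + pd.to_datetime(wide["date"]).dt.strftime("%Y-%m-%d")
    wide = wide.pivot(index="animal_id", columns="date", values="weight")
    out = profiles.set_index("animal_id").join(wide).reset_index()
    out.to_csv(path, index=False, float_format="%.3f")


# ---------------------------------------------------------------------------
# stream bundle + synchronization

def read_streams(paths: dict[str, str | Path],
                 config: PipelineConfig = DEFAULT_CONFIG) -> dict:
    """Read every pipeline input.

    ``paths`` maps ``behavior, gnss, weather, canopy, animals`` to files.
    Returns a dict with keys ``behavior, gnss, weather, canopy, profiles,
    weights``.
    """
    profiles, weights = read_animals_csv(paths["animals"])
    return {
        "behavior": read_behavior_csv(paths["behavior"], config),
        "gnss": read_gnss_csv(paths["gnss"], config),
        "weather": read_weather_csv(paths["weather"], config),
        "canopy": CanopyMap.from_geojson(paths["canopy"]),
        "profiles": profiles,
        "weights": weights,
    }


def synchronize(behavior: pd.DataFrame, positions: pd.DataFrame,
                weather: pd.DataFrame,
                config: PipelineConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """Join the three streams onto a common (animal, hour) grid.

    ``behavior`` is the raw label stream, ``positions`` classified 10-minute
    median positions (with ``in_open``), ``weather`` a 10-minute table which
    may already carry a ``cci`` column (computed here if absent).

    The output has one row per animal x hour for every hour in which *any*
    stream has data (weather counts), i.e. ``|animals| * |hours with >=1
    stream|`` rows.  A stream with no data in an hour contributes explicit
    NaN — never a silent zero.  Animals present in GNSS but absent from the
    behavior stream are retained with missing behavior and a logged warning.
    """
    from .behavior_budget import hourly_budget
    from .climate_index import cci_series

    hb = hourly_budget(behavior, dt_s=config.label_dt_s)

    pos = positions.copy()
    pos["hour"] = pd.to_datetime(pos["interval_start"]).dt.floor("h")
    ph = (
        pos.groupby(["animal_id", "hour"], observed=True)
        .agg(n_intervals=("in_open", "size"), n_open=("in_open", "sum"))
        .reset_index()
    )
    ph["time_in_open"] = ph["n_open"] / 6.0

    w = weather if "cci" in weather.columns else cci_series(weather)
    w = w.copy()
    w["hour"] = pd.to_datetime(w["t"]).dt.floor("h")
    wh = (w.groupby("hour")[["ta", "rh", "ws", "rad", "cci"]].mean().reset_index())

    behav_animals = set(hb["animal_id"].unique()) if len(hb) else set()
    gnss_animals = set(ph["animal_id"].unique()) if len(ph) else set()
    only_gnss = gnss_animals - behav_animals
    if only_gnss:
        logger.warning(
            "animal(s) %s present in GNSS but absent from behavior stream",
            sorted(only_gnss))
    animals = sorted(behav_animals | gnss_animals)

    hours = pd.Index(sorted(set(hb["hour"]) | set(ph["hour"]) | set(wh["hour"])),
                     name="hour")
    grid = pd.MultiIndex.from_product([animals, hours],
                                      names=["animal_id", "hour"]).to_frame(index=False)
    out = (
        grid.merge(hb, on=["animal_id", "hour"], how="left")
        .merge(ph[["animal_id", "hour", "n_intervals", "time_in_open"]],
               on=["animal_id", "hour"], how="left")
        .merge(wh, on="hour", how="left")
    )
    return out
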