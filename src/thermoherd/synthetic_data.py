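"""Synthetic multimodal trial generator.

Emulates the five input streams of a two-trial grazing study — 5-second
collar behavior labels, high-rate GNSS fixes, 10-minute weather records, a
paddock/canopy map, and an animal table with weekly Monday weights and Bos
indicus proportions — with *planted*, parameterized CCI-dependent effects:

* shade affinity: the probability that an animal's 10-minute attractor is a
  tree canopy during daytime follows a logistic curve in the day's maximum
  CCI, so hotter days mean less time in the open;
* grazing shift: hours of grazing move from day to night linearly in the
  day's maximum CCI;
* daytime resting grows linearly in the day's maximum CCI;
* a small positive Bos indicus x CCI interaction on walking time;
* weekly weight gain responds weakly to grazing hours and travel distance.

Effects are planted at the daily-budget level, so their theoretical signs
and approximate magnitudes are known in closed form and the whole pipeline
can be tested for parameter recovery.  Everything is a pure function of
:class:`SimConfig` (seeded substreams per stream), so identical
configurations give byte-identical fixtures.
"""

from __future__ import annotations

import datetime as dt
import json
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .climate_index import cci_series, daily_max_cci
from .config import BEHAVIOR_CLASSES, PipelineConfig, TrialWindow
from .io_formats import (CanopyMap, write_animals_csv, write_behavior_csv,
                         write_gnss_csv, write_weather_csv)

__all__ = ["SimConfig", "build_paddock", "generate_weather", "generate_herd",
           "generate_behaviors", "generate_tracks", "generate_animals",
           "generate_all", "write_fixture"]

_M_PER_DEG_LAT = 111_320.0

# Stream indices for seed derivation (SeedSequence(seed, stream)).
_STREAMS = {"weather": 0, "herd": 1, "behavior": 2, "tracks": 3, "weights": 4}


class SimConfig(BaseModel):
    """Study-condition parameters of the synthetic trials.

    Defaults reproduce the emulated study design: two 28-day late-spring
    trials of 60 animals on a ~3 ha paddock, 5-s behavior labels, 1-Hz GNSS
    (600 fixes per 10-minute interval), weather tuned so daily maximum CCI
    spans roughly 36-52, behavior budgets centered on the reported weekly
    medians, initial weights with median 259 kg (spread 39 kg) gaining about
    25 kg over four weeks, and Bos indicus proportions uniform on
    [0.47, 0.95].  ``label_dt_s`` and ``fixes_per_interval`` are sensor
    *cadences*: coarsening them changes quantization only, never the planted
    effects, and is how large test batteries keep runtimes reasonable.
    """

    seed: int = 0
    n_animals: int = 60
    trial_windows: list[TrialWindow] = Field(default_factory=lambda: [
        TrialWindow(trial_id="trial1", start=dt.date(2022, 11, 21)),
        TrialWindow(trial_id="trial2", start=dt.date(2023, 11, 20)),
    ])

    # sensor cadences
    label_dt_s: float = 5.0
    fixes_per_interval: int = 600
    gnss_noise_m: float = 3.0

    # paddock (~3 ha) and canopies
    lat0: float = -27.55
    lon0: float = 152.33
    paddock_w_m: float = 200.0
    paddock_h_m: float = 150.0
    n_canopies: int = 6
    canopy_size_m: float = 26.0
    canopy_margin_m: float = 5.0

    # weather model
    ta_mean: float = 26.8
    ta_amp: float = 6.8
    ta_ar_phi: float = 0.65
    ta_ar_sd: float = 1.7
    trial2_ta_offset: float = 1.0
    rh_base: float = 62.0
    rh_slope: float = -1.7
    rad_peak: float = 960.0
    ws_log_mean: float = 0.26  # ln(1.3 m/s)
    ws_log_sd: float = 0.40
    rain_day_prob: float = 0.12

    # planted effects
    shade_affinity_slope: float = 0.45   # logit canopy per CCI unit (daytime)
    shade_cci_midpoint: float = 47.0
    night_canopy_prob: float = 0.25
    graze_shift_slope: float = 0.12      # h moved day->night per CCI unit
    rest_gain_slope: float = 0.05        # h added to daytime resting per unit
    walk_bos_cci_slope: float = 0.05     # h per (bos dev x CCI unit)
    cci_midpoint: float = 43.0

    # behavior budget baselines: class -> (median daily hours, day fraction)
    behavior_base: dict[str, tuple[float, float]] = Field(default_factory=lambda: {
        "grazing": (7.0, 0.72), "ruminating": (2.9, 0.45),
        "resting": (2.0, 0.55), "walking": (0.7, 0.70),
        "drinking": (0.08, 0.90), "other": (0.15, 0.50),
    })
    animal_effect_sd: float = 0.08   # lognormal sd of per-animal class levels
    day_noise_sd: float = 0.10       # lognormal sd of per-animal-day totals

    # movement model
    redraw_prob: float = 0.22        # per-interval attractor redraw
    wander_sd_m: float = 2.0

    # animal table
    initial_weight_median: float = 259.0
    initial_weight_spread: float = 39.0
    bos_indicus_range: tuple[float, float] = (0.47, 0.95)
    base_weekly_gain: float = 6.25
    gain_graze_coef: float = 1.2     # kg/week per extra mean daily grazing h
    gain_dist_coef: float = -0.8     # kg/week per extra mean daily km
    gain_noise_sd: float = 2.5

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(
            entropy=self.seed, spawn_key=(_STREAMS[stream],)))

    def pipeline_config(self) -> PipelineConfig:
        return PipelineConfig(label_dt_s=self.label_dt_s,
                              trial_windows=self.trial_windows)


# ---------------------------------------------------------------------------
# geometry

def _to_latlon(cfg: SimConfig, x_m, y_m):
    lat = cfg.lat0 + np.asarray(y_m) / _M_PER_DEG_LAT
    lon = cfg.lon0 + np.asarray(x_m) / (_M_PER_DEG_LAT * np.cos(np.radians(cfg.lat0)))
    return lat, lon


# canopy centers as fixed fractions of the paddock (layout is part of the
# study conditions, not of the random draw)
_CANOPY_FRACS = [(0.20, 0.25), (0.50, 0.18), (0.80, 0.30),
                 (0.28, 0.72), (0.62, 0.78), (0.86, 0.62)]


def _canopy_centers(cfg: SimConfig) -> np.ndarray:
    fr = np.asarray(_CANOPY_FRACS[: cfg.n_canopies])
    return fr * np.array([cfg.paddock_w_m, cfg.paddock_h_m])


def build_paddock(cfg: SimConfig) -> CanopyMap:
    """Rectangular paddock with square canopy polygons (lat/lon space)."""
    w, h = cfg.paddock_w_m, cfg.paddock_h_m
    corners = [(0, 0), (w, 0), (w, h), (0, h), (0, 0)]
    lat, lon = _to_latlon(cfg, [c[0] for c in corners], [c[1] for c in corners])
    paddock = list(zip(lat, lon))
    canopies = []
    s = cfg.canopy_size_m / 2.0
    for cx, cy in _canopy_centers(cfg):
        sq = [(cx - s, cy - s), (cx + s, cy - s), (cx + s, cy + s),
              (cx - s, cy + s), (cx - s, cy - s)]
        clat, clon = _to_latlon(cfg, [p[0] for p in sq], [p[1] for p in sq])
        canopies.append(list(zip(clat, clon)))
    return CanopyMap.from_latlon(paddock, canopies)


# ---------------------------------------------------------------------------
# weather

def generate_weather(cfg: SimConfig) -> pd.DataFrame:
    """10-minute weather for both trial windows.

    Air temperature is a mid-afternoon-peaked sinusoid on an AR(1)
    day-to-day drift; humidity is anti-correlated with the temperature
    anomaly; radiation is a daylight half-sine scaled by a per-day cloud
    factor (exactly zero at night); wind is log-normal with a mild daytime
    boost; rain is sparse.  Trial 2 rides on a small warm offset.
    """
    rng = cfg.rng("weather")
    frames = []
    for ti, win in enumerate(cfg.trial_windows):
        n_days = win.n_days
        offset = cfg.trial2_ta_offset * ti
        drift = np.empty(n_days)
        ar = 0.0
        sd_innov = cfg.ta_ar_sd
        for d in range(n_days):
            ar = cfg.ta_ar_phi * ar + rng.normal(0.0, sd_innov)
            drift[d] = ar
        amp = cfg.ta_amp * (1.0 + rng.normal(0.0, 0.08, n_days))
        cloud = np.clip(rng.normal(0.90, 0.12, n_days), 0.45, 1.05)
        rain_day = rng.random(n_days) < cfg.rain_day_prob

        slots = np.arange(n_days * 144)
        day_idx = slots // 144
        hod = (slots % 144) / 6.0  # hour of day, 10-min resolution
        ta = (cfg.ta_mean + offset + drift[day_idx]
              + amp[day_idx] * np.cos(2 * np.pi * (hod - 15.0) / 24.0)
              + rng.normal(0.0, 0.4, len(slots)))
        rh = np.clip(cfg.rh_base + cfg.rh_slope * (ta - cfg.ta_mean)
                     + rng.normal(0.0, 3.0, len(slots)), 20.0, 98.0)
        daylight = (hod >= 5.5) & (hod < 18.5)
        rad = np.where(
            daylight,
            cfg.rad_peak * cloud[day_idx]
            * np.sin(np.pi * np.clip((hod - 5.5) / 13.0, 0.0, 1.0))
            * np.clip(1.0 + rng.normal(0.0, 0.06, len(slots)), 0.0, None),
            0.0,
        )
        rad = np.clip(rad, 0.0, None)
        diurnal_ws = 1.0 + 0.25 * np.sin(np.pi * np.clip((hod - 5.0) / 14.0, 0, 1))
        ws = np.clip(np.exp(rng.normal(cfg.ws_log_mean, cfg.ws_log_sd, len(slots)))
                     * diurnal_ws, 0.2, 12.0)
        rain = np.zeros(len(slots))
        wet = rain_day[day_idx] & (rng.random(len(slots)) < 0.06)
        rain[wet] = rng.exponential(1.2, int(wet.sum()))

        t0 = pd.Timestamp(win.start)
        t = t0 + pd.to_timedelta(slots * 10, unit="min")
        frames.append(pd.DataFrame({
            "t": t, "ta": ta, "rh": rh, "ws": ws, "rad": rad, "rain": rain}))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# herd

def generate_herd(cfg: SimConfig) -> pd.DataFrame:
    """Animal profiles: ids, trial, Bos indicus proportion, initial weight."""
    rng = cfg.rng("herd")
    rows = []
    for win in cfg.trial_windows:
        tag = win.trial_id[-1]
        bos = rng.uniform(*cfg.bos_indicus_range, cfg.n_animals)
        iw = np.clip(rng.normal(cfg.initial_weight_median,
                                cfg.initial_weight_spread, cfg.n_animals),
                     160.0, 400.0)
        for i in range(cfg.n_animals):
            rows.append({"animal_id": f"T{tag}A{i + 1:02d}",
                         "trial_id": win.trial_id,
                         "initial_weight": round(float(iw[i]), 3),
                         "bos_indicus": round(float(bos[i]), 4)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# behavior

# diurnal allocation templates (relative weight per clock hour, one per class);
# grazing peaks after dawn and before dusk, rumination and resting fill the
# night and midday lulls.
def _hour_templates() -> dict[str, np.ndarray]:
    h = np.arange(24)
    tpl = {}
    tpl["grazing"] = 0.3 + np.exp(-0.5 * ((h - 7.5) / 2.0) ** 2) \
        + np.exp(-0.5 * ((h - 16.5) / 2.0) ** 2)
    tpl["ruminating"] = 0.6 + 0.6 * np.exp(-0.5 * ((h - 12.5) / 2.5) ** 2) \
        + 0.5 * np.exp(-0.5 * ((h - 1.0) / 3.0) ** 2)
    tpl["resting"] = 0.5 + 0.8 * np.exp(-0.5 * ((h - 13.0) / 2.5) ** 2) \
        + 0.6 * np.exp(-0.5 * ((h - 2.0) / 3.0) ** 2)
    tpl["walking"] = 0.4 + 0.6 * np.exp(-0.5 * ((h - 8.0) / 3.0) ** 2) \
        + 0.6 * np.exp(-0.5 * ((h - 16.0) / 3.0) ** 2)
    tpl["drinking"] = 0.2 + np.exp(-0.5 * ((h - 11.0) / 3.0) ** 2)
    tpl["other"] = np.ones(24)
    return tpl


def _trial_dates(win: TrialWindow) -> list[dt.date]:
    return [win.start + dt.timedelta(days=d) for d in range(win.n_days)]


def _fit_capacity(block: np.ndarray, max_iter: int = 8) -> np.ndarray:
    """Cap each hour's class total at 1 h, pushing overflow to spare hours.

    ``block`` has shape (..., C, H).  Daypart class totals are preserved as
    long as the daypart has spare capacity (always true for realistic
    budgets); any residual overflow in a saturated daypart is dropped.
    """
    out = block.copy()
    for _ in range(max_iter):
        tot = out.sum(-2, keepdims=True)                    # (..., 1, H)
        if not (tot > 1.0 + 1e-9).any():
            break
        scale = np.minimum(1.0, 1.0 / np.maximum(tot, 1e-12))
        clipped = out * scale
        overflow = (out - clipped).sum(-1, keepdims=True)   # (..., C, 1)
        spare = np.clip(1.0 - clipped.sum(-2, keepdims=True), 0.0, None)
        spare_tot = spare.sum(-1, keepdims=True)
        weights = np.where(spare_tot > 1e-12, spare / np.maximum(spare_tot, 1e-12), 0.0)
        out = clipped + overflow * weights
    return out


def generate_behaviors(cfg: SimConfig, daily_cci: pd.DataFrame,
                       herd: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Behavior-label stream plus the planted daily targets.

    Per animal-day, class totals are drawn around the baseline medians with
    multiplicative animal- and day-level noise, the CCI-dependent shifts are
    applied to the day/night split, and the daypart totals are spread over
    clock hours by diurnal templates before being quantized into
    ``label_dt_s``-second labels.

    Returns ``(records, truth)`` where ``truth`` holds one row per
    animal-date with the planted day/night hour targets for every class.
    """
    rng = cfg.rng("behavior")
    config = cfg.pipeline_config()
    cci_by_date = dict(zip(daily_cci["date"], daily_cci["max_cci"]))
    tpl = _hour_templates()
    day_hours = np.arange(config.day_start, config.day_end)
    night_hours = np.array([h for h in range(24) if h not in day_hours])
    dt_s = cfg.label_dt_s
    cap_per_hour = int(round(3600 / dt_s))
    classes = list(BEHAVIOR_CLASSES)

    rec_frames = []
    truth_rows = []
    for win in cfg.trial_windows:
        sub = herd[herd["trial_id"] == win.trial_id].reset_index(drop=True)
        A = len(sub)
        dates = _trial_dates(win)
        D = len(dates)
        dc = np.array([cci_by_date[d] - cfg.cci_midpoint for d in dates])
        bos_dev = sub["bos_indicus"].to_numpy() - np.mean(cfg.bos_indicus_range)

        # per-animal and per-animal-day multiplicative levels
        animal_fx = np.exp(rng.normal(0.0, cfg.animal_effect_sd, (A, 1, len(classes))))
        day_fx = np.exp(rng.normal(0.0, cfg.day_noise_sd, (A, D, len(classes))))

        base = np.array([cfg.behavior_base[c][0] for c in classes])
        dayfrac = np.array([cfg.behavior_base[c][1] for c in classes])
        totals = base[None, None, :] * animal_fx * day_fx      # (A, D, C)
        iw = classes.index("walking")
        totals[:, :, iw] = np.clip(
            totals[:, :, iw] + cfg.walk_bos_cci_slope * bos_dev[:, None] * dc[None, :],
            0.05, None)

        day_h = totals * dayfrac[None, None, :]
        night_h = totals - day_h
        ig, ir = classes.index("grazing"), classes.index("resting")
        shift = cfg.graze_shift_slope * dc                      # (D,)
        day_h[:, :, ig] = np.clip(day_h[:, :, ig] - shift[None, :], 0.1, None)
        night_h[:, :, ig] = np.clip(night_h[:, :, ig] + shift[None, :], 0.05, None)
        day_h[:, :, ir] = np.clip(
            day_h[:, :, ir] + cfg.rest_gain_slope * dc[None, :], 0.05, None)

        # spread daypart totals over clock hours with jittered templates
        w_day = np.stack([tpl[c][day_hours] for c in classes])       # (C, 13)
        w_night = np.stack([tpl[c][night_hours] for c in classes])   # (C, 11)
        jd = rng.gamma(8.0, 1 / 8.0, (A, D, len(classes), len(day_hours)))
        jn = rng.gamma(8.0, 1 / 8.0, (A, D, len(classes), len(night_hours)))
        wd = w_day[None, None] * jd
        wn = w_night[None, None] * jn
        wd /= wd.sum(-1, keepdims=True)
        wn /= wn.sum(-1, keepdims=True)
        hours24 = np.zeros((A, D, len(classes), 24))
        hours24[:, :, :, day_hours] = _fit_capacity(day_h[..., None] * wd)
        hours24[:, :, :, night_hours] = _fit_capacity(night_h[..., None] * wn)

        counts = np.rint(hours24 * cap_per_hour).astype(np.int64)
        excess = counts.sum(2) - cap_per_hour                    # (A, D, 24)
        if (excess > 0).any():
            # drop surplus labels from the largest class of the hour
            ai, di, hi = np.nonzero(excess > 0)
            big = counts[ai, di, :, hi].argmax(-1)
            counts[ai, di, big, hi] -= excess[ai, di, hi]

        # emit the label stream
        flat = np.moveaxis(counts, 2, 3).reshape(-1)  # (A, D, 24, C) order
        ncell = flat.size
        cell = np.repeat(np.arange(ncell), flat)
        within = np.arange(flat.sum()) - np.repeat(
            np.concatenate(([0], np.cumsum(flat)[:-1])), flat)
        c_idx = cell % len(classes)
        h_idx = (cell // len(classes)) % 24
        d_idx = (cell // (len(classes) * 24)) % D
        a_idx = cell // (len(classes) * 24 * D)
        # slot offset of each class within its hour (exclusive cumsum)
        perhour = np.moveaxis(counts, 2, 3).reshape(-1, len(classes))
        offs = np.cumsum(perhour, axis=1) - perhour
        slot = offs.reshape(-1)[cell] + within
        date0 = pd.Timestamp(win.start)
        t = (date0.value // 10**9
             + d_idx * 86400 + h_idx * 3600
             + (slot * dt_s).astype(np.int64))
        ids = sub["animal_id"].to_numpy()
        rec_frames.append(pd.DataFrame({
            "animal_id": ids[a_idx],
            "t": pd.to_datetime(t, unit="s"),
            "label": pd.Categorical.from_codes(c_idx, categories=classes),
        }))

        for a in range(A):
            for d in range(D):
                row = {"animal_id": ids[a], "date": dates[d],
                       "max_cci": cci_by_date[dates[d]]}
                for ci, c in enumerate(classes):
                    row[f"day_{c}"] = day_h[a, d, ci]
                    row[f"night_{c}"] = night_h[a, d, ci]
                truth_rows.append(row)

    records = pd.concat(rec_frames, ignore_index=True)
    records["label"] = records["label"].astype(str)
    records = records.sort_values(["animal_id", "t"], kind="mergesort").reset_index(drop=True)
    return records, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# tracks

def generate_tracks(cfg: SimConfig, daily_cci: pd.DataFrame,
                    herd: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """GNSS fix stream plus planted occupancy/distance truth.

    Each animal follows a persistent-attractor walk on the 10-minute grid:
    with probability ``redraw_prob`` per interval the attractor is redrawn —
    a canopy with probability logistic(shade_affinity_slope x (day's max CCI
    - midpoint)) during daytime, ``night_canopy_prob`` at night — otherwise
    the animal wanders a couple of metres around the current attractor.
    Fixes are the interval position plus isotropic receiver noise, clipped
    to the paddock.
    """
    rng = cfg.rng("tracks")
    config = cfg.pipeline_config()
    cci_by_date = dict(zip(daily_cci["date"], daily_cci["max_cci"]))
    centers = _canopy_centers(cfg)
    half = cfg.canopy_size_m / 2.0 - cfg.canopy_margin_m
    W, H = cfg.paddock_w_m, cfg.paddock_h_m

    fix_frames = []
    truth_frames = []
    for win in cfg.trial_windows:
        sub = herd[herd["trial_id"] == win.trial_id].reset_index(drop=True)
        A = len(sub)
        dates = _trial_dates(win)
        D = len(dates)
        n_iv = D * 144
        hod = (np.arange(n_iv) % 144) / 6.0
        is_day = (hod >= config.day_start) & (hod < config.day_end)
        dcci = np.array([cci_by_date[d] for d in dates])
        p_day = 1.0 / (1.0 + np.exp(-cfg.shade_affinity_slope
                                    * (dcci - cfg.shade_cci_midpoint)))
        p_day = np.clip(p_day, 0.01, 0.99)
        p_canopy = np.where(is_day, p_day[np.arange(n_iv) // 144],
                            cfg.night_canopy_prob)

        redraw = rng.random((A, n_iv)) < cfg.redraw_prob
        redraw[:, 0] = True
        to_canopy = rng.random((A, n_iv)) < p_canopy[None, :]
        which = rng.integers(0, len(centers), (A, n_iv))

        # attractor coordinates for every potential redraw
        cx = centers[which, 0] + rng.uniform(-half, half, (A, n_iv))
        cy = centers[which, 1] + rng.uniform(-half, half, (A, n_iv))
        ox = rng.uniform(1.0, W - 1.0, (A, n_iv))
        oy = rng.uniform(1.0, H - 1.0, (A, n_iv))
        # open attractors must clear the canopy squares (+3 m guard so the
        # wander noise cannot drift them under a canopy): rejection redraw
        guard = cfg.canopy_size_m / 2.0 + 3.0
        for _ in range(6):
            bad = np.zeros(ox.shape, dtype=bool)
            for kx, ky in centers:
                bad |= (np.abs(ox - kx) < guard) & (np.abs(oy - ky) < guard)
            if not bad.any():
                break
            n_bad = int(bad.sum())
            ox[bad] = rng.uniform(1.0, W - 1.0, n_bad)
            oy[bad] = rng.uniform(1.0, H - 1.0, n_bad)
        tx = np.where(to_canopy, cx, ox)
        ty = np.where(to_canopy, cy, oy)

        idx = np.where(redraw, np.arange(n_iv)[None, :], -1)
        ff = np.maximum.accumulate(idx, axis=1)
        tx = np.take_along_axis(tx, ff, axis=1)
        ty = np.take_along_axis(ty, ff, axis=1)
        in_canopy = np.take_along_axis(to_canopy, ff, axis=1)

        px = np.clip(tx + rng.normal(0.0, cfg.wander_sd_m, (A, n_iv)), 0.5, W - 0.5)
        py = np.clip(ty + rng.normal(0.0, cfg.wander_sd_m, (A, n_iv)), 0.5, H - 0.5)

        # planted truth: per animal-date daytime open intervals and distance
        step = np.hypot(np.diff(px, axis=1), np.diff(py, axis=1)) / 1000.0
        same_date = (np.arange(1, n_iv) // 144) == (np.arange(n_iv - 1) // 144)
        step = step * same_date[None, :]
        day_of_iv = np.arange(n_iv) // 144
        dist_km = np.zeros((A, D))
        for d in range(D):
            m = (day_of_iv[1:] == d) & same_date
            dist_km[:, d] = step[:, m].sum(axis=1)
        open_day = (~in_canopy) & is_day[None, :]
        open_h = np.zeros((A, D))
        for d in range(D):
            m = day_of_iv == d
            open_h[:, d] = open_day[:, m].sum(axis=1) / 6.0
        ids = sub["animal_id"].to_numpy()
        truth_frames.append(pd.DataFrame({
            "animal_id": np.repeat(ids, D),
            "date": np.tile(dates, A),
            "open_hours_day": open_h.reshape(-1),
            "distance_km": dist_km.reshape(-1),
        }))

        # fixes
        F = cfg.fixes_per_interval
        stride = 600.0 / F
        fx = (px[:, :, None] + rng.normal(0.0, cfg.gnss_noise_m, (A, n_iv, F)))
        fy = (py[:, :, None] + rng.normal(0.0, cfg.gnss_noise_m, (A, n_iv, F)))
        fx = np.clip(fx, 0.2, W - 0.2)
        fy = np.clip(fy, 0.2, H - 0.2)
        lat, lon = _to_latlon(cfg, fx.reshape(-1), fy.reshape(-1))
        t0 = pd.Timestamp(win.start).value // 10**9
        iv_sec = np.arange(n_iv) * 600
        t = (t0 + iv_sec[None, :, None]
             + (np.arange(F) * stride).astype(np.int64)[None, None, :])
        fix_frames.append(pd.DataFrame({
            "animal_id": np.repeat(ids, n_iv * F),
            "t": pd.to_datetime(np.broadcast_to(t, (A, n_iv, F)).reshape(-1), unit="s"),
            "lat": lat, "lon": lon,
        }))

    fixes = pd.concat(fix_frames, ignore_index=True)
    truth = pd.concat(truth_frames, ignore_index=True)
    return fixes, truth


# ---------------------------------------------------------------------------
# weights

def generate_animals(cfg: SimConfig, herd: pd.DataFrame,
                     behavior_truth: pd.DataFrame,
                     track_truth: pd.DataFrame) -> pd.DataFrame:
    """Weekly Monday weights from the planted daily budgets.

    Weekly gain = base + gain_graze_coef x (mean daily grazing - baseline)
    + gain_dist_coef x (mean daily km - typical) + noise, cumulated from the
    initial weight at the trial-start Monday through four weekly weigh days.
    Returns the long weights table ``animal_id, date, weight``.
    """
    rng = cfg.rng("weights")
    bt = behavior_truth.copy()
    bt["grazing_total"] = bt["day_grazing"] + bt["night_grazing"]
    daily = bt[["animal_id", "date", "grazing_total"]].merge(
        track_truth[["animal_id", "date", "distance_km"]],
        on=["animal_id", "date"], how="left")
    rows = []
    for win in cfg.trial_windows:
        sub = herd[herd["trial_id"] == win.trial_id]
        weigh_dates = [win.start + dt.timedelta(days=7 * k)
                       for k in range(win.n_days // 7 + 1)]
        for _, animal in sub.iterrows():
            ad = daily[daily["animal_id"] == animal["animal_id"]]
            w = float(animal["initial_weight"])
            rows.append({"animal_id": animal["animal_id"],
                         "date": weigh_dates[0], "weight": round(w, 3)})
            for k in range(len(weigh_dates) - 1):
                wk = ad[(ad["date"] >= weigh_dates[k])
                        & (ad["date"] < weigh_dates[k + 1])]
                gain = (cfg.base_weekly_gain
                        + cfg.gain_graze_coef
                        * (wk["grazing_total"].mean() - cfg.behavior_base["grazing"][0])
                        + cfg.gain_dist_coef * (wk["distance_km"].mean() - 3.2)
                        + rng.normal(0.0, cfg.gain_noise_sd))
                w += gain
                rows.append({"animal_id": animal["animal_id"],
                             "date": weigh_dates[k + 1], "weight": round(w, 3)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# orchestration

def generate_all(cfg: SimConfig) -> dict:
    """Generate every stream in memory.

    Returns a dict with keys ``weather, cci, daily_cci, canopy, profiles,
    behavior, gnss, weights, truth`` (truth bundles the planted daily
    targets and the effect parameters).
    """
    weather = generate_weather(cfg)
    cci = cci_series(weather)
    daily = daily_max_cci(cci)
    herd = generate_herd(cfg)
    behavior, behavior_truth = generate_behaviors(cfg, daily, herd)
    gnss, track_truth = generate_tracks(cfg, daily, herd)
    weights = generate_animals(cfg, herd, behavior_truth, track_truth)
    truth = {
        "planted": {
            "shade_affinity_slope": cfg.shade_affinity_slope,
            "shade_cci_midpoint": cfg.shade_cci_midpoint,
            "graze_shift_slope": cfg.graze_shift_slope,
            "rest_gain_slope": cfg.rest_gain_slope,
            "walk_bos_cci_slope": cfg.walk_bos_cci_slope,
            "cci_midpoint": cfg.cci_midpoint,
            "expected_signs": {
                "r_cci_time_in_open_day": -1 if cfg.shade_affinity_slope > 0 else 0,
                "r_cci_grazing_day": -1 if cfg.graze_shift_slope > 0 else 0,
                "r_cci_grazing_night": 1 if cfg.graze_shift_slope > 0 else 0,
                "r_cci_resting_day": 1 if cfg.rest_gain_slope > 0 else 0,
            },
        },
        "daily_cci": {str(d): float(v)
                      for d, v in zip(daily["date"], daily["max_cci"])},
        "behavior_daily": behavior_truth,
        "track_daily": track_truth,
    }
    return {"weather": weather, "cci": cci, "daily_cci": daily,
            "canopy": build_paddock(cfg), "profiles": herd,
            "behavior": behavior, "gnss": gnss, "weights": weights,
            "truth": truth}


def write_fixture(cfg: SimConfig, out_dir: str | Path, *, force: bool = False) -> dict:
    """Write the five input files plus the ground-truth JSON.

    Same config (including seed) -> byte-identical files.  Refuses to
    overwrite an existing fixture unless ``force``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {name: out / fname for name, fname in [
        ("behavior", "behavior.csv"), ("gnss", "gnss.csv"),
        ("weather", "weather.csv"), ("canopy", "canopy.geojson"),
        ("animals", "animals.csv"), ("truth", "truth.json")]}
    clashes = [p for p in paths.values() if p.exists()]
    if clashes and not force:
        raise FileExistsError(
            f"fixture files already present (e.g. {clashes[0]}); use force=True")
    data = generate_all(cfg)
    write_behavior_csv(data["behavior"], paths["behavior"])
    write_gnss_csv(data["gnss"], paths["gnss"])
    write_weather_csv(data["weather"], paths["weather"])
    data["canopy"].to_geojson(paths["canopy"])
    write_animals_csv(data["profiles"], data["weights"], paths["animals"])
    truth = data["truth"]
    payload = {
        "planted": truth["planted"],
        "daily_cci": truth["daily_cci"],
        "behavior_daily": truth["behavior_daily"].to_dict(orient="list"),
        "track_daily": truth["track_daily"].to_dict(orient="list"),
    }
    payload["behavior_daily"]["date"] = [str(d) for d in payload["behavior_daily"]["date"]]
    payload["track_daily"]["date"] = [str(d) for d in payload["track_daily"]["date"]]
    with open(paths["truth"], "w") as fh:
        json.dump(payload, fh)
        fh.write("\n")
    return {"paths": paths, "data": data}
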