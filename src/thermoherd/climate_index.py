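"""Comprehensive Climate Index (CCI).

The CCI expresses the combined thermal load of air temperature, humidity,
wind and solar radiation as a single apparent temperature,

    CCI = Ta + RH_adj(Ta, RH) + WS_adj(WS) + RAD_adj(Ta, RAD),

covering both cold- and heat-stress ranges.  The three adjustment equations
are those published by Mader, Johnson & Gaughan (2010, J. Anim. Sci.
88:2153-2165); every coefficient is collected in :data:`MADER_2010` rather
than scattered through the code so the index stays auditable and swappable.

Sign behaviour worth knowing: the humidity adjustment vanishes at RH = 30 %
and, at warm temperatures, grows with RH; the wind adjustment is positive in
still air and decreases monotonically with wind speed (wind cools); the
radiation adjustment at zero radiation reduces to a pure function of Ta.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import DomainError

__all__ = ["MADER_2010", "compute_cci", "cci_series", "daily_max_cci"]

# Coefficients of the Mader et al. (2010) CCI adjustment equations.
# RH_adj = exp(e1*RH + e2*Ta*RH) * (q2*Ta^2 + q1*Ta + q0) * (RH - rh0)
# WS_adj = ws_num / exp((1/(a*WS + b))^(p * (c + d*WS^2.5 - log_base(a*WS + g)))) - k*WS^2 + m
# RAD_adj = r1*RAD + r2*RAD*Ta + r3*Ta^2*sqrt(RAD) + r4*Ta + r5
MADER_2010 = {
    "version": "Mader-Johnson-Gaughan-2010",
    "rh": {"e1": 0.00182, "e2": 1.8e-5, "q2": 0.000054, "q1": 0.00192,
           "q0": -0.0246, "rh0": 30.0},
    "ws": {"a": 2.26, "b": 0.23, "g": 0.33, "p": 0.45, "c": 2.9,
           "d": 1.14e-6, "log_base": 0.3, "num": -6.56, "k": 0.00566,
           "m": 3.33},
    "rad": {"r1": 0.0076, "r2": -0.00002, "r3": 0.00005, "r4": 0.1,
            "r5": -2.0},
    # Validity envelope of the published equations (approximate; the source
    # develops them for ambient livestock conditions).
    "envelope": {"ta": (-30.0, 45.0), "rh": (0.0, 100.0),
                 "ws": (0.0, 30.0), "rad": (0.0, 1500.0)},
}


def _rh_adjustment(ta, rh):
    c = MADER_2010["rh"]
    return (
        np.exp(c["e1"] * rh + c["e2"] * ta * rh)
        * (c["q2"] * ta**2 + c["q1"] * ta + c["q0"])
        * (rh - c["rh0"])
    )


def _ws_adjustment(ws):
    c = MADER_2010["ws"]
    base = c["a"] * ws + c["b"]
    expo = c["p"] * (
        c["c"] + c["d"] * ws**2.5
        - np.log(c["a"] * ws + c["g"]) / np.log(c["log_base"])
    )
    return c["num"] / np.exp((1.0 / base) ** expo) - c["k"] * ws**2 + c["m"]


def _rad_adjustment(ta, rad):
    c = MADER_2010["rad"]
    return (
        c["r1"] * rad + c["r2"] * rad * ta
        + c["r3"] * ta**2 * np.sqrt(rad) + c["r4"] * ta + c["r5"]
    )


def compute_cci(ta, rh, ws, rad, *, envelope: str = "warn"):
    """Compute the CCI and its additive decomposition.

    Parameters
    ----------
    ta, rh, ws, rad
        Air temperature (degC), relative humidity (%), wind speed (m/s) and
        solar radiation (W/m2); scalars or array-likes of equal shape.
    envelope
        ``warn`` computes outside the published validity envelope with a
        warning, ``clamp`` clips inputs to the envelope, ``raise`` refuses.

    Returns
    -------
    dict with keys ``cci``, ``rh_adj``, ``ws_adj``, ``rad_adj`` (ndarrays or
    scalars matching the input shape).  ``cci`` equals
    ``ta + rh_adj + ws_adj + rad_adj`` exactly.

    Raises
    ------
    DomainError
        If RH is outside [0, 100] or radiation is negative (hard physical
        bounds, regardless of ``envelope``).
    """
    scalar = all(np.isscalar(v) for v in (ta, rh, ws, rad))
    ta = np.asarray(ta, dtype=float)
    rh = np.asarray(rh, dtype=float)
    ws = np.asarray(ws, dtype=float)
    rad = np.asarray(rad, dtype=float)

    if np.any((rh < 0.0) | (rh > 100.0)):
        raise DomainError("relative humidity outside [0, 100] %")
    if np.any(rad < 0.0):
        raise DomainError("negative solar radiation")
    if np.any(ws < 0.0):
        raise DomainError("negative wind speed")

    env = MADER_2010["envelope"]
    out_of_env = (ta < env["ta"][0]) | (ta > env["ta"][1]) | (ws > env["ws"][1]) | (rad > env["rad"][1])
    if np.any(out_of_env):
        if envelope == "raise":
            raise DomainError("input outside the CCI validity envelope")
        if envelope == "clamp":
            ta = np.clip(ta, *env["ta"])
            ws = np.clip(ws, *env["ws"])
            rad = np.clip(rad, *env["rad"])
        else:
            warnings.warn(
                f"{int(np.sum(out_of_env))} record(s) outside the CCI "
                "validity envelope; computed anyway", stacklevel=2)

    rh_adj = _rh_adjustment(ta, rh)
    ws_adj = _ws_adjustment(ws)
    rad_adj = _rad_adjustment(ta, rad)
    cci = ta + rh_adj + ws_adj + rad_adj
    out = {"cci": cci, "rh_adj": rh_adj, "ws_adj": ws_adj, "rad_adj": rad_adj}
    if scalar:
        out = {k: float(v) for k, v in out.items()}
    return out


def cci_series(weather: pd.DataFrame, *, envelope: str = "warn") -> pd.DataFrame:
    """Attach the CCI decomposition to a 10-minute weather table.

    ``weather`` needs columns ``t, ta, rh, ws, rad`` (wind in m/s).  Returns
    a copy with ``rh_adj, ws_adj, rad_adj, cci`` appended.
    """
    parts = compute_cci(
        weather["ta"].to_numpy(), weather["rh"].to_numpy(),
        weather["ws"].to_numpy(), weather["rad"].to_numpy(),
        envelope=envelope,
    )
    out = weather.copy()
    for k in ("rh_adj", "ws_adj", "rad_adj", "cci"):
        out[k] = parts[k]
    return out


def daily_max_cci(cci: pd.DataFrame) -> pd.DataFrame:
    """Reduce a CCI series to one peak-thermal-load value per calendar date.

    A date's records are all rows whose local timestamp falls on that date.
    The per-date maximum is computed over the *full* day and is attached
    unchanged to the full-day, daytime and nighttime summaries downstream —
    peak load, not daypart-local load, is the exposure measure.

    Returns columns ``date, max_cci, n_records``; empty dates simply do not
    appear.
    """
    if len(cci) == 0:
        raise ValueError("empty CCI series")
    dates = pd.to_datetime(cci["t"]).dt.date
    grouped = cci.groupby(dates)["cci"]
    out = grouped.agg(max_cci="max", n_records="size").reset_index(names="date")
    return out
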