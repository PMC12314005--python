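"""Exposure-response correlation tables.

Within each week group and daypart, behavior hours, shade use, distance,
weekly weight gain, initial weight and Bos indicus proportion are correlated
(Pearson, with a Spearman cross-check) against the daily maximum CCI and the
animal-level anchors.  95 % confidence intervals use the Fisher
z-transform, z +/- 1.96 / sqrt(n - 3), back-transformed — the closed-form
interval conventionally drawn in forest plots.

The unit of analysis defaults to the animal-day pooled within a group's two
weeks; missing cells are handled by pairwise-complete deletion, never
imputed, and a zero-variance pair is reported as a missing cell rather than
r = 0.  No multiple-testing correction is applied by default (a
Benjamini-Hochberg column is available behind a flag); "significant" in
output vocabulary means only that the CI excludes zero.
"""

from __future__ import annotations

import logging
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .config import BEHAVIOR_CLASSES, DEFAULT_CONFIG, PipelineConfig
from .errors import UndefinedCorrelationError

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationResult", "fisher_ci", "pearson_with_ci", "spearman_check",
    "weekly_weight_gain", "correlation_suite", "forest_plot",
]

Z95 = 1.959963984540054  # two-sided 95 % normal quantile


class CorrelationResult(NamedTuple):
    r: float
    ci_low: float
    ci_high: float
    n: int
    method: str


def fisher_ci(r: float, n: int, z: float = Z95) -> tuple[float, float]:
    """Fisher z-transform CI; degenerate cases map to the admissible range.

    At n = 3 the half-width is infinite and the interval is (-1, 1); at
    |r| = 1 the transform diverges and the interval collapses onto r.
    """
    if abs(r) >= 1.0:
        return (float(r), float(r))
    if n <= 3:
        return (-1.0, 1.0)
    zr = np.arctanh(r)
    half = z / np.sqrt(n - 3)
    return (float(np.tanh(zr - half)), float(np.tanh(zr + half)))


def _validate_pair(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise UndefinedCorrelationError(f"only {len(x)} complete pairs (< 3)")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in x or y")
    return x, y


def pearson_with_ci(x, y) -> CorrelationResult:
    """Product-moment correlation with a Fisher-z 95 % CI.

    Pairwise-complete: pairs with a non-finite member are dropped first.
    """
    x, y = _validate_pair(x, y)
    r = float(stats.pearsonr(x, y).statistic)
    lo, hi = fisher_ci(r, len(x))
    return CorrelationResult(r, lo, hi, len(x), "pearson")


def spearman_check(x, y) -> CorrelationResult:
    """Rank correlation (Pearson on tie-averaged ranks), same CI recipe."""
    x, y = _validate_pair(x, y)
    rho = float(stats.spearmanr(x, y).statistic)
    lo, hi = fisher_ci(rho, len(x))
    return CorrelationResult(rho, lo, hi, len(x), "spearman")


def weekly_weight_gain(weights: pd.DataFrame,
                       config: PipelineConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """Consecutive weigh-day differences per animal.

    ``weights`` is the long table ``animal_id, date, weight`` (Monday weigh
    days).  Each gain is attributed to the week ending at the later weigh
    date; gains whose weigh gap is not exactly 7 days are flagged
    ``is_weekly = False`` and excluded from weekly correlations downstream.

    Returns ``animal_id, date_start, date_end, gain, is_weekly, week``
    (global week index of the 7 days preceding the later weigh date).
    """
    rows = []
    for animal, grp in weights.sort_values(["animal_id", "date"]).groupby("animal_id"):
        d = list(grp["date"])
        w = list(grp["weight"])
        for (d0, w0), (d1, w1) in zip(zip(d, w), zip(d[1:], w[1:])):
            gap = (d1 - d0).days
            trial = config.trial_of(d0)
            week = (config.global_week(trial.trial_id, trial.week_of(d0))
                    if trial is not None and gap == 7 else np.nan)
            rows.append({"animal_id": animal, "date_start": d0, "date_end": d1,
                         "gain": w1 - w0, "is_weekly": gap == 7, "week": week})
    cols = ["animal_id", "date_start", "date_end", "gain", "is_weekly", "week"]
    return pd.DataFrame(rows, columns=cols)


ANCHORS = ("max_cci", "bos_indicus", "initial_weight", "weight_gain")


def correlation_suite(
    summaries: pd.DataFrame,
    gains: pd.DataFrame,
    profiles: pd.DataFrame,
    groups: pd.DataFrame,
    config: PipelineConfig = DEFAULT_CONFIG,
    *,
    min_n: int = 10,
) -> pd.DataFrame:
    """Full correlation table: group x daypart x anchor x variable.

    For every group and daypart in {full, day, night}, each anchor (daily
    max CCI, Bos indicus proportion, initial weight, weekly weight gain) is
    correlated against every behavior class, travel distance and — in the
    daytime analyses only, since shade seeking has no meaning after dark —
    time spent in the open; weight gain additionally appears as a response
    against the CCI and Bos indicus anchors.  Incomplete-coverage rows and
    implausible-distance animal-days are dropped first.  Groups or cells
    with insufficient data are skipped with a log entry.
    """
    summ = summaries[~summaries["incomplete"] & ~summaries["excluded"]].copy()
    summ = summ.merge(profiles[["animal_id", "bos_indicus", "initial_weight"]],
                      on="animal_id", how="left")
    weekly = gains[gains["is_weekly"]][["animal_id", "week", "gain"]].rename(
        columns={"gain": "weight_gain"})
    summ = summ.merge(weekly, on=["animal_id", "week"], how="left")

    results = []
    for group_id, gweeks in groups.groupby("group_id")["week"]:
        gsub = summ[summ["week"].isin(set(gweeks))]
        for daypart in ("full", "day", "night"):
            sub = gsub[gsub["daypart"] == daypart]
            if config.correlation_unit == "animal_mean":
                num = [c for c in sub.columns
                       if pd.api.types.is_numeric_dtype(sub[c])]
                sub = sub.groupby("animal_id", observed=True)[num].mean().reset_index()
            if len(sub) < min_n:
                logger.warning("group %s daypart %s: only %d usable rows; skipped",
                               group_id, daypart, len(sub))
                continue
            variables = [*BEHAVIOR_CLASSES, "distance"]
            if daypart == "day":
                variables.append("time_in_open")
            for anchor in ANCHORS:
                targets = list(variables)
                if anchor in ("max_cci", "bos_indicus"):
                    targets.append("weight_gain")
                for var in targets:
                    if var == anchor:
                        continue
                    for fn in (pearson_with_ci, spearman_check):
                        try:
                            res = fn(sub[anchor], sub[var])
                        except UndefinedCorrelationError as exc:
                            logger.info(
                                "group %s %s %s~%s: %s", group_id, daypart,
                                anchor, var, exc)
                            continue
                        results.append({
                            "group_id": group_id, "daypart": daypart,
                            "x_var": anchor, "y_var": var, **res._asdict()})
    cols = ["group_id", "daypart", "x_var", "y_var", "r", "ci_low", "ci_high",
            "n", "method"]
    return pd.DataFrame(results, columns=cols)


def forest_plot(results: pd.DataFrame, out_dir, *, group_id=None,
                daypart="full", fmt: str = "png") -> list:
    """Forest plots of correlation estimates, one panel per anchor.

    Points are Pearson r, whiskers the 95 % CI.  Returns the written paths.
    """
    from pathlib import Path

    import matplotlib
    matplotlib.use("Agg", force=False)
    from matplotlib.figure import Figure

    if len(results) == 0:
        raise ValueError("no correlation results to plot")
    sel = results[results["method"] == "pearson"]
    if group_id is not None:
        sel = sel[sel["group_id"] == group_id]
    sel = sel[sel["daypart"] == daypart]
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    anchors = [a for a in ANCHORS if a in set(sel["x_var"])]
    for anchor in anchors:
        panel = sel[sel["x_var"] == anchor].reset_index(drop=True)
        fig = Figure(figsize=(5, 0.5 + 0.4 * len(panel)))
        ax = fig.subplots()
        y = np.arange(len(panel))[::-1]
        ax.errorbar(panel["r"], y,
                    xerr=[panel["r"] - panel["ci_low"],
                          panel["ci_high"] - panel["r"]],
                    fmt="o", color="k", ecolor="gray", capsize=3)
        ax.axvline(0.0, color="steelblue", lw=0.8, ls="--")
        ax.set_yticks(y, panel["y_var"])
        ax.set_xlim(-1, 1)
        ax.set_xlabel("Pearson r (95% CI)")
        ax.set_title(f"{anchor} — {daypart}"
                     + (f", group {group_id}" if group_id is not None else ""))
        path = out_dir / f"forest_{anchor}_{daypart}.{fmt}"
        fig.savefig(path, bbox_inches="tight", dpi=120)
        paths.append(path)
    return paths
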