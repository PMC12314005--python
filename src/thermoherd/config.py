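"""Pipeline-wide configuration.

All timestamps in the pipeline are interpreted in the trial's fixed local
time (Queensland runs UTC+10 with no daylight saving), and every aggregation
interval (5 s labels, 10 min positions, 1 h budgets, 1 day summaries) is
half-open ``[t, t + delta)`` so interval partitions are exact.
"""

from __future__ import annotations

import datetime as dt
from typing import Literal, Sequence

from pydantic import BaseModel, Field, model_validator

#: Behavior classes of the collar ethogram, in canonical column order.
BEHAVIOR_CLASSES: tuple[str, ...] = (
    "grazing", "walking", "ruminating", "resting", "drinking", "other",
)

#: Daypart labels used throughout; daytime is [day_start, day_end) local.
DAYPARTS: tuple[str, ...] = ("full", "day", "night")


class TrialWindow(BaseModel):
    """A contiguous trial period. ``start`` is day 1; ``n_days`` days follow."""

    trial_id: Literal["trial1", "trial2"]
    start: dt.date
    n_days: int = 28

    @property
    def end(self) -> dt.date:
        """First date after the window (half-open)."""
        return self.start + dt.timedelta(days=self.n_days)

    def contains(self, date: dt.date) -> bool:
        return self.start <= date < self.end

    def week_of(self, date: dt.date) -> int:
        """1-based calendar week within the trial (7-day blocks from start)."""
        return (date - self.start).days // 7 + 1


class PipelineConfig(BaseModel):
    """Knobs shared by every pipeline stage.

    Parameters
    ----------
    utc_offset_hours
        Fixed local offset applied when inputs carry timezone information.
    wind_unit
        Unit of the wind-speed column in weather CSVs.  Internally the
        pipeline always uses m/s; km/h input is divided by 3.6 on read.
    day_start, day_end
        Local hours bounding the daytime daypart, half-open
        ``[day_start, day_end)`` — sunrise 05:00, sunset 18:00 by default,
        giving a 13 h day and an 11 h night.
    label_dt_s
        Duration of one behavior label (collar classification cadence).
    gap_limit_min
        No travel segment is accumulated across a gap in median positions
        longer than this many minutes.
    distance_range_km
        Plausible full-day travel range; animal-days outside it are flagged
        ``excluded`` and dropped from correlations.
    coverage_threshold
        Minimum fraction of a daypart's hours that must contain at least one
        behavior record for the daypart summary to count as complete.
    cci_envelope
        Out-of-envelope weather handling for the climate index:
        ``warn`` (compute anyway), ``clamp`` or ``raise``.
    correlation_unit
        ``animal_day`` pools every animal-day in a group; ``animal_mean``
        first averages within animal.
    night_spans_midnight
        If False (default) a date's night is that date's 18:00-24:00 plus the
        same date's 00:00-05:00; if True the pre-dawn block is taken from the
        following calendar date.
    """

    utc_offset_hours: int = 10
    wind_unit: Literal["m/s", "km/h"] = "m/s"
    day_start: int = 5
    day_end: int = 18
    label_dt_s: float = 5.0
    gap_limit_min: float = 60.0
    distance_range_km: tuple[float, float] = (0.0, 10.0)
    coverage_threshold: float = 0.8
    cci_envelope: Literal["warn", "clamp", "raise"] = "warn"
    correlation_unit: Literal["animal_day", "animal_mean"] = "animal_day"
    night_spans_midnight: bool = False
    bounding_box_margin_km: float = 1.0
    trial_windows: Sequence[TrialWindow] = Field(
        default_factory=lambda: [
            TrialWindow(trial_id="trial1", start=dt.date(2022, 11, 21)),
            TrialWindow(trial_id="trial2", start=dt.date(2023, 11, 20)),
        ]
    )

    @model_validator(mode="after")
    def _check_dayparts(self) -> "PipelineConfig":
        if not (0 <= self.day_start < self.day_end <= 24):
            raise ValueError("need 0 <= day_start < day_end <= 24")
        return self

    @property
    def day_hours(self) -> int:
        return self.day_end - self.day_start

    @property
    def night_hours(self) -> int:
        return 24 - self.day_hours

    def daypart_length(self, daypart: str) -> int:
        return {"full": 24, "day": self.day_hours, "night": self.night_hours}[daypart]

    def trial_of(self, date: dt.date) -> TrialWindow | None:
        for w in self.trial_windows:
            if w.contains(date) or date == w.end:  # final weigh day allowed
                return w
        return None

    def global_week(self, trial_id: str, week_in_trial: int) -> int:
        """Week index 1..8 across both trials (trial1 weeks first)."""
        offset = 0
        for w in self.trial_windows:
            if w.trial_id == trial_id:
                return offset + week_in_trial
            offset += w.n_days // 7
        raise KeyError(trial_id)


DEFAULT_CONFIG = PipelineConfig()
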