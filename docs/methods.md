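# Methods

## The analysis in one paragraph

The pipeline estimates how a grazing herd's behavior responds to thermal
load.  Thermal load is summarized per 10-minute weather record by the
Comprehensive Climate Index (CCI) and reduced to one peak value per
calendar day; behavior, shade use and movement are aggregated per animal,
calendar date and daypart; days are ranked by peak CCI across both trials
and grouped into four two-week exposure strata; and within each stratum the
association of every behavioral variable with CCI and with the animal-level
covariates (initial weight, weekly gain, *Bos indicus* proportion) is
reported as a Pearson correlation with a Fisher-z 95 % confidence interval
(Spearman alongside, as a linearity check).

## Climate index

CCI = Tₐ + RH_adj + WS_adj + RAD_adj, with the three adjustment equations
of Mader, Johnson & Gaughan (2010) transcribed into the constants table
`climate_index.MADER_2010`.  Useful structure, exploited by the tests:
the humidity adjustment carries an (RH − 30) factor and vanishes at
RH = 30 %; the wind adjustment is +3.17 °C-equivalent in still air and
decreases monotonically with wind speed; the radiation adjustment at zero
radiation reduces to 0.1·Tₐ − 2.  Wind speed is handled internally in m/s
(a km/h input column is declared in the config and divided by 3.6 on read);
group-level summaries report km/h, the customary unit.  Inputs outside the
published validity envelope (Tₐ ∈ [−30, 45] °C, WS ≤ 30 m/s,
RAD ≤ 1500 W/m²) are computed with a warning by default; `clamp` and
`raise` modes exist.  Physical bounds (RH ∈ [0, 100], RAD ≥ 0, WS ≥ 0) are
hard errors.

A day's records are all 10-minute rows whose local timestamp falls on that
calendar date; the per-date maximum CCI is computed over the full day and
attached unchanged to the full-day, daytime and nighttime summaries — peak
exposure, not daypart-local exposure, is the stressor of interest.

## Time, dayparts, intervals

All timestamps are interpreted in fixed local trial time (UTC+10,
Queensland, no DST).  Every interval is half-open [t, t + Δ): 5-s labels,
10-min positions and weather, 1-h budgets, 1-day summaries — so interval
partitions are exact.  Daytime is [05:00, 18:00) (13 h), night the
remaining 11 h.  A date's night is that date's evening plus that date's
pre-dawn block; the alternative (night spanning midnight into the next
date) is one config flag (`night_spans_midnight`), retained because the
convention is genuinely arbitrary.

## Trajectories

Raw fixes are reduced to component-wise median lat/lon per 10-minute
interval.  A median position is *open* iff it lies in the paddock and in no
canopy polygon; boundary points count as canopy, the conservative
convention for shade estimates.  Distance is the sum of haversine segments
(R = 6371.0 km) between consecutive medians of the same animal and date.
This median-to-median estimator systematically underestimates true path
length; it is implemented as-is and the bias documented rather than
corrected, because it is the estimator the daily summaries are defined by.
Two guards are our own additions where the procedure is otherwise silent:
no segment is accumulated across a gap in medians longer than 60 min
(prevents spurious jumps across outages), and segments straddling the
day/night boundary count toward the full day only, which makes
full = day + night + boundary exact on gap-free tracks.  Animal-days whose
full-day distance falls outside 0–10 km are flagged implausible and the
flag propagates to both dayparts of that animal-day.

## Budgets and summaries

Hours per class per hour = labels × (label duration)/3600; coverage is the
labelled fraction of the hour.  Daily daypart summaries sum class-hours;
full-day rows are the exact sum of their day and night rows.  Weigh-day
(Monday) rows are excluded from behavioral summaries — mustering distorts
budgets — but weigh records themselves are kept, and Mondays *do*
participate in the exposure ranking, which is a property of the weather,
not of behavior.  A daypart with behavior records in fewer than 80 % of its
hours (configurable) is flagged incomplete and excluded from correlations;
missingness is always explicit (NaN), never imputed, and correlations use
pairwise-complete deletion.

## Exposure ranking

Days of both trials are merged and ranked by daily maximum CCI, rank 1 the
coldest; ties receive average ranks (our choice — it makes every downstream
step invariant to permutation and to strictly monotone transforms of the
index).  Weekly exposure is the mean of member-day ranks over the trial's
calendar weeks (7-day blocks from trial start); the eight weeks are sorted
by that mean and paired in order into four groups.  Group 4 (warmest pair)
and group 1 (coolest pair) are the high/low-CCI strata.

## Correlations

Pearson r with the Fisher-z interval tanh(atanh r ± 1.96/√(n−3)); at n = 3
the interval is the full admissible range (−1, 1), at |r| = 1 it collapses
onto r.  Zero-variance or n < 3 cells are reported as missing, never as
r = 0.  The unit of analysis is the animal-day pooled over a group's two
weeks (config `animal_day`; `animal_mean` first averages within animal) —
the pooling is the main reproduction assumption of the analysis and is
deliberately configurable.  Time-in-open appears in daytime analyses only;
weekly weight gain is joined to animal-days by the week the gain accrued
over and additionally appears as a response against the CCI and
*Bos indicus* anchors.  No multiple-testing correction is applied in the
default output; "significant" vocabulary is restricted to "CI excludes 0".

Pooled animal-days are not independent: all animals share each day's CCI,
and each animal repeats its own covariates across days.  The nominal
Fisher CI is therefore anti-conservative for cells that pair two clustered
variables (notably CCI × weekly gain).  This is a property of the pooled
design, not of the CI code, and is why the null-coverage battery (below)
uses a pre-registered 0.92–0.98 band rather than the iid 0.93–0.97.

## Synthetic trials

The generator emulates the study design the package targets: two 28-day late-spring
trials (starting Mondays 2022-11-21 and 2023-11-20) of 60 animals on a
~3 ha rectangular paddock (200 × 150 m) with six fixed square canopies.

* **Weather**: Tₐ is a mid-afternoon-peaked sinusoid (mean 26.8 °C,
  amplitude 6.8 °C) on an AR(1) day-to-day drift (φ = 0.65, σ = 1.7 °C),
  trial 2 offset +1 °C; RH anti-correlated with the temperature anomaly;
  radiation a daylight half-sine (peak 960 W/m²) scaled by a per-day cloud
  factor, exactly zero at night; wind log-normal around 1.3 m/s; sparse
  rain.  Parameters are tuned once so daily maximum CCI spans roughly
  36–52, the moderate subtropical band the analysis targets.
* **Behavior**: per animal-day, class totals around medians (grazing 7.0 h,
  ruminating 2.9 h, resting 2.0 h, walking 0.7 h, drinking 0.08 h, other
  0.15 h) with multiplicative animal- (σ = 0.08) and day-level (σ = 0.10)
  log-normal noise, split day/night by fixed fractions, then shifted by the
  planted effects: `graze_shift_slope` = 0.12 h of grazing moved day→night
  per CCI unit above 43, `rest_gain_slope` = 0.05 h added to daytime
  resting per unit, and a small walking × *Bos indicus* × CCI interaction.
  Daypart totals are spread over clock hours by diurnal templates, capped
  at 1 h/hour with overflow redistributed within the daypart, and quantized
  to labels.  Effects are planted at the **daily-budget** level so their
  theoretical signs are known in closed form.
* **Tracks**: a persistent-attractor walk on the 10-minute grid — with
  probability 0.22 per interval the attractor is redrawn, landing in a
  canopy with probability logistic(0.45 × (day's max CCI − 47)) by day and
  0.25 by night, otherwise the animal wanders ~2 m around its attractor;
  fixes add 3 m isotropic receiver noise and are clipped to the paddock.
  This yields median daily distances ≈ 3.2 km, comfortably inside the
  0–10 km plausibility window.  The planted shade response is monotone in
  CCI, so (unlike some real herds, which sun-seek in mild conditions) the
  cool-stratum shade correlation is negative too.
* **Animals**: initial weights normal (median 259 kg, spread 39 kg),
  *Bos indicus* uniform on [0.47, 0.95]; weekly gains = 6.25 kg + 1.2 ×
  (mean daily grazing − 7 h) − 0.8 × (mean daily km − 3.2) + noise,
  totalling ≈ 25 kg over four weeks.

Everything is a pure function of `SimConfig` (per-stream seeded
substreams): identical configurations give byte-identical fixture files.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: GNSS dropouts and multipath, collar failures and
partial days, behavior misclassification, spatially heterogeneous pasture,
sun-angle-dependent shade geometry, rain- or wind-driven behavior, herd
social structure, and non-monotone shade responses.  Recovery results
demonstrate that the *pipeline* measures what was planted, not that real
cattle behave like the model.

## Problem sizes and numerical choices

`label_dt_s` and `fixes_per_interval` are sensor cadences, not effect
parameters: coarsening them changes quantization noise only.  The
end-to-end batteries run the full 60-animal × 2 × 28-day design at 120-s
labels and 4 fixes per interval (the acceptance script at 30-s labels and
8 fixes), which keeps a 60-run battery within a few minutes on one core;
unit tests exercise the native 5-s/1-Hz cadence on small windows.  The
sign-recovery battery requires each planted sign (daytime open-time down,
daytime grazing down, nighttime grazing up, in the warmest group) in at
least 95 % of 40 seeds; the exchangeable-null battery (all slopes and
shared random effects zero, 20 seeds) requires pooled CI coverage of zero
in 0.92–0.98.  Label rounding is to the nearest whole label per
(hour, class), so a reconstructed daily budget differs from its planted
target by at most half a label per hour.  Weekly behavior summaries report
raw (unscaled) median absolute deviation when asked for MAD.

## Known limitations

* Plain pooled correlations — no animal-level random effects, by design
  fidelity to the emulated analysis; the clustering caveat above applies to
  every reported CI.
* The day-ranking scheme captures cumulative heat ordinally; it does not
  model lagged physiological load.
* Median-to-median distances understate path length, increasingly so for
  tortuous movement.
* Canopy polygons are treated as static full shade; sun angle is ignored.
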