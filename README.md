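# thermoherd

Exposure–response analytics for grazing cattle under thermal stress.

Grazing cattle respond to heat by seeking shade, shifting grazing into the
night, and resting more by day — behavioral signals that matter for welfare,
productivity and breeding, but are hard to quantify in extensive systems.
`thermoherd` turns multimodal sensor streams from a collared herd —
per-animal behavior labels (a six-class ethogram at 5-second cadence:
grazing, walking, ruminating, resting, drinking, other), 1-Hz GNSS fixes, a
paddock/tree-canopy map, 10-minute weather-station records, and weekly
Monday weights with genomic *Bos indicus* proportions — into:

* a **Comprehensive Climate Index (CCI)** series and its daily maxima.  The
  CCI expresses combined thermal load as an apparent temperature,

  CCI = Tₐ + RH_adj(Tₐ, RH) + WS_adj(WS) + RAD_adj(Tₐ, RAD),

  with the published humidity, wind-speed and solar-radiation adjustment
  equations (Mader, Johnson & Gaughan 2010) kept in a single auditable
  constants table;
* **10-minute median positions**, open/canopy occupancy from point-in-polygon
  tests against the canopy map, and daily haversine travel distances with a
  0–10 km plausibility filter;
* **hourly and daily ethogram time budgets**, split at sunrise 05:00 /
  sunset 18:00 into daytime (13 h) and nighttime (11 h), with weigh-Monday
  days excluded from behavioral summaries;
* **day-ranked climate-exposure groups**: all trial days (both trials
  merged) ranked by daily maximum CCI (rank 1 = coldest), ranks averaged per
  week, the eight weeks ranked and paired — group 1 the coolest pair of
  weeks, group 4 the warmest;
* **daypart-stratified correlation tables** (Pearson with Fisher-z 95 % CIs,
  Spearman cross-check) of CCI, behavior hours, time-in-open, distance,
  weekly weight gain, initial weight and *Bos indicus* proportion within
  each exposure group, plus forest plots.

Because raw trial data of this kind is rarely public, the package ships a
first-class **synthetic-trial generator**: two 28-day trials of 60 animals
with planted, parameterized CCI-dependent effects (logistic shade affinity,
linear day→night grazing shift, daytime resting gain, a small
*Bos indicus* × CCI walking interaction, and behavior/distance-driven weight
gain), so the whole pipeline is testable end-to-end for sign and magnitude
recovery.

## Worked example

```python
from thermoherd import SimConfig, generate_all, run_pipeline

cfg = SimConfig(seed=1, label_dt_s=30.0, fixes_per_interval=8)
data = generate_all(cfg)                      # five streams + ground truth
res = run_pipeline(data, cfg.pipeline_config())

warm = res.groups["group_id"].max()           # warmest pair of weeks
c = res.correlations
cell = c[(c.group_id == warm) & (c.method == "pearson")
         & (c.x_var == "max_cci") & (c.daypart == "day")
         & (c.y_var == "time_in_open")].iloc[0]
print(f"r(CCI, daytime time-in-open) = {cell.r:.2f} "
      f"[{cell.ci_low:.2f}, {cell.ci_high:.2f}], n = {cell.n}")
```

prints

```
r(CCI, daytime time-in-open) = -0.77 [-0.79, -0.73], n = 720
```

i.e. within the warmest exposure group, hotter days (higher daily maximum
CCI) see animals spend markedly less daytime in the open — the planted
shade-seeking response, recovered by the full pipeline from raw labels,
fixes and weather.  The same run yields r = −0.41 for daytime grazing and
r = +0.76 for nighttime grazing against CCI (grazing moves into the night
on hot days), a daily-max CCI range of 37.5–48.0, and herd median weights
of 261 kg at trial start and 287 kg at trial end.

The same stages are available from the shell:

```bash
thermoherd simulate fixtures/ --seed 17            # synthetic trial
thermoherd cci --weather weather.csv --out cci.csv
thermoherd track --gnss gnss.csv --canopy map.geojson --out movement.csv
thermoherd run behavior.csv gnss.csv weather.csv map.geojson animals.csv out/
```

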