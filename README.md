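# droughtring

Drought-resilience analysis of multi-provenance tree-ring collections.

Common-garden (provenance) trials grow seed sources of known geographic
origin under identical conditions, so differences in how their trees
weather a drought are genetic. `droughtring` implements the full
tree-ring workflow such a study needs, from raw ring-width files to
provenance-level statistics, for dendroecologists and forest
geneticists working with Norway spruce or similar conifers:

1. **Ingestion & screening** — Tucson/RWL and long-form CSV readers;
   series whose intercorrelation with the leave-one-out master
   chronology falls below 0.328 are excluded (high-pass filtered,
   COFECHA-style).
2. **Detrending & chronologies** — smoothing-spline standardization
   with a 0.50 frequency response at a wavelength of 0.67 × series
   length; RWI = RW / fit; Tukey-biweight mean chronologies.
3. **Drought identification** — Thornthwaite PET from monthly
   temperature, climatic water balance D = P − PET, SPEI at scale *k*
   (3-parameter log-logistic fitted by unbiased probability-weighted
   moments, per calendar month); months classed moderate
   (−1.5, −1], severe (−2, −1.5], extreme ≤ −2.
4. **Pointer years** — years in which ≥ 60% of trees show a relative
   growth change beyond ±10%.
5. **Resilience indices** (Lloret) per tree × event year, with 3-year
   windows:
   Res = Dr/preDr, Rec = postDr/Dr, Rsl = postDr/preDr,
   relRsl = (postDr − Dr)/preDr.
6. **Provenance variation** — the mixed model
   X = μ + P + B + Y + P×Y + e with provenance (P) and P×Y random and
   block (B) and year (Y) fixed; REML likelihood-ratio tests for each
   variance component (boundary-corrected reference by default), and
   Pearson correlation tables of traits and indices against the
   provenances' latitude, longitude and elevation.
7. **Climate–growth functions** — bootstrapped correlation and
   principal-components response functions of the chronology on
   March–September monthly temperature and precipitation over 25-year
   moving windows, for non-stationarity analysis.

A synthetic-data module generates a complete trial (seasonal climate
with warming trend and imposed droughts; a randomised complete block
design of provenances with negative-exponential age trend, climate
signal and drought-year growth reductions) with known ground truth, so
every stage is testable without access to the original measurements.

## Worked example

```python
import dataclasses
import numpy as np
import droughtring as dr

cfg = dataclasses.replace(dr.SimulationConfig(seed=42),
                          n_provenances=12, trees_per_plot=2)
rng = np.random.default_rng(42)
climate = dr.gen_climate(cfg, rng)
rings, truth = dr.gen_rings(cfg, climate, rng)

retained, rejected = dr.screen_collection(rings, threshold=0.328)
print(f"screening: kept {len(retained)}/{len(rings)} series, "
      f"rbar = {dr.rbar(retained):.3f}")

calendar = dr.classify_drought(dr.spei(dr.thornthwaite_pet(climate), 3))
print(f"extreme drought years: {calendar.extreme_years()}")

records, skipped = dr.compute_collection(retained, [2000, 2003], window=3)
print(records.groupby("event_year")[["resistance", "recovery",
                                     "resilience"]].mean().round(2))
```

prints

```
screening: kept 72/72 series, rbar = 0.897
extreme drought years: [1992, 1996, 2000, 2001, 2003]
            resistance  recovery  resilience
event_year
2000              0.40      1.94        0.74
2003              0.53      2.13        1.11
```

All 72 simulated cores share enough common signal to pass the 0.328
screening (rbar 0.897). The imposed droughts of 2000 and 2003 are
recovered as extreme SPEI-3 years (alongside a few naturally dry
simulated years). Mean resistance 0.40 in 2000 reflects the imposed
40% ring-width reduction compounded by the simulated precipitation
deficit; recovery above 1 means growth rebounded after each event,
and the 2000 resilience of 0.74 indicates growth had not returned to
pre-drought levels within three years — unsurprising, since the 2003
event sits inside that post-drought window (the records carry a
`contaminated` flag for exactly this situation).

The same stages are scriptable from the shell:

```sh
droughtring simulate --seed 42 --out sim/   # writes climate.csv, rings.csv, rings.rwl
droughtring spei sim/climate.csv --scale 3 --out sim/spei.csv
droughtring screen sim/rings.rwl --threshold 0.328
droughtring run config.yaml                 # full pipeline from a YAML config
```

The pipeline (`droughtring run`) executes every stage from a single
YAML config and writes the calendar, series statistics, variance-test,
resilience, correlation and moving-window tables plus a JSON manifest
recording every parameter and seed.

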