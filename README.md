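# wezmap

**Phenology-aware agroclimatic risk mapping for winter wheat.**

`wezmap` is for agroclimatologists and crop-modelling teams who want to ask,
for every grid cell of a daily weather dataset: *when* is the wheat crop in
each sensitive developmental phase, *which* climate hazards hit it during
that phase, *how often* do they hit, and how does that risk geography shift
under climate-change scenarios. It chains four pieces:

1. **Phenology.** A photo-vernal thermal-time model advances the crop
   through the BBCH-anchored stages SO (sowing, fixed 15 October) → EM
   (emergence, BBCH 10) → E1 (ear at 1 cm, BBCH 30) → FL (flag leaf,
   BBCH 39) → AN (anthesis, BBCH 65) → GM (grain maturity, BBCH 89).
   The daily development increment is

   `dD = max(0, Tavg − Tbase) · f_P(daylength) · f_V(vernalization)`

   with `Tbase = 0 °C`, a linear long-day photoperiod ramp
   `f_P = clip((P − P_base)/(P_opt − P_base), 0, 1)` applied from EM to AN,
   and `f_V = min(1, V/V_sat)`, the satisfied fraction of the cold
   requirement, applied to the juvenile phase EM→E1. Each phase has a fixed
   thermal target; a stage falls on the first day its phase's cumulative
   increment reaches the target.

2. **Ecoclimatic indicators.** For each phenophase, raw stress metrics
   (days below/above a threshold, longest runs, phase sums of the climatic
   water balance P−PET) are normalized onto a common damage scale in
   [0, 1] — 1 = no stress, 0 = maximal stress — through negative-exponential
   or sigmoid response functions. Drought indicators are purely climatic:
   the sigmoid midpoint is the first quartile of the phase P−PET sum pooled
   over all cells and reference seasons, frozen for future periods.

3. **Zoning.** A *risk year* is a season whose normalized indicator falls
   below 0.7; counting them over a 30-season reference period gives each
   cell an integer score in [0, 30] per indicator. Indicators that never
   flag a risk anywhere are removed, K-means clusters the remaining score
   profiles into wheat ecoclimatic zones (WEZ), and the cluster count is
   picked by the elbow rule (maximum second difference of within-cluster
   inertia).

4. **Projection and aggregation.** Future periods are re-run under
   delta-change scenarios inside the frozen reference zones; indicators are
   grouped into four risk families (cold, heat, water deficit, water
   excess) with equal indicator weights and reported as frequencies in
   years per decade, affected-area fractions, 5/50/95 % ensemble quantiles,
   bivariate heat × water-deficit classes, and phenology-shift tables.

A seeded synthetic-weather generator (seasonal cycle + AR(1) noise, Markov
chain/gamma precipitation, Hargreaves PET) emulates a SAFRAN-like gridded
reanalysis so the whole pipeline runs and is tested without external data.

## Worked example

```python
import wezmap as wz

# 12-cell France-like grid, 10 harvest seasons + spin-up year
spec = wz.GridSpec.france_like(12, seed=1)
grid = wz.generate_reference_climate(spec, 11, seed=1)

cfg = wz.RiskConfig(period_length=10, kmeans_seed=1, k_range=range(2, 7))
scenario = wz.ClimateScenarioSpec.uniform(2.0, 0.9, label="warm_dry")
result = wz.full_pipeline(grid, wz.PhenoParams(), wz.default_catalog(),
                          cfg, scenarios={"warm_dry": scenario})

print("zones:", result.zones.k, "| indicators retained:",
      result.scores.scores.shape[1])
print(result.zone_summary.round(2).head(8))
shift = wz.stage_shift_summary(result.stages,
                               result.projections["warm_dry"].stages,
                               result.zones)
print(shift.round(1))
```

Output:

```
zones: 3 | indicators retained: 15
measure             frequency  area_fraction
zone family
1    cold                1.47            1.0
     heat                1.40            1.0
     water_deficit       2.72            1.0
     water_excess        1.44            1.0
2    cold                1.97            1.0
     heat                0.45            1.0
     water_deficit       2.80            1.0
     water_excess        2.05            1.0
       EM    E1    FL    AN    GM
zone
1    -2.0 -12.0 -12.5 -10.5 -13.5
2    -4.0 -18.5 -13.0 -12.5 -15.0
3    -4.5 -16.5 -13.5 -12.5 -16.0
```

Reading it: the elbow rule split the 12 synthetic cells into 3 ecoclimatic
zones; 15 of the 24 default indicators flagged a risk somewhere (the rest
were pruned). In zone 1 the water-deficit family is the dominant hazard at
2.7 risk years per decade, and every zone cell saw at least one occurrence
of each family (area fraction 1.0 — small zones saturate easily). Under the
uniform +2 °C / −10 % precipitation scenario, all stages advance: grain
maturity (GM) comes 13–16 days earlier depending on the zone, ear at 1 cm
(E1) up to 18 days earlier where winters were coldest.

The same flow is available from the shell:

```bash
wezmap make-fixtures --n-cells 20 --n-years 11 --seed 1 --out weather.csv
wezmap simulate-phenology --weather weather.csv --seasons 1992:2001 --out stages.csv
wezmap compute-indicators --weather weather.csv --stages stages.csv --out panel.csv
wezmap cluster --panel panel.csv --period-length 10 --out-prefix run
wezmap project --weather weather.csv --delta-t 2 --period-length 10 --out-prefix proj
```

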