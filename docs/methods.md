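# Methods

This note documents the models implemented in `wezmap`, the defaults they
ship with, what the synthetic-weather generator does and does not emulate,
and the numerical conventions that matter for reproducing results.

## Phenology model

Winter wheat development is simulated with a photo-vernal thermal-time
model. Each phase (SO–EM, EM–E1, E1–FL, FL–AN, AN–GM; stages anchored to
BBCH 10/30/39/65/89) has a fixed effective thermal target in °C·days. The
daily increment is the growing-degree-day term `max(0, Tavg − Tbase)`
multiplied by a photoperiod factor and a vernalization factor where those
apply:

- **Factor combination** is multiplicative (the common photo-vernal
  convention); `PhenoParams(factor_combination="min")` switches to limiting-
  factor form.
- **Phase applicability**: vernalization affects only the juvenile phase
  EM→E1 (floral initiation); photoperiod affects EM→AN; SO→EM and AN→GM are
  purely thermal.
- **Photoperiod**: linear ramp, zero development at/below `p_base = 6.6 h`,
  full at/above `p_opt = 16 h`. Day length uses the standard declination /
  hour-angle formula with the sun centre at −0.833° elevation.
- **Vernalization**: effective days accumulate with credit 1 on the
  0–10 °C plateau, declining linearly to 0 at the 17 °C pause threshold
  (the physiological pause is reported between 16 and 18 °C; 17 °C is the
  midpoint). A day also requires `Tmin ≥ 0 °C` (configurable). Days above
  20 °C remove 0.5 effective days (devernalization) while the requirement
  is unsaturated; the state is clamped to `[0, v_sat]`, `v_sat = 50`
  effective days (a high-cold-requirement cultivar). The development
  factor is `min(1, state/v_sat)`.
- **Sowing** is fixed at 15 October of the year before harvest; the cycle
  is declared incomplete if grain maturity is not reached within 365 days
  of sowing. Accumulation for each phase starts the day after the
  phase-opening stage; a stage falls on the first day the cumulative
  effective increment reaches the phase target.

**Default thermal targets** (°C·days, effective): SO–EM 150, EM–E1 200,
E1–FL 250, FL–AN 180, AN–GM 800. These are calibration placeholders for a
Talent-like cultivar, chosen once so that the reference synthetic climate
(below) puts median stage dates in the documented French range — E1 near
20 March, flag leaf late April, anthesis mid-May, grain maturity
late June–mid July — and so that a uniform +1 °C warming advances maturity
by ≈ 7 days, consistent with the ~5.8 days/°C literature estimate. Note the
EM–E1 and E1–FL targets are *effective* (post-multiplication) degree days:
they are numerically much smaller than raw-GDD winter requirements because
the winter photoperiod factor at French latitudes is ≈ 0.2–0.5. All
parameters load from YAML (`PhenoParams.from_yaml`), so a calibrated
cultivar file replaces the defaults without code change.

Evaluation helpers report the per-stage mean error and RMSE (days) between
simulated and observed stage day-of-year; cell-seasons whose simulated
cycle did not complete are excluded from both metrics.

## Ecoclimatic indicators

Indicators are built in three steps: phase windows from the simulated stage
dates (anchors may carry day offsets, e.g. `[E1, AN+10]` for warm nights or
`[FL−5, FL+5]` as the meiosis proxy — meiosis happens near booting, so a
symmetric window around flag leaf is used); a raw metric inside the window
(`count_days`, `max_run_length`, or `sum`, with AND-compound threshold
conditions); and a normalization onto [0, 1] where 1 = no stress.

**Normalizations.** Negative exponential `n = exp(−k·raw)` for raw ≥ 0,
with `k` derived from an anchor `(x_ref, n_ref)` as `k = −ln(n_ref)/x_ref`;
sigmoid `n = 1/(1 + exp(−s·(raw − x0)))` used for the drought indicators
(raw = phase P−PET sum, larger = wetter = less stress).

**Drought.** The climatic water balance P−PET is initialized on 1 January
of the sowing year so the pre-season atmospheric water status carries into
the crop season, and summed per phase. Each drought indicator's sigmoid
midpoint `x0` is the first quartile (type-7 linear interpolation) of its
raw distribution pooled over all cells and reference seasons; the slope is
`s = ln 9 / (median − Q1)` so a median reference year scores 0.9 and a
Q1 year 0.5. Both are calibrated once on the reference period and frozen
for all future periods; computing a drought indicator on a future period
without a frozen calibration is an error, not a silent re-fit.

**Default catalog** (all thresholds from the published stress physiology
for winter wheat; one indicator per mechanism; exponential anchors in
parentheses as `(x_ref, n_ref)`):

| id | family | window | raw metric | anchor |
|---|---|---|---|---|
| soem_flood_run | water_excess | SO–EM | longest run P−PET > 0 | (5, 0.5) — a 5-day flood kills the seed |
| soem_cold_run | cold | SO–EM | longest run Tavg < 2 °C | (4, 0.5) |
| soem_frost_days | cold | SO–EM | days Tmin < −5 °C | (3, 0.5) |
| eme1_cold_days | cold | EM–E1 | days Tavg < 5 °C | (15, 0.55) — published model output |
| eme1_freeze_run | cold | EM–E1 | longest run Tavg < 0 °C | (4, 0.5) |
| eme1_frost_days | cold | EM–E1 | days Tmin < −8 °C | (3, 0.5) |
| vern_pause_days | heat | SO–E1 | days Tavg > 17 °C | (10, 0.5) |
| devern_days | heat | SO–E1 | days Tavg > 20 °C | (5, 0.5) |
| e1fl_cold_days | cold | E1–FL | days Tmin < 0 °C | (5, 0.5) |
| e1fl_frost_days | cold | E1–FL | days Tmin < −5 °C | (3, 0.5) |
| meiosis_cold_lowrad | cold | FL±5 d | days Tmin < 4 °C AND radiation < 200 W/m² | (3, 0.5) |
| warm_nights | heat | E1 to AN+10 d | days Tmin > 12 °C | (10, 0.5) |
| flan_heat_days | heat | FL–AN | days Tmax > 30 °C | (3, 0.5) |
| angm_heat_days | heat | AN–GM | days Tmax > 30 °C | (5, 0.5) |
| angm_cold_band | cold | AN–GM | days −6 < Tmin < −2 °C | (2, 0.5) |
| {phase}_drought ×5 | water_deficit | each phase | P−PET sum | sigmoid, Q1-calibrated |
| {phase}_wet_run ×4 | water_excess | EM–GM phases | longest run P−PET > 0 | (10, 0.5) |

Where the literature states only a threshold and a severity (lethal in
N days, etc.), the anchor places `n = 0.5` at that severe value; the one
published worked value — 15 cold days EM–E1 normalizing to 0.55 — pins that
curve exactly (a 12-day/45 %-photosynthesis literature datum is mutually
inconsistent with it; the printed 15 → 0.55 output is taken as
authoritative). Vernalization-related windows use the calendar interval
[sowing, E1] because the model treats vernalization as completed by E1.
The catalog round-trips through YAML so a site- or cultivar-specific table
replaces the defaults without code change.

Missing handling: a window whose anchor stage was never reached, or that
runs off the grid calendar, yields a missing (NaN) value; panel missingness
therefore tracks incomplete phenological cycles exactly.

## Risk scoring and zoning

A risk year is a season with a normalized value `< 0.7` (one common
threshold for all indicators, i.e. equal weight to all hazards). Counts
over the `period_length = 30` reference seasons give scores in [0, 30].
Missing seasons never count as risk years; cells with more than 50 %
missing values are excluded from clustering (logged) — an extension of the
published exclusion of non-completing areas, applied here to keep the
score space well defined. Indicators scoring zero at every cell are pruned
before clustering.

K-means runs on the raw score profiles — no standardization, since all
columns share the 0–30 scale — with 25 restarts and a fixed seed. The
cluster count is scanned over k = 2..12 and chosen by the **maximum second
difference of within-cluster inertia** (an explicit, reproducible variant
of the elbow rule; a kneedle-style alternative was considered and rejected
as harder to specify). Zones are relabeled deterministically: 1..k by
descending cell count, ties broken by centroid lexicographic order, so
repeated runs and cell permutations yield identical labelings. Zone-level
hazard intensity is the mean score per zone × indicator binned into five
half-open classes: [0,5) very low, [5,10) low, [10,15) medium, [15,20)
high, [20,25) very high.

## Projection and aggregation

Climate scenarios are delta perturbations: 12 monthly additive temperature
offsets and 12 multiplicative precipitation factors; PET is either
recomputed with Hargreaves from the shifted temperatures (default) or
scaled. Future periods re-run phenology and indicators under the perturbed
weather, reusing the frozen drought calibration and the reference zones —
zones are never re-fit on future data.

Family frequencies divide total risk occurrences by the family's indicator
count (equal weights; duplicating all of a family's indicators is a no-op)
and rescale to years per decade (×10/period_length). Zone frequency is the
mean over zone cells (with equal season counts per cell this equals the
pooled ratio; `pooled=True` computes the pooled form). The affected-area
fraction counts zone cells with frequency above a cutoff, default 0 — any
occurrence in the period counts as affected; the cutoff is configurable
because "affected" has no canonical definition. Ensemble spread across
climate realizations is summarized by empirical 5/50/95 % percentiles with
linear interpolation (with a 3-member ensemble, q5/q95 effectively track
min/max). Bivariate heat × water-deficit classes bin per-cell frequencies
half-open at (1, 2, 3) years per decade per axis. Phenology shifts are
differences of zone-median stage day-of-year, negative = advance.

## Synthetic weather generator

The generator emulates the *structure* of a temperate 8-km gridded daily
reanalysis, not any particular dataset:

- daily mean temperature = sinusoidal seasonal cycle (annual mean falling
  with latitude and a continentality covariate, amplitude growing with
  continentality) + AR(1) anomalies (lag-1 autocorrelation 0.7, σ 2.5 °C,
  so multi-day cold/heat spells and run-length indicators are exercised);
- tmin/tmax = tavg ∓ a seasonal half-range;
- precipitation: two-state Markov occurrence (P(wet|wet)=0.6,
  P(wet|dry)=0.25 — typical temperate persistence) with gamma amounts
  (shape 0.8), slightly wetter in winter;
- radiation: clear-sky seasonal curve damped on wet days;
- PET: Hargreaves–Samani from tmin/tmax and latitude.

It does **not** emulate spatial correlation between cells, real GCM-RCM
field statistics, orographic effects, or extreme-event clustering beyond
AR(1); passing tests on this generator demonstrate the pipeline's logic
and statistical behaviour, not skill on real reanalysis data. Zoning
testbeds come in two forms: a weather-level testbed drawing cells from
contrasting climate regimes (Mediterranean-like, oceanic, continental,
montane, …) whose separation must survive the whole indicator transform,
and a score-level testbed drawing integer risk scores around seven
equidistant block-design centroid profiles (each zone elevated by 20 score
units in its own two indicators, Gaussian noise σ = 1.5) — the geometry in
which the inertia curve has a clean elbow at the true zone count.

## Numerical conventions and degenerate inputs

- Quantiles/quartiles everywhere use linear interpolation (numpy default,
  type 7).
- `tavg` missing from an input is derived as `(tmin+tmax)/2`.
- Radiation is a daily mean in W/m²; MJ/m²/day inputs divide by 0.0864.
- Calendars are proleptic Gregorian with real leap years; the grid
  validator rejects gaps and cells on different calendars.
- Negative raw values are a domain error for exponential normalization;
  sigmoid arguments are overflow-guarded.
- A flat inertia curve (single repeated score profile) degenerates to the
  smallest scanned k with a warning; k exceeding the number of distinct
  profiles is an error.
- All stochastic components take explicit integer seeds; fixed seed ⇒
  bit-identical outputs through the whole pipeline.

## Problem sizes

The shipped tests run the full pipeline at 6–12 cells × 5–10 seasons and
the zoning recovery at 2,000 cells × 14 indicators; these sizes keep the
suite fast while exercising every code path, and all operations scale
linearly in cells × seasons (phenology and indicators) or via scikit-learn
K-means (zoning).

## Known limitations

- No soil water balance: drought is purely climatic (P−PET), so soil-depth
  and texture effects on drought damage are not represented.
- Stress interactions are additive through the family aggregation;
  compounding of successive stresses within a season is not modelled.
- The default cultivar parameters are placeholders calibrated to the
  synthetic climate, not a fitted Talent parameter set.
- Devernalization is implemented as a simple linear removal below
  saturation; the experimental basis concerns constant-temperature
  conditions and the daily-weather extrapolation is a modelling choice.
- Zone geography from synthetic weather has no correspondence to real
  administrative or agro-ecological regions.
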