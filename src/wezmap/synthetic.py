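"""Synthetic multi-year gridded daily weather and scenario perturbations.

Emulates the structure of an 8-km reanalysis over a temperate wheat region:
sinusoidal seasonal temperature cycle modulated by latitude and a
continentality covariate, AR(1) day-to-day temperature noise, two-state
Markov precipitation occurrence with gamma amounts, clear-sky radiation
damped on wet days, and Hargreaves PET. Climate-change scenarios are
represented abstractly as monthly temperature deltas and precipitation
scale factors, the way delta-perturbed projection ensembles are summarized.

The generator's defaults are the study conditions every downstream module
is tested under; they are chosen for a France-like winter-wheat climate
and are not tuned per test.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .weather import WeatherGrid, daylength, pet_hargreaves

__all__ = [
    "ClimateScenarioSpec",
    "GridSpec",
    "generate_reference_climate",
    "apply_scenario",
    "make_cluster_testbed",
    "make_score_testbed",
    "REGIME_PRESETS",
]

# day-to-day temperature persistence and noise (°C) on daily mean temperature
AR1_RHO = 0.7
AR1_SIGMA = 2.5
# two-state Markov rain occurrence: typical temperate persistence
P_WET_GIVEN_WET = 0.6
P_WET_GIVEN_DRY = 0.25
GAMMA_SHAPE = 0.8


@dataclasses.dataclass
class ClimateScenarioSpec:
    """Delta-change climate scenario: monthly additive warming and
    multiplicative precipitation factors.

    ``pet_response`` is either ``"recompute_hargreaves"`` (PET re-derived
    from perturbed temperatures) or ``"scale"`` (PET kept, optionally
    scaled by ``pet_scale``).
    """

    delta_t_monthly: Sequence[float]
    precip_scale_monthly: Sequence[float]
    pet_response: str = "recompute_hargreaves"
    pet_scale: float = 1.0
    label: str = "scenario"

    def __post_init__(self) -> None:
        self.delta_t_monthly = np.asarray(self.delta_t_monthly, dtype=float)
        self.precip_scale_monthly = np.asarray(self.precip_scale_monthly, dtype=float)
        if self.delta_t_monthly.shape != (12,) or self.precip_scale_monthly.shape != (12,):
            raise ValueError("scenario needs 12 monthly deltas and 12 precip factors")
        if (self.precip_scale_monthly <= 0).any():
            raise ValueError("precipitation scale factors must be positive")
        if self.pet_response not in {"recompute_hargreaves", "scale"}:
            raise ValueError(f"unknown pet_response {self.pet_response!r}")

    @classmethod
    def uniform(cls, delta_t: float = 0.0, precip_scale: float = 1.0,
                label: str = "uniform", **kw) -> "ClimateScenarioSpec":
        return cls([delta_t] * 12, [precip_scale] * 12, label=label, **kw)


@dataclasses.dataclass
class GridSpec:
    """Cell layout: latitudes plus a continentality/altitude covariate in
    [0, 1] (0 = mild oceanic lowland, 1 = cold continental/montane)."""

    latitudes: Sequence[float]
    continentality: Sequence[float]
    longitudes: Sequence[float] | None = None
    cell_ids: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.latitudes = np.asarray(self.latitudes, dtype=float)
        self.continentality = np.asarray(self.continentality, dtype=float)
        if self.latitudes.shape != self.continentality.shape:
            raise ValueError("latitudes and continentality must have equal length")
        n = len(self.latitudes)
        if self.longitudes is None:
            self.longitudes = np.linspace(-1.0, 6.0, n) if n > 1 else np.array([2.0])
        if self.cell_ids is None:
            self.cell_ids = [f"c{i:04d}" for i in range(n)]

    @classmethod
    def france_like(cls, n_cells: int, seed: int = 0) -> "GridSpec":
        """Random France-like layout: latitudes 43–50 °N, mixed continentality."""
        rng = np.random.default_rng(seed)
        return cls(
            latitudes=rng.uniform(43.0, 50.0, n_cells),
            continentality=rng.uniform(0.0, 1.0, n_cells),
        )


def _seasonal_params(lat: float, cont: float, *,
                     mean_shift: float = 0.0, amp_shift: float = 0.0,
                     precip_scale: float = 1.0) -> dict:
    """Per-cell seasonal climate parameters from latitude and continentality.

    Annual-mean temperature decreases with latitude and continentality;
    seasonal amplitude grows with continentality (maritime damping).
    """
    mean_t = 13.5 - 0.45 * (lat - 43.0) - 3.0 * cont + mean_shift
    amp_t = 6.5 + 3.0 * cont + amp_shift
    diurnal = 4.0 + 2.0 * cont           # half-range around tavg, seasonal below
    wet_scale = 4.5 * precip_scale       # gamma scale, mm on wet days
    return dict(mean_t=mean_t, amp_t=amp_t, diurnal=diurnal, wet_scale=wet_scale)


def _synth_cell(dates: pd.DatetimeIndex, lat: float, params: dict,
                rng: np.random.Generator) -> pd.DataFrame:
    """One cell's daily series under the stochastic weather model."""
    n = len(dates)
    doy = dates.dayofyear.values.astype(float)
    # seasonal mean temperature, coldest ~mid January (DOY 15)
    seas = params["mean_t"] - params["amp_t"] * np.cos(2 * np.pi * (doy - 15.0) / 365.25)

    # AR(1) anomalies on tavg
    eps = rng.normal(0.0, AR1_SIGMA * np.sqrt(1 - AR1_RHO**2), n)
    anom = np.empty(n)
    anom[0] = rng.normal(0.0, AR1_SIGMA)
    for i in range(1, n):
        anom[i] = AR1_RHO * anom[i - 1] + eps[i]
    tavg = seas + anom

    # seasonal diurnal range: wider in summer
    half_range = params["diurnal"] * (0.75 + 0.25 * np.sin(2 * np.pi * (doy - 105.0) / 365.25))
    half_range = np.maximum(half_range, 1.0)
    tmin = tavg - half_range
    tmax = tavg + half_range

    # two-state Markov occurrence, gamma amounts (slightly wetter in winter)
    wet = np.empty(n, dtype=bool)
    u = rng.random(n)
    wet[0] = u[0] < P_WET_GIVEN_DRY / (1 - P_WET_GIVEN_WET + P_WET_GIVEN_DRY)
    for i in range(1, n):
        p = P_WET_GIVEN_WET if wet[i - 1] else P_WET_GIVEN_DRY
        wet[i] = u[i] < p
    season_wet = 1.0 + 0.3 * np.cos(2 * np.pi * (doy - 15.0) / 365.25)
    amounts = rng.gamma(GAMMA_SHAPE, params["wet_scale"], n) * season_wet
    precip = np.where(wet, amounts, 0.0)

    # clear-sky seasonal radiation damped by clouds on wet days (daily mean W/m²)
    clear = 250.0 - 160.0 * np.cos(2 * np.pi * (doy - 172.0) / 365.25) * np.sign(lat)
    clear = np.maximum(clear, 30.0)
    cloud = np.where(wet, rng.uniform(0.25, 0.55, n), rng.uniform(0.65, 1.0, n))
    radiation = clear * cloud

    pet = pet_hargreaves(tmin, tmax, lat, doy)

    return pd.DataFrame(
        {"tmin": tmin, "tmax": tmax, "tavg": tavg, "precip": precip,
         "pet": pet, "radiation": radiation},
        index=dates,
    )


def generate_reference_climate(grid_spec: GridSpec, n_years: int, seed: int,
                               start_year: int = 1991, **regime_kw) -> WeatherGrid:
    """Generate a reference-period weather grid.

    The calendar runs 1 Jan ``start_year`` through 31 Dec of the final year,
    so every harvest season in [start_year+1, start_year+n_years] has full
    coverage from 1 Jan of its sowing year (as the water-balance
    initialization requires). Deterministic for a fixed seed.
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    dates = pd.date_range(f"{start_year}-01-01", f"{start_year + n_years}-12-31", freq="D")
    root = np.random.default_rng(seed)
    frames = {}
    for i, cid in enumerate(grid_spec.cell_ids):
        rng = np.random.default_rng(root.integers(2**31))
        params = _seasonal_params(grid_spec.latitudes[i], grid_spec.continentality[i],
                                  **regime_kw)
        frames[cid] = _synth_cell(dates, grid_spec.latitudes[i], params, rng)
    frame = pd.concat(frames, names=["cell_id", "date"])
    cells = pd.DataFrame(
        {"lat": grid_spec.latitudes, "lon": np.asarray(grid_spec.longitudes, float)},
        index=pd.Index(grid_spec.cell_ids, name="cell_id"),
    )
    return WeatherGrid(frame=frame, cells=cells)


def apply_scenario(grid: WeatherGrid, scenario: ClimateScenarioSpec) -> WeatherGrid:
    """Perturb a weather grid with monthly deltas and precipitation factors.

    Temperatures are shifted additively (tmin, tavg, tmax alike, preserving
    their ordering); precipitation is scaled; PET is either recomputed with
    Hargreaves from the shifted temperatures or scaled.
    """
    frame = grid.frame.copy()
    months = frame.index.get_level_values("date").month.values
    dt = np.asarray(scenario.delta_t_monthly)[months - 1]
    ps = np.asarray(scenario.precip_scale_monthly)[months - 1]
    for var in ("tmin", "tmax", "tavg"):
        frame[var] = frame[var].values + dt
    frame["precip"] = frame["precip"].values * ps

    if scenario.pet_response == "recompute_hargreaves":
        doy = frame.index.get_level_values("date").dayofyear.values
        lats = grid.cells["lat"].reindex(frame.index.get_level_values("cell_id")).values
        # Ra depends on latitude; vectorized per-row
        frame["pet"] = _hargreaves_rows(frame["tmin"].values, frame["tmax"].values, lats, doy)
    else:
        frame["pet"] = frame["pet"].values * scenario.pet_scale
    return WeatherGrid(frame=frame, cells=grid.cells.copy())


def _hargreaves_rows(tmin, tmax, lats, doy):
    from .weather import extraterrestrial_radiation

    phi = np.deg2rad(lats)
    d = np.asarray(doy, float)
    dr = 1.0 + 0.033 * np.cos(2 * np.pi * d / 365.0)
    delta = 0.409 * np.sin(2 * np.pi * d / 365.0 - 1.39)
    cos_ws = np.clip(-np.tan(phi) * np.tan(delta), -1.0, 1.0)
    ws = np.arccos(cos_ws)
    ra = (24 * 60 / np.pi) * 0.0820 * dr * (
        ws * np.sin(phi) * np.sin(delta) + np.cos(phi) * np.cos(delta) * np.sin(ws)
    )
    ra = np.maximum(ra, 0.0)
    pet = 0.0023 * (ra / 2.45) * (0.5 * (tmin + tmax) + 17.8) * np.sqrt(
        np.maximum(tmax - tmin, 0.0)
    )
    return np.maximum(pet, 0.0)


# ---------------------------------------------------------------------------
# zoning testbeds

#: contrasting climate regimes; (mean_shift °C, amp_shift °C, precip_scale)
REGIME_PRESETS = [
    ("mediterranean", dict(mean_shift=+3.5, amp_shift=-1.0, precip_scale=0.55)),
    ("oceanic_mild", dict(mean_shift=+1.5, amp_shift=-2.0, precip_scale=1.25)),
    ("continental_cold", dict(mean_shift=-2.5, amp_shift=+3.5, precip_scale=0.9)),
    ("montane", dict(mean_shift=-5.0, amp_shift=+2.0, precip_scale=1.4)),
    ("hot_dry", dict(mean_shift=+5.0, amp_shift=+1.0, precip_scale=0.4)),
    ("wet_cool", dict(mean_shift=-1.0, amp_shift=-1.5, precip_scale=1.8)),
    ("semi_continental", dict(mean_shift=0.0, amp_shift=+1.5, precip_scale=0.7)),
]


def make_cluster_testbed(n_cells_per_zone: int, n_zones: int, n_years: int,
                         seed: int, start_year: int = 1991):
    """Weather grid drawn from ``n_zones`` contrasting climate regimes.

    Returns ``(WeatherGrid, labels)`` where ``labels`` is a Series mapping
    cell_id to the true regime index (0..n_zones-1). Regimes differ jointly
    in seasonal mean, amplitude and precipitation so that the separation
    survives the indicator transform.
    """
    if n_zones < 2:
        raise ValueError("n_zones must be >= 2")
    if n_zones > len(REGIME_PRESETS):
        raise ValueError(f"at most {len(REGIME_PRESETS)} regimes available")
    root = np.random.default_rng(seed)
    grids, labels = [], {}
    for z in range(n_zones):
        _, kw = REGIME_PRESETS[z]
        spec = GridSpec(
            latitudes=root.uniform(44.0, 49.0, n_cells_per_zone),
            continentality=root.uniform(0.3, 0.7, n_cells_per_zone),
            cell_ids=[f"z{z}_{i:03d}" for i in range(n_cells_per_zone)],
        )
        g = generate_reference_climate(spec, n_years, int(root.integers(2**31)),
                                       start_year=start_year, **kw)
        grids.append(g)
        for cid in spec.cell_ids:
            labels[cid] = z
    frame = pd.concat([g.frame for g in grids])
    cells = pd.concat([g.cells for g in grids])
    grid = WeatherGrid(frame=frame, cells=cells)
    return grid, pd.Series(labels, name="zone").rename_axis("cell_id")


def make_score_testbed(n_cells: int, n_zones: int, seed: int,
                       n_indicators: int | None = None, period_length: int = 30,
                       separation: int = 20, noise_sd: float = 1.5):
    """Integer risk-score matrix drawn around well-separated zone centroids.

    Emulates the per-cell risk-year counts (0..period_length) that feed the
    zoning step. Centroids follow a block design: each zone's profile is
    elevated by ``separation`` score units in its own two indicators
    (default 20, on a base of 4), so every pair of zone profiles differs by
    the full separation in at least two indicators and all pairs are
    equidistant — the geometry in which the within-cluster-inertia curve
    has a clean elbow at the true zone count. Small Gaussian noise
    (``noise_sd`` score units) is added and scores are rounded and clipped
    to [0, period_length]. Returns ``(scores DataFrame, labels Series)``.
    """
    if n_zones < 2:
        raise ValueError("n_zones must be >= 2")
    if n_indicators is None:
        n_indicators = 2 * n_zones
    if n_indicators < 2 * n_zones:
        raise ValueError("block design needs n_indicators >= 2 * n_zones")
    rng = np.random.default_rng(seed)
    base, high = 4, 4 + separation
    if high > period_length:
        raise ValueError("separation exceeds the score range")
    centroids = np.full((n_zones, n_indicators), base, dtype=float)
    for z in range(n_zones):
        centroids[z, 2 * z] = high
        centroids[z, 2 * z + 1] = high
    zone_of = rng.integers(0, n_zones, n_cells)
    noise = rng.normal(0.0, noise_sd, size=(n_cells, n_indicators))
    scores = np.clip(np.rint(centroids[zone_of] + noise), 0, period_length).astype(int)
    ids = pd.Index([f"c{i:04d}" for i in range(n_cells)], name="cell_id")
    cols = [f"ind{j:02d}" for j in range(n_indicators)]
    return (pd.DataFrame(scores, index=ids, columns=cols),
            pd.Series(zone_of, index=ids, name="zone"))
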