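"""Photo-vernal thermal-time simulation of winter-wheat development.

The model advances the crop through the BBCH-anchored stages

    SO (sowing) → EM (emergence, BBCH 10) → E1 (ear at 1 cm, BBCH 30)
    → FL (flag leaf, BBCH 39) → AN (anthesis, BBCH 65)
    → GM (grain maturity, BBCH 89)

by accumulating a daily effective thermal-time increment

    dD = GDD(tavg) × f_photoperiod × f_vernalization

where GDD = max(0, tavg − t_base) is the growing-degree-day increment,
f_photoperiod is a linear ramp between a base and an optimal day length
(long-day response, applied from emergence to anthesis), and
f_vernalization is the fraction of the cultivar's cold requirement
satisfied so far (applied to the juvenile phase EM→E1 only). Each phase
has a fixed thermal target in °C·days; a stage falls on the first day the
phase's cumulative effective increment reaches its target.

Vernalization accumulates effective days on cool days (full credit on the
0–10 °C plateau, declining to zero at the pause threshold), is paused by
warm days, and is partially reversed (devernalization) by sustained heat
above 20 °C until saturation is reached. Sowing is fixed at 15 October of
the year preceding harvest.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .weather import WeatherGrid, daylength

__all__ = [
    "STAGES",
    "PHASES",
    "PhenoParams",
    "StageDates",
    "CoverageError",
    "thermal_increment",
    "photoperiod_factor",
    "vernalization_step",
    "vernalization_factor",
    "simulate_stages",
    "simulate_grid",
    "evaluate_stage_errors",
]

STAGES = ("EM", "E1", "FL", "AN", "GM")
PHASES = ("SO-EM", "EM-E1", "E1-FL", "FL-AN", "AN-GM")


class CoverageError(ValueError):
    """Weather series does not cover the required simulation window."""


@dataclasses.dataclass
class PhenoParams:
    """Cultivar development parameters (defaults: Talent-like winter wheat,
    medium precocity, large cold requirement; placeholders for calibration).

    Thermal targets are °C·days per phase. Photoperiod: zero development
    below ``p_base`` hours, full above ``p_opt``. Vernalization: ``v_sat``
    effective days to saturation; daily effectiveness is 1 on
    [vern_t_lo, vern_t_plateau] °C, declines linearly to 0 at
    ``vern_t_pause`` and is 0 above it; days above ``devern_threshold``
    remove ``devern_rate`` effective days until saturation. ``vern_tmin_floor``
    additionally requires tmin ≥ 0 °C for a day to vernalize.
    """

    t_base: float = 0.0
    sowing_month_day: tuple[int, int] = (10, 15)
    stage_thermal_targets: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {
            "SO-EM": 150.0, "EM-E1": 200.0, "E1-FL": 250.0,
            "FL-AN": 180.0, "AN-GM": 800.0,
        }
    )
    p_base: float = 6.6
    p_opt: float = 16.0
    photoperiod_phases: tuple[str, ...] = ("EM-E1", "E1-FL", "FL-AN")
    v_sat: float = 50.0
    vern_t_lo: float = 0.0
    vern_t_plateau: float = 10.0
    vern_t_pause: float = 17.0
    devern_threshold: float = 20.0
    devern_rate: float = 0.5
    vern_tmin_floor: bool = True
    vernalization_phases: tuple[str, ...] = ("EM-E1",)
    season_cutoff: int = 365
    factor_combination: str = "multiplicative"  # or "min"

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.stage_thermal_targets.values()):
            raise ValueError("thermal targets must be positive")
        if not self.p_base < self.p_opt:
            raise ValueError("p_base must be < p_opt")
        if self.v_sat <= 0:
            raise ValueError("v_sat must be positive")
        if self.devern_threshold < self.vern_t_pause:
            raise ValueError("devern_threshold must be >= vernalization pause threshold")

    @classmethod
    def from_yaml(cls, path) -> "PhenoParams":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "sowing_month_day" in raw:
            raw["sowing_month_day"] = tuple(raw["sowing_month_day"])
        for key in ("photoperiod_phases", "vernalization_phases"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["sowing_month_day"] = list(self.sowing_month_day)
        d["stage_thermal_targets"] = dict(self.stage_thermal_targets)
        for key in ("photoperiod_phases", "vernalization_phases"):
            d[key] = list(d[key])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    def sowing_date(self, harvest_year: int) -> pd.Timestamp:
        m, d = self.sowing_month_day
        return pd.Timestamp(harvest_year - 1, m, d)


# ---------------------------------------------------------------------------
# elementary responses


def thermal_increment(tavg, t_base: float = 0.0):
    """Daily growing-degree-day increment max(0, tavg − t_base), °C·days."""
    return np.maximum(0.0, np.asarray(tavg, dtype=float) - t_base)


def photoperiod_factor(daylength_h, p_base: float, p_opt: float):
    """Long-day photoperiod response in [0, 1]: 0 at/below ``p_base`` hours,
    1 at/above ``p_opt``, linear in between."""
    if not p_base < p_opt:
        raise ValueError("p_base must be < p_opt")
    dl = np.asarray(daylength_h, dtype=float)
    return np.clip((dl - p_base) / (p_opt - p_base), 0.0, 1.0)


def _vern_effectiveness(tavg: np.ndarray, p: PhenoParams) -> np.ndarray:
    """Daily vernalization credit in [0, 1] from mean temperature."""
    t = np.asarray(tavg, dtype=float)
    eff = np.where(
        (t >= p.vern_t_lo) & (t <= p.vern_t_plateau),
        1.0,
        np.where(
            (t > p.vern_t_plateau) & (t < p.vern_t_pause),
            (p.vern_t_pause - t) / (p.vern_t_pause - p.vern_t_plateau),
            0.0,
        ),
    )
    return eff


def vernalization_step(state: float, tavg: float, params: PhenoParams,
                       tmin: float | None = None) -> float:
    """Advance the vernalization state by one day.

    Cool days add their effectiveness; days above the devernalization
    threshold subtract ``devern_rate`` while the requirement is still
    unsaturated. The state stays within [0, v_sat].
    """
    if state < 0:
        raise ValueError("vernalization state must be non-negative")
    eff = float(_vern_effectiveness(np.array([tavg]), params)[0])
    if params.vern_tmin_floor and tmin is not None and tmin < params.vern_t_lo:
        eff = 0.0
    new = state + eff
    if tavg > params.devern_threshold and state < params.v_sat:
        new -= params.devern_rate
    return float(np.clip(new, 0.0, params.v_sat))


def vernalization_factor(state: float, v_sat: float) -> float:
    """Fraction of the cold requirement satisfied: min(1, state / v_sat)."""
    if v_sat <= 0:
        raise ValueError("v_sat must be positive")
    return float(min(1.0, max(0.0, state) / v_sat))


def _vern_state_series(tavg: np.ndarray, tmin: np.ndarray, p: PhenoParams) -> np.ndarray:
    """Vernalization state after each day, starting from 0 at sowing."""
    eff = _vern_effectiveness(tavg, p)
    if p.vern_tmin_floor:
        eff = np.where(tmin < p.vern_t_lo, 0.0, eff)
    devern = tavg > p.devern_threshold
    out = np.empty(len(tavg))
    state = 0.0
    for i in range(len(tavg)):
        new = state + eff[i]
        if devern[i] and state < p.v_sat:
            new -= p.devern_rate
        state = min(max(new, 0.0), p.v_sat)
        out[i] = state
    return out


# ---------------------------------------------------------------------------
# stage containers


@dataclasses.dataclass
class StageDates:
    """Simulated stage dates per (cell_id, season).

    ``frame`` is indexed by a (cell_id, season) MultiIndex — season is the
    harvest year — with Timestamp columns sowing_date, EM, E1, FL, AN, GM
    (NaT where a stage was not reached) and a boolean ``completed`` column
    (grain maturity reached within the season cutoff).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        comp = self.frame[self.frame["completed"]]
        for a, b in zip(("sowing_date",) + STAGES[:-1], STAGES):
            if (comp[b] <= comp[a]).any():
                bad = comp.index[comp[b] <= comp[a]][0]
                raise ValueError(f"stage ordering violated ({a} !< {b}) at {bad}")

    def doy(self, stage: str) -> pd.Series:
        """Day-of-year of a stage (NaN where missing)."""
        return self.frame[stage].dt.dayofyear.astype(float)

    def median_doy(self, stage: str) -> pd.Series:
        """Per-cell median stage DOY over completed seasons."""
        d = self.doy(stage)[self.frame["completed"]]
        return d.groupby(level="cell_id").median()

    def to_csv(self, path) -> None:
        long = self.frame.reset_index().melt(
            id_vars=["cell_id", "season", "sowing_date", "completed"],
            value_vars=list(STAGES), var_name="stage", value_name="date",
        )
        long["doy"] = long["date"].dt.dayofyear
        long["date"] = long["date"].dt.strftime("%Y-%m-%d")
        long["sowing_date"] = long["sowing_date"].dt.strftime("%Y-%m-%d")
        long.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "StageDates":
        long = pd.read_csv(path, parse_dates=["date", "sowing_date"])
        wide = long.pivot_table(index=["cell_id", "season"], columns="stage",
                                values="date", aggfunc="first")
        meta = long.groupby(["cell_id", "season"])[["sowing_date", "completed"]].first()
        frame = meta.join(wide)[["sowing_date", *STAGES, "completed"]]
        return cls(frame=frame)


# ---------------------------------------------------------------------------
# simulation


def simulate_stages(cell_weather: pd.DataFrame, params: PhenoParams,
                    harvest_year: int, latitude: float) -> pd.Series:
    """Simulate one cell-season; returns a row for a StageDates frame.

    ``cell_weather`` is a date-indexed daily frame with tavg and tmin.
    Accumulation for each phase starts the day after the phase-opening
    stage (the day after sowing for SO→EM); a stage falls on the first day
    the phase's cumulative effective thermal time reaches its target.
    """
    sowing = params.sowing_date(harvest_year)
    start = sowing + pd.Timedelta(days=1)
    end = sowing + pd.Timedelta(days=params.season_cutoff)
    idx = cell_weather.index
    if idx[0] > start:
        raise CoverageError(
            f"weather starts {idx[0].date()}, need coverage from {start.date()}"
        )
    # a calendar truncated before sowing + cutoff is tolerated: stages not
    # reached by the series end are simply unreached (incomplete cycle)
    win = cell_weather.loc[start:end]
    tavg = win["tavg"].to_numpy(dtype=float)
    tmin = win["tmin"].to_numpy(dtype=float)
    doy = win.index.dayofyear.to_numpy()

    gdd = thermal_increment(tavg, params.t_base)
    photo = photoperiod_factor(daylength(latitude, doy), params.p_base, params.p_opt)
    vern = np.minimum(1.0, _vern_state_series(tavg, tmin, params) / params.v_sat)

    def rate(phase: str) -> np.ndarray:
        factors = [gdd]
        if phase in params.photoperiod_phases:
            factors.append(photo)
        if phase in params.vernalization_phases:
            factors.append(vern)
        if params.factor_combination == "min" and len(factors) > 1:
            return factors[0] * np.minimum.reduce(factors[1:])
        out = factors[0]
        for f in factors[1:]:
            out = out * f
        return out

    row = {"sowing_date": sowing, "completed": True}
    pos = 0
    for phase, stage in zip(PHASES, STAGES):
        if not row["completed"]:
            row[stage] = pd.NaT
            continue
        r = rate(phase)[pos:]
        cum = np.cumsum(r)
        target = params.stage_thermal_targets[phase]
        j = int(np.searchsorted(cum, target - 1e-9))
        if j >= len(cum):
            row[stage] = pd.NaT
            row["completed"] = False
        else:
            pos += j
            row[stage] = win.index[pos]
            pos += 1
    return pd.Series(row)


def simulate_grid(grid: WeatherGrid, params: PhenoParams,
                  seasons: Sequence[int]) -> StageDates:
    """Simulate all cells over the given harvest years.

    Incomplete cycles (grain maturity not reached within the cutoff) are
    flagged, not dropped.
    """
    rows = {}
    for cid in grid.cell_ids:
        cw = grid.cell(cid)
        lat = grid.latitude(cid)
        for season in seasons:
            rows[(cid, season)] = simulate_stages(cw, params, season, lat)
    frame = pd.DataFrame(rows).T
    frame.index.names = ["cell_id", "season"]
    frame["completed"] = frame["completed"].astype(bool)
    for col in ("sowing_date", *STAGES):
        frame[col] = pd.to_datetime(frame[col])
    return StageDates(frame=frame[["sowing_date", *STAGES, "completed"]])


def evaluate_stage_errors(simulated: StageDates,
                          observed: pd.DataFrame) -> pd.DataFrame:
    """Per-stage mean error and RMSE (days) of simulated vs observed DOY.

    ``observed`` has columns cell_id, season, stage, doy. Cell-seasons whose
    simulated cycle did not complete are excluded from the comparison.
    """
    sim = simulated.frame[simulated.frame["completed"]]
    rows = []
    for stage in STAGES:
        obs = observed[observed["stage"] == stage].set_index(["cell_id", "season"])["doy"]
        common = sim.index.intersection(obs.index)
        if len(common) == 0:
            continue
        err = sim.loc[common, stage].dt.dayofyear.astype(float) - obs.loc[common]
        rows.append({"stage": stage, "n": len(err),
                     "mean_error": float(err.mean()),
                     "rmse": float(np.sqrt((err**2).mean()))})
    if not rows:
        raise ValueError("no overlapping (cell, season, stage) keys to compare")
    return pd.DataFrame(rows).set_index("stage")
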