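"""Declarative ecoclimatic-indicator engine.

An ecoclimatic indicator is built in three steps: (1) the crop cycle is cut
into phenological phases (SO–EM, EM–E1, E1–FL, FL–AN, AN–GM, possibly with
day offsets around a stage), (2) a raw stress metric is computed inside the
phase window — a count of threshold-exceeding days, the longest run of such
days, or a sum such as the phase climatic water balance P−PET — and (3) the
raw value is mapped onto a common damage scale in [0, 1] through a
normalization function (negative exponential or sigmoid), where 1 means no
stress during the phase and 0 maximal stress.

Drought indicators are purely climatic: the cumulative P−PET balance is
initialized on 1 January of the sowing year, summed per phase, and the
sigmoid midpoint of each drought indicator is calibrated as the first
quartile of its pooled distribution (all cells × all reference seasons)
and then frozen for use on future periods.

The default catalog encodes one indicator per documented stress mechanism
(cold, frost, heat, warm nights, flood, wet runs, drought per phase); it is
serializable to YAML so a site-specific parameterization can replace it
without code change.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .phenology import STAGES, StageDates
from .weather import WeatherGrid

__all__ = [
    "Condition",
    "WindowSpec",
    "NormalizationSpec",
    "IndicatorSpec",
    "IndicatorPanel",
    "phase_window",
    "count_condition_days",
    "max_run_length",
    "water_balance_series",
    "phase_deficit",
    "drought_threshold_q1",
    "normalize",
    "compute_panel",
    "default_catalog",
    "catalog_to_yaml",
    "catalog_from_yaml",
]

FAMILIES = ("cold", "heat", "water_deficit", "water_excess")
#: variables usable in conditions; p_minus_pet is derived on the fly
CONDITION_VARIABLES = ("tmin", "tmax", "tavg", "precip", "pet", "radiation", "p_minus_pet")


# ---------------------------------------------------------------------------
# specs


@dataclasses.dataclass(frozen=True)
class Condition:
    """One comparison clause; clauses of an indicator are ANDed.

    ``op`` is one of lt, le, gt, ge, between (strict two-sided band,
    lo < x < hi given as ``threshold=(lo, hi)``).
    """

    variable: str
    op: str
    threshold: float | tuple[float, float]

    def __post_init__(self) -> None:
        if self.variable not in CONDITION_VARIABLES:
            raise ValueError(f"unknown condition variable {self.variable!r}")
        if self.op not in {"lt", "le", "gt", "ge", "between"}:
            raise ValueError(f"unknown comparator {self.op!r}")
        thr = np.asarray(self.threshold, dtype=float)
        if not np.isfinite(thr).all():
            raise ValueError("condition thresholds must be finite")

    def mask(self, frame: pd.DataFrame) -> np.ndarray:
        x = frame[self.variable].to_numpy(dtype=float)
        if self.op == "lt":
            return x < self.threshold
        if self.op == "le":
            return x <= self.threshold
        if self.op == "gt":
            return x > self.threshold
        if self.op == "ge":
            return x >= self.threshold
        lo, hi = self.threshold
        return (x > lo) & (x < hi)


@dataclasses.dataclass(frozen=True)
class WindowSpec:
    """Phase window anchored on stages, with day offsets.

    Anchors are SO (sowing) or any of EM, E1, FL, AN, GM; e.g.
    ``WindowSpec("FL", -5, "FL", +5)`` is the 11-day meiosis proxy window.
    """

    start_stage: str
    start_offset: int = 0
    end_stage: str = ""
    end_offset: int = 0

    def __post_init__(self) -> None:
        valid = {"SO", *STAGES}
        if self.start_stage not in valid or self.end_stage not in valid:
            raise ValueError(f"window anchors must be in {sorted(valid)}")


@dataclasses.dataclass
class NormalizationSpec:
    """Damage normalization onto [0, 1] (1 = no stress, 0 = maximal).

    negative_exponential: n = exp(−k·raw) for raw ≥ 0; ``k`` may be given
    directly or derived from an anchor (x_ref, n_ref) as k = −ln(n_ref)/x_ref.

    sigmoid: n = 1 / (1 + exp(−s·(raw − x0))). With s > 0 larger raw means
    less stress (the drought convention: raw is the phase P−PET balance).
    ``calibrate="q1"`` marks the midpoint/slope as fitted on the reference
    period (x0 = pooled first quartile; s = ln 9 / (median − Q1), so a
    median year scores 0.9).
    """

    kind: str
    k: float | None = None
    anchor: tuple[float, float] | None = None
    x0: float | None = None
    s: float | None = None
    calibrate: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in {"negative_exponential", "sigmoid"}:
            raise ValueError(f"unknown normalization kind {self.kind!r}")
        if self.kind == "negative_exponential":
            if self.k is None:
                if self.anchor is None:
                    raise ValueError("exponential normalization needs k or an anchor")
                x_ref, n_ref = self.anchor
                if not 0 < n_ref < 1 or x_ref <= 0:
                    raise ValueError("anchor needs x_ref > 0 and n_ref in (0,1)")
                self.k = -math.log(n_ref) / x_ref
            if self.k <= 0:
                raise ValueError("exponential rate k must be positive")
        else:
            if self.calibrate is None and (self.x0 is None or self.s is None or self.s == 0):
                raise ValueError("sigmoid needs x0 and nonzero s, or calibrate='q1'")


def normalize(raw: float, spec: NormalizationSpec) -> float:
    """Apply a normalization function; result clamped to [0, 1]."""
    if spec.kind == "negative_exponential":
        if raw < 0:
            raise ValueError("negative raw value for exponential normalization")
        return float(np.clip(math.exp(-spec.k * raw), 0.0, 1.0))
    if spec.x0 is None or spec.s is None:
        raise ValueError("sigmoid normalization is uncalibrated (run reference calibration)")
    z = spec.s * (raw - spec.x0)
    # guard exp overflow for extreme deficits
    if z < -700:
        return 0.0
    return float(np.clip(1.0 / (1.0 + math.exp(-z)), 0.0, 1.0))


@dataclasses.dataclass
class IndicatorSpec:
    """One declarative ecoclimatic indicator."""

    id: str
    family: str
    window: WindowSpec
    aggregator: str  # count_days | max_run_length | sum
    conditions: tuple[Condition, ...] = ()
    variable: str | None = None  # for aggregator == "sum"
    normalization: NormalizationSpec = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.aggregator not in {"count_days", "max_run_length", "sum"}:
            raise ValueError(f"unknown aggregator {self.aggregator!r}")
        if self.aggregator == "sum" and self.variable is None:
            raise ValueError("sum aggregator needs a variable")
        if self.aggregator != "sum" and not self.conditions:
            raise ValueError("count/run aggregators need at least one condition")


# ---------------------------------------------------------------------------
# raw metrics


def phase_window(stage_row: pd.Series, spec: WindowSpec):
    """Closed calendar interval [start, end] for one cell-season.

    ``stage_row`` is one row of a StageDates frame. Returns None when any
    anchor stage is missing (incomplete cycle) — a missing-window signal,
    not an error.
    """
    def anchor(stage: str, offset: int):
        date = stage_row["sowing_date"] if stage == "SO" else stage_row[stage]
        if pd.isna(date):
            return None
        return date + pd.Timedelta(days=offset)

    start = anchor(spec.start_stage, spec.start_offset)
    end = anchor(spec.end_stage, spec.end_offset)
    if start is None or end is None:
        return None
    if end < start:
        raise ValueError(f"window end {end.date()} precedes start {start.date()}")
    return start, end


def _condition_mask(frame: pd.DataFrame, conditions: Sequence[Condition]) -> np.ndarray:
    mask = np.ones(len(frame), dtype=bool)
    for c in conditions:
        mask &= c.mask(frame)
    return mask


def count_condition_days(frame: pd.DataFrame, conditions: Sequence[Condition]) -> int:
    """Number of days in the window satisfying every condition clause."""
    return int(_condition_mask(frame, conditions).sum())


def max_run_length(frame: pd.DataFrame, conditions: Sequence[Condition]) -> int:
    """Longest run of consecutive days satisfying every condition clause."""
    mask = _condition_mask(frame, conditions)
    best = cur = 0
    for hit in mask:
        cur = cur + 1 if hit else 0
        best = max(best, cur)
    return int(best)


def water_balance_series(cell_weather: pd.DataFrame, sowing_year: int) -> pd.Series:
    """Daily cumulative P−PET from 1 January of the sowing year.

    Initializing the balance at the start of the sowing year (not at
    sowing) lets the drought indicators carry over the pre-season water
    status of the atmosphere.
    """
    start = pd.Timestamp(sowing_year, 1, 1)
    if cell_weather.index[0] > start:
        raise ValueError(
            f"coverage starts {cell_weather.index[0].date()}, "
            f"need 1 Jan {sowing_year} for water-balance initialization"
        )
    daily = cell_weather.loc[start:, "precip"] - cell_weather.loc[start:, "pet"]
    return daily.cumsum()


def phase_deficit(cell_weather: pd.DataFrame, window) -> float:
    """Sum of daily P−PET (mm) inside the window; 0 for a degenerate window."""
    if window is None:
        return float("nan")
    start, end = window
    sl = cell_weather.loc[start:end]
    if len(sl) == 0:
        return 0.0
    return float((sl["precip"] - sl["pet"]).sum())


def drought_threshold_q1(raw_values) -> float:
    """First quartile (linear interpolation) of pooled phase P−PET sums."""
    vals = np.asarray(raw_values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < 4:
        raise ValueError(f"need at least 4 values to estimate a quartile, got {vals.size}")
    return float(np.quantile(vals, 0.25))


# ---------------------------------------------------------------------------
# panel computation


@dataclasses.dataclass
class IndicatorPanel:
    """Normalized indicator values per cell × season × indicator.

    ``values`` is a long frame with columns cell_id, season, indicator,
    raw, value; ``value`` is in [0, 1] or NaN where the phase window is
    missing (incomplete cycle). ``calibration`` maps drought indicator ids
    to their frozen (x0, s) sigmoid parameters.
    """

    values: pd.DataFrame
    catalog: list
    period: str = "reference"
    calibration: dict = dataclasses.field(default_factory=dict)

    def pivot(self, column: str = "value") -> pd.DataFrame:
        """(cell, season) × indicator matrix."""
        return self.values.pivot_table(index=["cell_id", "season"],
                                       columns="indicator", values=column,
                                       dropna=False)

    @property
    def seasons(self) -> list:
        return sorted(self.values["season"].unique())

    @property
    def families(self) -> dict:
        return {spec.id: spec.family for spec in self.catalog}

    def to_csv(self, path) -> None:
        self.values.to_csv(path, index=False, float_format="%.6g")


def _raw_value(cell_weather: pd.DataFrame, stage_row: pd.Series,
               spec: IndicatorSpec) -> float:
    window = phase_window(stage_row, spec.window)
    if window is None:
        return float("nan")
    start, end = window
    if start < cell_weather.index[0] or end > cell_weather.index[-1]:
        # window runs off the grid calendar (truncated season): missing,
        # consistent with the incomplete-cycle handling
        return float("nan")
    frame = cell_weather.loc[start:end]
    if spec.aggregator == "sum":
        if spec.variable == "p_minus_pet":
            return float((frame["precip"] - frame["pet"]).sum())
        return float(frame[spec.variable].sum())
    if any(c.variable == "p_minus_pet" for c in spec.conditions):
        frame = frame.assign(p_minus_pet=frame["precip"] - frame["pet"])
    if spec.aggregator == "count_days":
        return float(count_condition_days(frame, spec.conditions))
    return float(max_run_length(frame, spec.conditions))


def compute_panel(grid: WeatherGrid, stages: StageDates,
                  catalog: Sequence[IndicatorSpec],
                  calibration: Mapping[str, tuple[float, float]] | None = None,
                  calibrate: bool = False,
                  period: str = "reference") -> IndicatorPanel:
    """Raw and normalized indicator values for every cell × season × indicator.

    Sigmoid indicators marked ``calibrate='q1'`` need either ``calibrate=True``
    (reference period: fit midpoint = pooled Q1, slope = ln 9/(median − Q1),
    and freeze them) or a ``calibration`` mapping fitted previously — using
    them uncalibrated on a future period is an error.
    """
    ids = [s.id for s in catalog]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate indicator ids in catalog: {dup}")

    weather_by_cell = {cid: grid.cell(cid) for cid in grid.cell_ids}

    # pass 1: raw values
    records = []
    for (cid, season), stage_row in stages.frame.iterrows():
        cw = weather_by_cell[cid]
        for spec in catalog:
            records.append((cid, season, spec.id,
                            _raw_value(cw, stage_row, spec)))
    values = pd.DataFrame(records, columns=["cell_id", "season", "indicator", "raw"])

    # pass 2: calibrate / resolve drought sigmoids, then normalize
    calibration = dict(calibration or {})
    for spec in catalog:
        norm = spec.normalization
        if norm.kind == "sigmoid" and norm.calibrate == "q1":
            if spec.id in calibration:
                norm.x0, norm.s = calibration[spec.id]
            elif calibrate:
                raws = values.loc[values["indicator"] == spec.id, "raw"]
                q1 = drought_threshold_q1(raws)
                med = float(np.nanmedian(raws.to_numpy(dtype=float)))
                spread = med - q1
                s = math.log(9.0) / spread if spread > 1e-9 else 1.0
                norm.x0, norm.s = q1, s
                calibration[spec.id] = (q1, s)
            else:
                raise ValueError(
                    f"drought indicator {spec.id!r} is uncalibrated on period "
                    f"{period!r}; calibrate on the reference period first"
                )

    norm_by_id = {spec.id: spec.normalization for spec in catalog}
    values["value"] = [
        float("nan") if not np.isfinite(raw) else normalize(raw, norm_by_id[ind])
        for ind, raw in zip(values["indicator"], values["raw"])
    ]
    return IndicatorPanel(values=values, catalog=list(catalog),
                          period=period, calibration=calibration)


# ---------------------------------------------------------------------------
# default catalog


def _exp(x_ref: float, n_ref: float) -> NormalizationSpec:
    return NormalizationSpec(kind="negative_exponential", anchor=(x_ref, n_ref))


def _drought_sigmoid() -> NormalizationSpec:
    return NormalizationSpec(kind="sigmoid", calibrate="q1")


def default_catalog() -> list[IndicatorSpec]:
    """Default wheat indicator catalog, one entry per documented mechanism.

    Temperature/radiation thresholds follow the published stress physiology
    for winter wheat (flood kills the seed in 5 days; tavg < 2 °C runs delay
    emergence; tmin < −5 °C destroys coleoptiles; tavg < 5 °C slows seedling
    growth; tavg < 0 °C runs kill the stem apex; tmin < −8 °C kills the
    plantlet; vernalization pauses above ~17 °C and reverses above 20 °C;
    tmin > 12 °C nights raise tiller mortality from stem elongation to 10
    days past anthesis; tmin < 4 °C with radiation < 200 W/m² around
    meiosis cuts pollen fertility; tmax > 30 °C sterilizes pollen and
    shortens grain filling; tmin between −6 and −2 °C damages grain set;
    phase P−PET sums index drought). Exponential anchors place n = 0.5 at
    a severe raw value except where a published model output pins the
    curve (15 cold days → 0.55).
    """
    W = WindowSpec
    C = Condition
    cat = [
        # --- SO–EM
        IndicatorSpec("soem_flood_run", "water_excess", W("SO", 0, "EM"),
                      "max_run_length", (C("p_minus_pet", "gt", 0.0),), None, _exp(5, 0.5)),
        IndicatorSpec("soem_cold_run", "cold", W("SO", 0, "EM"),
                      "max_run_length", (C("tavg", "lt", 2.0),), None, _exp(4, 0.5)),
        IndicatorSpec("soem_frost_days", "cold", W("SO", 0, "EM"),
                      "count_days", (C("tmin", "lt", -5.0),), None, _exp(3, 0.5)),
        # --- EM–E1
        IndicatorSpec("eme1_cold_days", "cold", W("EM", 0, "E1"),
                      "count_days", (C("tavg", "lt", 5.0),), None, _exp(15, 0.55)),
        IndicatorSpec("eme1_freeze_run", "cold", W("EM", 0, "E1"),
                      "max_run_length", (C("tavg", "lt", 0.0),), None, _exp(4, 0.5)),
        IndicatorSpec("eme1_frost_days", "cold", W("EM", 0, "E1"),
                      "count_days", (C("tmin", "lt", -8.0),), None, _exp(3, 0.5)),
        IndicatorSpec("vern_pause_days", "heat", W("SO", 0, "E1"),
                      "count_days", (C("tavg", "gt", 17.0),), None, _exp(10, 0.5)),
        IndicatorSpec("devern_days", "heat", W("SO", 0, "E1"),
                      "count_days", (C("tavg", "gt", 20.0),), None, _exp(5, 0.5)),
        # --- E1–FL
        IndicatorSpec("e1fl_cold_days", "cold", W("E1", 0, "FL"),
                      "count_days", (C("tmin", "lt", 0.0),), None, _exp(5, 0.5)),
        IndicatorSpec("e1fl_frost_days", "cold", W("E1", 0, "FL"),
                      "count_days", (C("tmin", "lt", -5.0),), None, _exp(3, 0.5)),
        IndicatorSpec("meiosis_cold_lowrad", "cold", W("FL", -5, "FL", 5),
                      "count_days",
                      (C("tmin", "lt", 4.0), C("radiation", "lt", 200.0)),
                      None, _exp(3, 0.5)),
        IndicatorSpec("warm_nights", "heat", W("E1", 0, "AN", 10),
                      "count_days", (C("tmin", "gt", 12.0),), None, _exp(10, 0.5)),
        # --- FL–AN
        IndicatorSpec("flan_heat_days", "heat", W("FL", 0, "AN"),
                      "count_days", (C("tmax", "gt", 30.0),), None, _exp(3, 0.5)),
        # --- AN–GM
        IndicatorSpec("angm_heat_days", "heat", W("AN", 0, "GM"),
                      "count_days", (C("tmax", "gt", 30.0),), None, _exp(5, 0.5)),
        IndicatorSpec("angm_cold_band", "cold", W("AN", 0, "GM"),
                      "count_days", (C("tmin", "between", (-6.0, -2.0)),), None, _exp(2, 0.5)),
    ]
    # drought: phase P−PET sum, sigmoid calibrated on the reference period
    phase_windows = {
        "soem": W("SO", 0, "EM"), "eme1": W("EM", 0, "E1"),
        "e1fl": W("E1", 0, "FL"), "flan": W("FL", 0, "AN"), "angm": W("AN", 0, "GM"),
    }
    for tag, win in phase_windows.items():
        cat.append(IndicatorSpec(f"{tag}_drought", "water_deficit", win, "sum",
                                 (), "p_minus_pet", _drought_sigmoid()))
    # water excess: longest wet run (P−PET > 0) per post-emergence phase
    for tag, win in list(phase_windows.items())[1:]:
        cat.append(IndicatorSpec(f"{tag}_wet_run", "water_excess", win,
                                 "max_run_length", (C("p_minus_pet", "gt", 0.0),),
                                 None, _exp(10, 0.5)))
    return cat


# ---------------------------------------------------------------------------
# YAML round-trip


def catalog_to_yaml(catalog: Sequence[IndicatorSpec], path) -> None:
    items = []
    for s in catalog:
        d = {
            "id": s.id, "family": s.family,
            "window": {"start": s.window.start_stage, "start_offset": s.window.start_offset,
                       "end": s.window.end_stage, "end_offset": s.window.end_offset},
            "aggregator": s.aggregator,
            "conditions": [
                {"variable": c.variable, "op": c.op,
                 "threshold": list(c.threshold) if isinstance(c.threshold, tuple)
                 else c.threshold}
                for c in s.conditions
            ],
            "normalization": {k: v for k, v in dataclasses.asdict(s.normalization).items()
                              if v is not None},
        }
        if isinstance(d["normalization"].get("anchor"), tuple):
            d["normalization"]["anchor"] = list(d["normalization"]["anchor"])
        if s.variable:
            d["variable"] = s.variable
        items.append(d)
    with open(path, "w") as fh:
        yaml.safe_dump(items, fh, sort_keys=False)


def catalog_from_yaml(path) -> list[IndicatorSpec]:
    with open(path) as fh:
        items = yaml.safe_load(fh)
    out = []
    for d in items:
        w = d["window"]
        norm = dict(d["normalization"])
        if "anchor" in norm:
            norm["anchor"] = tuple(norm["anchor"])
        conds = tuple(
            Condition(c["variable"], c["op"],
                      tuple(c["threshold"]) if isinstance(c["threshold"], list)
                      else float(c["threshold"]))
            for c in d.get("conditions", [])
        )
        out.append(IndicatorSpec(
            id=d["id"], family=d["family"],
            window=WindowSpec(w["start"], w.get("start_offset", 0),
                              w["end"], w.get("end_offset", 0)),
            aggregator=d["aggregator"], conditions=conds,
            variable=d.get("variable"),
            normalization=NormalizationSpec(**norm),
        ))
    return out
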