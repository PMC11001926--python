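"""Shared fixtures: a small France-like reference grid and derived products.

Everything is generated programmatically and seeded; the session scope keeps
the phenology/indicator pipeline from being re-run per test.
"""

import numpy as np
import pandas as pd
import pytest

import wezmap as wz
from wezmap.phenology import STAGES

N_CELLS = 6
N_SEASONS = 7
SEASONS = list(range(1992, 1992 + N_SEASONS))


@pytest.fixture(scope="session")
def small_grid() -> wz.WeatherGrid:
    spec = wz.GridSpec.france_like(N_CELLS, seed=11)
    return wz.generate_reference_climate(spec, N_SEASONS + 1, seed=12)


@pytest.fixture(scope="session")
def params() -> wz.PhenoParams:
    return wz.PhenoParams()


@pytest.fixture(scope="session")
def stages(small_grid, params) -> wz.StageDates:
    return wz.simulate_grid(small_grid, params, SEASONS)


@pytest.fixture(scope="session")
def panel(small_grid, stages) -> wz.IndicatorPanel:
    return wz.compute_panel(small_grid, stages, wz.default_catalog(), calibrate=True)


@pytest.fixture(scope="session")
def risk_config() -> wz.RiskConfig:
    return wz.RiskConfig(period_length=N_SEASONS)


def make_constant_weather(start="1999-01-01", end="2000-08-31", *,
                          tavg=12.0, spread=4.0, precip=0.0, pet=1.0,
                          radiation=250.0, lat=47.0, cell_id="cell") -> wz.WeatherGrid:
    """Single-cell grid with constant daily weather (tmin/tmax = tavg ∓ spread)."""
    dates = pd.date_range(start, end, freq="D")
    frame = pd.DataFrame(
        {
            "tmin": tavg - spread, "tmax": tavg + spread, "tavg": tavg,
            "precip": precip, "pet": pet, "radiation": radiation,
        },
        index=pd.MultiIndex.from_product([[cell_id], dates], names=["cell_id", "date"]),
        dtype=float,
    )
    cells = pd.DataFrame({"lat": [lat], "lon": [2.0]},
                         index=pd.Index([cell_id], name="cell_id"))
    return wz.WeatherGrid(frame=frame, cells=cells)


def make_stage_row(cell_id="cell", season=2000) -> pd.DataFrame:
    """Hand-placed stage dates for one cell-season (completed cycle)."""
    row = pd.DataFrame(
        {
            "sowing_date": [pd.Timestamp("1999-10-15")],
            "EM": [pd.Timestamp("1999-11-01")],
            "E1": [pd.Timestamp("2000-03-01")],
            "FL": [pd.Timestamp("2000-04-15")],
            "AN": [pd.Timestamp("2000-05-10")],
            "GM": [pd.Timestamp("2000-07-01")],
            "completed": [True],
        },
        index=pd.MultiIndex.from_tuples([(cell_id, season)],
                                        names=["cell_id", "season"]),
    )
    return row


@pytest.fixture()
def fixed_stages() -> wz.StageDates:
    return wz.StageDates(frame=make_stage_row())


def brute_force_risk_counts(panel: wz.IndicatorPanel, threshold: float) -> pd.DataFrame:
    """Independent per-season loop over the panel values."""
    out = {}
    for (cid, ind), sub in panel.values.groupby(["cell_id", "indicator"]):
        n = 0
        for v in sub["value"]:
            if np.isfinite(v) and v < threshold:
                n += 1
        out[(cid, ind)] = n
    ser = pd.Series(out)
    return ser.unstack()
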