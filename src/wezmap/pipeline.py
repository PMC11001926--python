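"""End-to-end orchestration: weather → phenology → indicators → zoning →
risk summaries, with scenario projection inside reference-period zones.

The reference period defines everything that is later held fixed: drought
sigmoid calibration (pooled first-quartile midpoints) and the zone map.
Future periods re-run phenology and indicators under perturbed weather but
are summarized within the reference zones — zones are never re-fit on
future data.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import pandas as pd

from . import clustering, indicators, phenology, summary
from .clustering import RiskConfig, RiskScoreMatrix, WEZMap
from .indicators import IndicatorPanel, IndicatorSpec
from .phenology import PhenoParams, StageDates
from .synthetic import ClimateScenarioSpec, apply_scenario
from .weather import WeatherGrid

log = logging.getLogger("wezmap")

__all__ = ["PipelineResult", "run_reference", "run_projection", "full_pipeline"]


@dataclasses.dataclass
class PipelineResult:
    stages: StageDates
    panel: IndicatorPanel
    scores: RiskScoreMatrix
    zones: WEZMap
    zone_summary: pd.DataFrame
    cell_freqs: pd.DataFrame
    projections: dict = dataclasses.field(default_factory=dict)


def _seasons(grid: WeatherGrid, params: PhenoParams, period_length: int) -> list[int]:
    """Harvest years fully covered by the grid calendar."""
    cal = grid.calendar
    first = cal[0].year + 1  # water balance needs 1 Jan of the sowing year
    out = []
    for harvest in range(first, cal[-1].year + 1):
        end = params.sowing_date(harvest) + pd.Timedelta(days=params.season_cutoff)
        if end <= cal[-1]:
            out.append(harvest)
    if len(out) < period_length:
        raise ValueError(
            f"grid covers {len(out)} full seasons, need {period_length}"
        )
    return out[:period_length]


def run_reference(grid: WeatherGrid, params: PhenoParams,
                  catalog: Sequence[IndicatorSpec], config: RiskConfig,
                  k: int | None = None) -> PipelineResult:
    """Reference-period run: simulate stages, compute and calibrate the
    indicator panel, count risk years, prune, select k by elbow (unless
    given) and cluster into zones."""
    seasons = _seasons(grid, params, config.period_length)
    log.info("phenology: %d cells × %d seasons", grid.n_cells, len(seasons))
    stages = phenology.simulate_grid(grid, params, seasons)
    n_incomplete = int((~stages.frame["completed"]).sum())
    log.info("phenology: %d incomplete cycles", n_incomplete)

    panel = indicators.compute_panel(grid, stages, catalog, calibrate=True,
                                     period="reference")
    scores = clustering.count_risk_years(panel, config)
    scores = clustering.prune_zero_indicators(scores)
    log.info("indicators: %d retained, %d dropped",
             scores.scores.shape[1], len(scores.dropped_indicators))

    inertia = {}
    if k is None:
        k, inertia = clustering.elbow_select_k(scores, config)
        log.info("elbow: k = %d", k)
    zones = clustering.cluster_zones(scores, k, config, inertia_by_k=inertia)

    freqs = summary.family_frequency(panel, config=config)
    zsum = summary.summarize_zone(freqs, zones)
    return PipelineResult(stages=stages, panel=panel, scores=scores,
                          zones=zones, zone_summary=zsum, cell_freqs=freqs)


def run_projection(grid: WeatherGrid, params: PhenoParams,
                   catalog: Sequence[IndicatorSpec], config: RiskConfig,
                   reference: PipelineResult,
                   scenario: ClimateScenarioSpec | None = None,
                   period: str = "future") -> PipelineResult:
    """Future-period run inside frozen reference zones and calibration."""
    g = apply_scenario(grid, scenario) if scenario is not None else grid
    seasons = _seasons(g, params, config.period_length)
    stages = phenology.simulate_grid(g, params, seasons)
    panel = indicators.compute_panel(g, stages, catalog,
                                     calibration=reference.panel.calibration,
                                     period=period)
    scores = clustering.count_risk_years(panel, config)
    freqs = summary.family_frequency(panel, config=config)
    zsum = summary.summarize_zone(freqs, reference.zones)
    return PipelineResult(stages=stages, panel=panel, scores=scores,
                          zones=reference.zones, zone_summary=zsum,
                          cell_freqs=freqs)


def full_pipeline(reference_grid: WeatherGrid, params: PhenoParams,
                  catalog: Sequence[IndicatorSpec], config: RiskConfig,
                  scenarios: Mapping[str, ClimateScenarioSpec] | None = None,
                  k: int | None = None) -> PipelineResult:
    """Reference run plus optional scenario projections keyed by label."""
    result = run_reference(reference_grid, params, catalog, config, k=k)
    for label, scen in (scenarios or {}).items():
        log.info("projection: %s", label)
        result.projections[label] = run_projection(
            reference_grid, params, catalog, config, result,
            scenario=scen, period=label,
        )
    return result
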