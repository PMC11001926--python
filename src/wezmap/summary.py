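"""Temporal and ensemble aggregation of phenology-aware climate risks.

Indicators are grouped into four major risk families (cold, heat,
water_deficit, water_excess). Within a family, annual risk occurrences are
divided by the family's indicator count so every family carries equal
weight, then rescaled to a frequency in years per 10-year period. Zone
summaries add the mean frequency and the fraction of zone area affected;
ensemble spread across climate realizations is reported as the 5th, 50th
and 95th percentiles. Bivariate heat × water-deficit classes and
phenology-shift summaries support the compound-risk and timing analyses.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .clustering import RiskConfig, WEZMap
from .indicators import IndicatorPanel
from .phenology import STAGES, StageDates

__all__ = [
    "family_frequency",
    "summarize_zone",
    "ensemble_quantiles",
    "bivariate_classes",
    "stage_shift_summary",
]


def family_frequency(panel: IndicatorPanel,
                     families: Mapping[str, str] | None = None,
                     config: RiskConfig | None = None) -> pd.DataFrame:
    """Per-cell family risk frequency in years per decade.

    frequency = (risk occurrences summed over the family's indicators and
    seasons) / (number of indicators in the family) × 10 / period_length.
    Equal weighting by the indicator count means duplicating an indicator
    within a family leaves the frequency unchanged.
    """
    config = config or RiskConfig(period_length=len(panel.seasons))
    families = dict(families or panel.families)
    v = panel.values[panel.values["indicator"].isin(families)]
    if v.empty:
        raise ValueError("family map covers no indicator present in the panel")
    fam = v["indicator"].map(families)
    n_ind = pd.Series(families).value_counts()
    if (n_ind == 0).any():
        raise ValueError("empty risk family in the family map")
    risky = (v["value"] < config.risk_threshold).astype(float)
    occ = risky.groupby([v["cell_id"], fam.rename("family")]).sum().unstack(fill_value=0.0)
    freq = occ.div(n_ind.reindex(occ.columns), axis=1) * 10.0 / config.period_length
    return freq


def summarize_zone(freqs: pd.DataFrame, zones: WEZMap,
                   risk_presence_cutoff: float = 0.0,
                   pooled: bool = False) -> pd.DataFrame:
    """Zone-level family summary: mean frequency and affected-area fraction.

    ``freqs`` is the per-cell frequency table from :func:`family_frequency`.
    ``area_fraction`` is the share of zone cells whose frequency exceeds
    ``risk_presence_cutoff`` (default: any occurrence at all). With
    ``pooled=True`` the zone frequency is recomputed from pooled cell
    occurrences instead of averaging per-cell frequencies; with equal
    seasons per cell the two coincide.
    """
    common = freqs.index.intersection(zones.labels.index)
    f = freqs.loc[common]
    z = zones.labels.loc[common]
    mean = f.groupby(z).mean()  # pooled == cell average at equal weights
    frac = (f > risk_presence_cutoff).groupby(z).mean()
    out = pd.concat({"frequency": mean, "area_fraction": frac}, axis=1)
    out.columns.names = ["measure", "family"]
    out = out.stack(level="family", future_stack=True)
    out.index.names = ["zone", "family"]
    return out


def ensemble_quantiles(summaries: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """5/50/95 % quantiles across climate-ensemble members.

    Input frames share an index and columns (e.g. zone × family summaries,
    one per GCM-RCM realization); quantiles use linear interpolation, so a
    3-member ensemble's q5/q95 effectively track min/max.
    """
    if len(summaries) < 2:
        import warnings

        warnings.warn("single realization: degenerate ensemble quantiles")
    stack = np.stack([s.to_numpy(dtype=float) for s in summaries])
    qs = np.percentile(stack, [5, 50, 95], axis=0)
    base = summaries[0]
    out = {}
    for name, arr in zip(("q5", "q50", "q95"), qs):
        df = pd.DataFrame(arr, index=base.index, columns=base.columns)
        out[name] = df
    merged = pd.concat(out, axis=1, names=["quantile", *base.columns.names])
    return merged


def bivariate_classes(heat_freq: pd.Series, deficit_freq: pd.Series,
                      breaks: Sequence[float] = (1.0, 2.0, 3.0)) -> pd.DataFrame:
    """Per-cell (heat class, water-deficit class) pair by half-open binning.

    With breaks (b1..bn), class 0 is [0, b1), class i is [b_i, b_{i+1}),
    class n is [b_n, ∞). Default breaks at 1, 2, 3 years per decade.
    """
    breaks = np.asarray(breaks, dtype=float)
    if not (np.diff(breaks) > 0).all():
        raise ValueError("breaks must be strictly increasing")
    idx = heat_freq.index.intersection(deficit_freq.index)
    heat_cls = np.digitize(heat_freq.loc[idx].to_numpy(float), breaks, right=False)
    def_cls = np.digitize(deficit_freq.loc[idx].to_numpy(float), breaks, right=False)
    return pd.DataFrame({"heat_class": heat_cls, "deficit_class": def_cls}, index=idx)


def stage_shift_summary(stages_ref: StageDates, stages_future: StageDates,
                        zones: WEZMap) -> pd.DataFrame:
    """Zone × stage shift of median stage DOY, future minus reference (days).

    Negative values mean the stage advances. Medians are taken over the
    completed cell-seasons of each zone.
    """
    def zone_medians(stages: StageDates) -> pd.DataFrame:
        comp = stages.frame[stages.frame["completed"]]
        z = zones.labels.reindex(comp.index.get_level_values("cell_id")).to_numpy()
        rows = {}
        for stage in STAGES:
            doy = comp[stage].dt.dayofyear.astype(float)
            rows[stage] = doy.groupby(z).median()
        return pd.DataFrame(rows)

    ref = zone_medians(stages_ref)
    fut = zone_medians(stages_future)
    missing = set(ref.index).symmetric_difference(fut.index)
    if missing:
        raise KeyError(f"zones present in only one period: {sorted(missing)}")
    shift = fut - ref
    shift.index.name = "zone"
    return shift
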