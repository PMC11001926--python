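"""Risk-year scoring and K-means ecoclimatic zoning.

A risk year for an indicator is a season in which its normalized value
falls below a cutoff (default 0.7); counting risk years over a 30-season
reference period gives each cell an integer score in [0, 30] per
indicator. Indicators whose score is zero everywhere carry no spatial
signal and are removed. K-means on the remaining per-cell score profiles
partitions the grid into wheat ecoclimatic zones (WEZ); the cluster count
is chosen by the elbow rule — the k maximizing the second difference of
within-cluster inertia over the scanned range.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .indicators import IndicatorPanel

__all__ = [
    "RiskConfig",
    "RiskScoreMatrix",
    "WEZMap",
    "count_risk_years",
    "prune_zero_indicators",
    "elbow_select_k",
    "cluster_zones",
    "zone_intensity_table",
    "average_score_matrices",
    "INTENSITY_CLASSES",
]

#: intensity classes for zone characterization (risk years over the period)
INTENSITY_CLASSES = (
    (0, 5, "very_low"),
    (5, 10, "low"),
    (10, 15, "medium"),
    (15, 20, "high"),
    (20, 25, "very_high"),
)


@dataclasses.dataclass
class RiskConfig:
    risk_threshold: float = 0.7
    period_length: int = 30
    k_range: Sequence[int] = tuple(range(2, 13))
    kmeans_seed: int = 0
    n_init: int = 25
    max_missing_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.risk_threshold < 1:
            raise ValueError("risk_threshold must be in (0, 1)")
        if self.period_length < 1:
            raise ValueError("period_length must be >= 1")
        self.k_range = tuple(sorted(self.k_range))


@dataclasses.dataclass
class RiskScoreMatrix:
    """Per-cell risk-year counts: cells × indicators, integers in
    [0, period_length]; plus indicators dropped by pruning and cells
    excluded for excessive missingness."""

    scores: pd.DataFrame
    period_length: int
    dropped_indicators: dict = dataclasses.field(default_factory=dict)
    excluded_cells: list = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        s = self.scores
        if ((s < 0) | (s > self.period_length)).any().any():
            raise ValueError("risk scores outside [0, period_length]")


def count_risk_years(panel: IndicatorPanel, config: RiskConfig) -> RiskScoreMatrix:
    """Count seasons with normalized value below the risk threshold.

    The panel must cover exactly ``period_length`` seasons. Seasons with a
    missing value (incomplete phenological cycle) do not count as risk
    years; cells missing more than ``max_missing_fraction`` of their values
    are flagged for exclusion from clustering.
    """
    n_seasons = len(panel.seasons)
    if n_seasons != config.period_length:
        raise ValueError(
            f"panel covers {n_seasons} seasons, config.period_length is "
            f"{config.period_length}"
        )
    v = panel.values
    risky = v["value"] < config.risk_threshold
    scores = (
        v.assign(risk=risky.astype(int))
        .pivot_table(index="cell_id", columns="indicator", values="risk",
                     aggfunc="sum", fill_value=0)
        .astype(int)
    )
    # preserve catalog order when the panel carries its catalog
    order = [s.id for s in panel.catalog if s.id in scores.columns]
    if order:
        scores = scores[order]

    miss = v["value"].isna().groupby(v["cell_id"]).mean()
    excluded = miss.index[miss > config.max_missing_fraction].tolist()
    if excluded:
        warnings.warn(
            f"{len(excluded)} cells excluded from clustering "
            f"(> {config.max_missing_fraction:.0%} missing indicator values)"
        )
    return RiskScoreMatrix(scores=scores, period_length=config.period_length,
                           excluded_cells=excluded)


def prune_zero_indicators(matrix: RiskScoreMatrix) -> RiskScoreMatrix:
    """Drop indicators whose risk never occurs anywhere (all-zero columns)."""
    zero = matrix.scores.columns[(matrix.scores == 0).all(axis=0)]
    if len(zero) == len(matrix.scores.columns):
        raise ValueError("all indicators are zero everywhere; nothing to cluster")
    dropped = dict(matrix.dropped_indicators)
    dropped.update({c: "risk never occurs anywhere" for c in zero})
    return RiskScoreMatrix(
        scores=matrix.scores.drop(columns=zero),
        period_length=matrix.period_length,
        dropped_indicators=dropped,
        excluded_cells=list(matrix.excluded_cells),
    )


def average_score_matrices(matrices: Sequence[RiskScoreMatrix]) -> RiskScoreMatrix:
    """Ensemble handling: average per-member score matrices (rounded to int)."""
    if not matrices:
        raise ValueError("no score matrices to average")
    frames = [m.scores for m in matrices]
    avg = np.rint(sum(f.values for f in frames) / len(frames)).astype(int)
    out = pd.DataFrame(avg, index=frames[0].index, columns=frames[0].columns)
    excluded = sorted(set().union(*(m.excluded_cells for m in matrices)))
    return RiskScoreMatrix(scores=out, period_length=matrices[0].period_length,
                           excluded_cells=excluded)


@dataclasses.dataclass
class WEZMap:
    """Zoning result: cell → zone label in 1..k, centroids in score space,
    and the inertia curve from the elbow scan."""

    labels: pd.Series
    centroids: pd.DataFrame
    k: int
    inertia_by_k: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        lab = self.labels
        if not lab.isin(range(1, self.k + 1)).all():
            raise ValueError("zone labels must be in 1..k")

    def zone_name(self, label: int) -> str:
        """Letter name A.. for a zone label (A = largest zone)."""
        return chr(ord("A") + label - 1)

    @property
    def named_labels(self) -> pd.Series:
        return self.labels.map(self.zone_name)


def _clustering_input(matrix: RiskScoreMatrix) -> pd.DataFrame:
    return matrix.scores.drop(index=matrix.excluded_cells, errors="ignore")


def elbow_select_k(matrix: RiskScoreMatrix, config: RiskConfig):
    """Elbow scan: K-means inertia over k_range; select the interior k with
    the largest second difference of inertia.

    Returns ``(k, inertia_by_k)``. A flat curve (single repeated profile)
    degenerates to the smallest k with a warning.
    """
    X = _clustering_input(matrix).to_numpy(dtype=float)
    n_distinct = np.unique(X, axis=0).shape[0]
    ks = [k for k in config.k_range if k <= n_distinct]
    if len(ks) < 3:
        if n_distinct <= 1:
            warnings.warn("degenerate score matrix (single profile); k = min(k_range)")
            return config.k_range[0], {config.k_range[0]: 0.0}
        raise ValueError(f"too few distinct cells ({n_distinct}) for the elbow scan")
    inertia = {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=config.n_init,
                    random_state=config.kmeans_seed)
        km.fit(X)
        inertia[k] = float(km.inertia_)
    if max(inertia.values()) < 1e-12:
        warnings.warn("flat inertia curve; k = min(k_range)")
        return ks[0], inertia
    second_diff = {
        ks[i]: inertia[ks[i - 1]] - 2 * inertia[ks[i]] + inertia[ks[i + 1]]
        for i in range(1, len(ks) - 1)
    }
    k_best = max(second_diff, key=second_diff.get)
    return k_best, inertia


def cluster_zones(matrix: RiskScoreMatrix, k: int, config: RiskConfig,
                  inertia_by_k: dict | None = None) -> WEZMap:
    """K-means zoning at a fixed k with deterministic relabeling.

    Distances are squared-Euclidean on the raw 0–30 scores (all columns
    share the scale, so no standardization). Zones are renumbered 1..k by
    descending cell count, ties broken by centroid lexicographic order, so
    repeated runs and cell permutations give identical labelings.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    X_df = _clustering_input(matrix)
    X = X_df.to_numpy(dtype=float)
    if np.unique(X, axis=0).shape[0] < k:
        raise ValueError(f"k={k} exceeds the number of distinct score profiles")
    km = KMeans(n_clusters=k, n_init=config.n_init, random_state=config.kmeans_seed)
    raw = km.fit_predict(X)

    counts = np.bincount(raw, minlength=k)
    order = sorted(range(k),
                   key=lambda c: (-counts[c], tuple(km.cluster_centers_[c])))
    remap = {old: new + 1 for new, old in enumerate(order)}
    labels = pd.Series([remap[c] for c in raw], index=X_df.index, name="zone")
    centroids = pd.DataFrame(
        km.cluster_centers_[order], index=pd.RangeIndex(1, k + 1, name="zone"),
        columns=X_df.columns,
    )
    return WEZMap(labels=labels, centroids=centroids, k=k,
                  inertia_by_k=dict(inertia_by_k or {}))


def zone_intensity_table(matrix: RiskScoreMatrix, zones: WEZMap) -> pd.DataFrame:
    """Mean risk score per zone × indicator, binned into intensity classes.

    Half-open bins [lo, hi): a mean of exactly 10 is "medium". Means at or
    above the top edge stay in the top class.
    """
    scores = _clustering_input(matrix)
    mean = scores.groupby(zones.labels).mean()

    def classify(x: float) -> str:
        for lo, hi, name in INTENSITY_CLASSES:
            if lo <= x < hi:
                return name
        return INTENSITY_CLASSES[-1][2]

    classes = mean.map(classify)
    classes.index.name = "zone"
    return classes
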