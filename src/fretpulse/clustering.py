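"""k-means clustering of single-cell normalized FRET trajectories.

Cells are clustered on their baseline-normalized, post-perturbation trace
vectors resampled to a common time grid.  Cluster identities are made
reproducible by canonical relabeling: clusters are ordered by descending
mean final normalized FRET and renumbered 1..k, so on the heterogeneous
mannose-type response cluster 1 contains the sustained switchers and
cluster k the declining cells regardless of the k-means seed.

k is a user choice (default 3); an inertia/silhouette report is available
to guide it but nothing auto-selects.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterResult",
    "GroupContrast",
    "resample_traces",
    "cluster_traces",
    "summarize_clusters",
    "composition_histogram",
    "compare_groups",
    "cluster_count_report",
]


@dataclass
class ClusterResult:
    """Per-cell labels (canonical 1..k order) and partition diagnostics."""

    labels: pd.Series  # index: cell_id, values: 1..k
    k: int
    inertia: float
    centroids: pd.DataFrame  # index: cluster 1..k, columns: grid times


@dataclass
class GroupContrast:
    """Two-sample comparison of a per-cell feature."""

    feature: str
    groups: tuple
    means: tuple
    sds: tuple
    ns: tuple
    t_statistic: float
    p_value: float
    equal_var: bool = True


def resample_traces(
    norm: pd.DataFrame,
    grid: np.ndarray | None = None,
    min_coverage: float = 0.5,
) -> tuple[pd.DataFrame, list]:
    """Linear interpolation of normalized traces onto a shared time grid.

    Default grid: the sorted unique post-perturbation (time >= 0) times.
    Cells whose trace spans less than ``min_coverage`` of the grid are
    excluded and listed; values beyond a trace's ends are edge-clipped.
    Returns (cells x timepoints matrix indexed by cell_id, excluded cells).
    """
    if grid is None:
        grid = np.sort(norm.loc[norm["time_min"] >= 0, "time_min"].unique())
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty resampling grid")
    span = grid[-1] - grid[0]
    rows, excluded = {}, []
    for cell, g in norm.groupby("cell_id", sort=True):
        t = g["time_min"].to_numpy()
        v = g["normalized_ratio"].to_numpy()
        overlap = min(t[-1], grid[-1]) - max(t[0], grid[0])
        if span > 0 and overlap < min_coverage * span:
            excluded.append(cell)
            continue
        if t[0] > grid[0] or t[-1] < grid[-1]:
            logger.info("trace %s clipped at grid edges", cell)
        rows[cell] = np.interp(grid, t, v)
    if excluded:
        logger.warning("%d traces excluded (cover < %.0f%% of grid)", len(excluded), 100 * min_coverage)
    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=grid)
    matrix.index.name = "cell_id"
    return matrix.sort_index(), excluded


def cluster_traces(
    matrix: pd.DataFrame,
    k: int = 3,
    seed: int = 0,
    n_restarts: int = 25,
) -> ClusterResult:
    """k-means (Euclidean, best of ``n_restarts`` by inertia) on trace vectors.

    Deterministic given the seed and invariant to input row order (rows
    are sorted by cell id before fitting).  Labels are canonically
    renumbered 1..k by descending cluster mean final normalized FRET
    (mean of the last 3 grid points).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > matrix.shape[0]:
        raise ValueError(f"k={k} exceeds the number of cells ({matrix.shape[0]})")
    X = matrix.sort_index()
    values = X.to_numpy(dtype=float)
    if k > 1 and np.unique(values, axis=0).shape[0] < k:
        raise ValueError("fewer distinct traces than clusters requested")
    km = KMeans(
        n_clusters=k,
        n_init=n_restarts,
        max_iter=300,
        tol=1e-6,
        random_state=seed,
        algorithm="lloyd",
    ).fit(values)
    raw = km.labels_
    finals = values[:, -min(3, values.shape[1]):].mean(axis=1)
    order = np.argsort(
        [-finals[raw == j].mean() for j in range(k)], kind="stable"
    )  # raw label -> rank position
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    labels = pd.Series(relabel[raw], index=X.index, name="cluster")
    centroids = pd.DataFrame(
        km.cluster_centers_[order], index=np.arange(1, k + 1), columns=X.columns
    )
    centroids.index.name = "cluster"
    return ClusterResult(labels=labels, k=k, inertia=float(km.inertia_), centroids=centroids)


def summarize_clusters(result: ClusterResult, features: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster n and mean/SD of the trace features.

    ``features`` must have one row per labeled cell (``cell_id`` column).
    """
    feats = features.set_index("cell_id")
    missing = result.labels.index.difference(feats.index)
    if len(missing):
        raise ValueError(f"features missing for labeled cells: {list(missing[:5])}")
    joined = feats.loc[result.labels.index].assign(cluster=result.labels)
    cols = ["basal_fret", "expression_proxy", "delta_norm_fret", "max_slope", "final_fret"]
    agg = joined.groupby("cluster")[cols].agg(["mean", "std"])
    agg.columns = [f"{c}_{s}" for c, s in agg.columns]
    agg.insert(0, "n", joined.groupby("cluster").size())
    return agg.reset_index()


def composition_histogram(result: ClusterResult, external_labels: pd.Series) -> pd.DataFrame:
    """Fraction of externally labeled (e.g. growing) cells per cluster.

    ``external_labels`` is boolean, indexed by cell_id, and must cover
    every clustered cell.  Empty clusters report a missing fraction.
    """
    missing = result.labels.index.difference(external_labels.index)
    if len(missing):
        raise ValueError(f"external labels missing for cells: {list(missing[:5])}")
    flags = external_labels.loc[result.labels.index].astype(bool)
    rows = []
    for cluster in range(1, result.k + 1):
        members = flags[result.labels == cluster]
        rows.append(
            {
                "cluster": cluster,
                "n": int(members.size),
                "grower_fraction": float(members.mean()) if members.size else np.nan,
            }
        )
    return pd.DataFrame(rows)


def compare_groups(
    values, group_labels, feature: str = "feature", equal_var: bool = True
) -> GroupContrast:
    """Two-sample t-test between the two groups of a per-cell feature.

    Defaults to the classical pooled-variance Student form; Welch with
    ``equal_var=False``.  The p-value is two-sided.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(group_labels)
    names = pd.unique(g)
    if len(names) != 2:
        raise ValueError(f"expected exactly 2 groups, got {len(names)}")
    a, b = v[g == names[0]], v[g == names[1]]
    if min(a.size, b.size) < 2:
        raise ValueError("each group needs at least 2 cells")
    if (a.size == 2 and a.std() == 0) or (b.size == 2 and b.std() == 0):
        warnings.warn("a group of size 2 has zero variance; p-value unreliable", stacklevel=2)
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return GroupContrast(
        feature=feature,
        groups=(names[0], names[1]),
        means=(float(a.mean()), float(b.mean())),
        sds=(float(a.std(ddof=1)), float(b.std(ddof=1))),
        ns=(int(a.size), int(b.size)),
        t_statistic=float(t),
        p_value=float(p),
        equal_var=equal_var,
    )


def cluster_count_report(
    matrix: pd.DataFrame, k_range=range(2, 8), seed: int = 0, n_restarts: int = 10
) -> pd.DataFrame:
    """Inertia (elbow) and silhouette per candidate k, to guide a manual choice."""
    rows = []
    X = matrix.sort_index().to_numpy(dtype=float)
    for k in k_range:
        if k >= X.shape[0]:
            break
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed).fit(X)
        rows.append(
            {
                "k": k,
                "inertia": float(km.inertia_),
                "silhouette": float(silhouette_score(X, km.labels_)),
            }
        )
    return pd.DataFrame(rows)
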