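"""Stage-wise demethylation dynamics over tile matrices.

Distribution summaries behind the per-stage violin/median plots, pairwise
methylation-change regression, K-means clustering of tile dynamics along a
developmental axis, average-linkage hierarchical clustering of samples, and
the cross-species comparison over conserved repeat-free tiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans

from .io import ValidationError
from .tiling import TileMatrix


def methylation_distribution(matrix: TileMatrix, sample_id: str,
                             bins: int = 50) -> dict:
    """Median/quartiles and histogram of passing-tile levels for one sample."""
    v = matrix.column(sample_id)
    v = v[~np.isnan(v)]
    if not len(v):
        raise ValidationError(f"sample {sample_id!r} has no passing tiles")
    counts, edges = np.histogram(v, bins=bins, range=(0.0, 1.0))
    return {
        "sample_id": sample_id,
        "n": int(len(v)),
        "median": float(np.median(v)),
        "q25": float(np.quantile(v, 0.25)),
        "q75": float(np.quantile(v, 0.75)),
        "mean": float(np.mean(v)),
        "hist_counts": counts,
        "hist_edges": edges,
    }


@dataclass
class PairwiseChange:
    sample_a: str
    sample_b: str
    slope: float
    intercept: float
    n: int
    density: np.ndarray       # 50x50 tile counts over [0,1]^2
    levels_a: np.ndarray
    levels_b: np.ndarray


def pairwise_change(matrix: TileMatrix, sample_a: str, sample_b: str,
                    grid: int = 50, min_tiles: int = 10) -> PairwiseChange:
    """Per-tile methylation change between two samples with an OLS trend line
    and binned density counts on a fixed grid over [0,1]^2."""
    a = matrix.column(sample_a)
    b = matrix.column(sample_b)
    ok = ~np.isnan(a) & ~np.isnan(b)
    a, b = a[ok], b[ok]
    if len(a) < min_tiles:
        raise ValidationError(
            f"only {len(a)} tiles non-missing in both samples (need {min_tiles})")
    X = np.column_stack([a, np.ones(len(a))])
    coef, *_ = np.linalg.lstsq(X, b, rcond=None)
    density, _, _ = np.histogram2d(a, b, bins=grid, range=[[0, 1], [0, 1]])
    return PairwiseChange(sample_a=sample_a, sample_b=sample_b,
                          slope=float(coef[0]), intercept=float(coef[1]),
                          n=int(len(a)), density=density, levels_a=a, levels_b=b)


@dataclass
class KMeansResult:
    labels: np.ndarray        # per-tile cluster (-1 where incomplete/missing)
    centroids: np.ndarray     # (k, n_samples), rows sorted by mean descending
    inertia: float
    sample_ids: list[str]


def kmeans_dynamics(matrix: TileMatrix, sample_ids: list[str], k: int,
                    seed: int = 0, n_init: int = 10,
                    max_iter: int = 300) -> KMeansResult:
    """K-means (k-means++/Lloyd, Euclidean) of per-tile level vectors along a
    stage axis; complete-case on the clustering samples.  Clusters are
    relabelled in order of decreasing centroid mean so labels are stable
    across runs with the same seed."""
    if k < 1:
        raise ValidationError("k must be >= 1")
    cols = [matrix.sample_ids.index(s) for s in sample_ids]
    data = matrix.levels[:, cols]
    complete = ~np.isnan(data).any(axis=1)
    X = data[complete]
    if len(X) < k:
        raise ValidationError(f"{len(X)} complete tiles < k={k}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init,
                max_iter=max_iter, random_state=seed)
    raw = km.fit_predict(X)
    order = np.argsort(-km.cluster_centers_.mean(axis=1), kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    labels = np.full(len(data), -1, dtype=int)
    labels[complete] = relabel[raw]
    return KMeansResult(labels=labels, centroids=km.cluster_centers_[order],
                        inertia=float(km.inertia_), sample_ids=list(sample_ids))


@dataclass
class Dendrogram:
    linkage_matrix: np.ndarray   # scipy linkage format
    sample_ids: list[str]
    n_tiles: int


def hierarchical_cluster(matrix: TileMatrix,
                         sample_ids: list[str] | None = None) -> Dendrogram:
    """Average-linkage hierarchical clustering of samples on Euclidean
    distance over tiles passing in every sample."""
    ids = sample_ids or matrix.sample_ids
    if len(ids) < 2:
        raise ValidationError("need >= 2 samples to cluster")
    cols = [matrix.sample_ids.index(s) for s in ids]
    data = matrix.levels[:, cols]
    common = ~np.isnan(data).any(axis=1)
    X = data[common].T  # samples x tiles
    if X.shape[1] == 0:
        raise ValidationError("no tiles pass in all samples")
    Z = linkage(pdist(X, metric="euclidean"), method="average")
    return Dendrogram(linkage_matrix=Z, sample_ids=list(ids),
                      n_tiles=int(common.sum()))


def hierarchical_cluster_frame(frame: pd.DataFrame) -> Dendrogram:
    """Average-linkage clustering of the columns of a wide level table
    (rows = regions/genes, columns = samples); complete-case on rows."""
    if frame.shape[1] < 2:
        raise ValidationError("need >= 2 samples to cluster")
    X = frame.dropna().to_numpy(float).T
    if X.shape[1] == 0:
        raise ValidationError("no complete rows")
    Z = linkage(pdist(X, metric="euclidean"), method="average")
    return Dendrogram(linkage_matrix=Z, sample_ids=list(frame.columns),
                      n_tiles=X.shape[1])


def conserved_tile_compare(matrix_h: TileMatrix, matrix_m: TileMatrix,
                           ortholog_map: pd.DataFrame,
                           repeat_free_only: bool = True) -> pd.DataFrame:
    """Join two species' tile matrices over 1:1 mapped tiles.

    ``ortholog_map`` needs columns (human_id, mouse_id) holding tile ids
    formatted chrom:start-end.  Rows are mapped tile pairs that pass the
    coverage filter in every sample of both matrices (and are repeat-free on
    both sides by default).  The result feeds the distribution and
    hierarchical-clustering reports.
    """
    if not len(ortholog_map):
        raise ValidationError("empty ortholog map")
    if ortholog_map["human_id"].duplicated().any() or \
            ortholog_map["mouse_id"].duplicated().any():
        raise ValidationError("ortholog map must be 1:1 for tiles")
    h_ids = matrix_h.tiles.ids()
    m_ids = matrix_m.tiles.ids()
    h_index = pd.Series(np.arange(len(h_ids)), index=h_ids)
    m_index = pd.Series(np.arange(len(m_ids)), index=m_ids)
    known = ortholog_map["human_id"].isin(h_index.index) & \
        ortholog_map["mouse_id"].isin(m_index.index)
    pairs = ortholog_map[known]
    hi = h_index[pairs["human_id"]].to_numpy()
    mi = m_index[pairs["mouse_id"]].to_numpy()
    keep = ~np.isnan(matrix_h.levels[hi]).any(axis=1) & \
        ~np.isnan(matrix_m.levels[mi]).any(axis=1)
    if repeat_free_only:
        keep &= matrix_h.tiles.tiles["is_repeat_free"].to_numpy()[hi]
        keep &= matrix_m.tiles.tiles["is_repeat_free"].to_numpy()[mi]
    hi, mi = hi[keep], mi[keep]
    if not len(hi):
        raise ValidationError("no mapped tile pairs survive the filters")
    data = {"human_id": h_ids.to_numpy()[hi], "mouse_id": m_ids.to_numpy()[mi]}
    for j, s in enumerate(matrix_h.sample_ids):
        data[s] = matrix_h.levels[hi, j]
    for j, s in enumerate(matrix_m.sample_ids):
        data[s] = matrix_m.levels[mi, j]
    return pd.DataFrame(data)
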