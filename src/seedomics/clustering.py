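"""Stage-resolved K-means clustering of differentially expressed genes.

Profiles are stage means of log2(FPKM + 1) z-scored across the six stages;
K-means (default K=24) groups them, each cluster is assigned the stage of its
centroid peak, and clusters are merged into superclusters (default 9) by
average-linkage hierarchical clustering under correlation distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .design import N_STAGES
from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)


def preprocess_profiles(
    expr: ExpressionMatrix, genes: list[str] | None = None, raw_scale: bool = False
) -> pd.DataFrame:
    """Gene x 6 standardized stage profiles.

    Stage means of log2(FPKM + 1), z-scored (ddof=1) across the six stages.
    Zero-variance (flat) genes are dropped with a warning. ``raw_scale``
    skips the log/z-score and clusters raw FPKM stage means.
    """
    if genes is not None:
        if len(genes) == 0:
            raise ValueError("empty gene set")
        missing = set(genes) - set(expr.data.index)
        if missing:
            raise KeyError(f"genes absent from matrix: {sorted(missing)[:5]}...")
        data = expr.data.loc[genes]
        expr = ExpressionMatrix(data, expr.design)
    means = expr.stage_means()
    if raw_scale:
        return means
    logmeans = np.log2(means + 1.0)
    sd = logmeans.std(axis=1, ddof=1)
    flat = sd == 0
    if flat.any():
        logger.warning("dropping %d zero-variance genes", int(flat.sum()))
    kept = logmeans.loc[~flat]
    return kept.sub(kept.mean(axis=1), axis=0).div(sd[~flat], axis=0)


@dataclass
class ClusterSet:
    """K-means clustering result over stage profiles."""

    cluster_of_gene: pd.Series  # gene -> 1..K
    centroids: pd.DataFrame  # K x 6, index = cluster id
    wss: float
    stage_of_cluster: dict[int, int] | None = None
    supercluster_of_cluster: dict[int, int] | None = None

    @property
    def k(self) -> int:
        return len(self.centroids)


def kmeans_cluster(
    profiles: pd.DataFrame, k: int = 24, seed: int = 0, n_restarts: int = 10
) -> ClusterSet:
    """Euclidean K-means, best of ``n_restarts`` k-means++ starts by WSS."""
    if len(profiles) < k:
        raise ValueError(f"need at least k={k} genes, got {len(profiles)}")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(profiles.to_numpy())
    cluster_of_gene = pd.Series(labels + 1, index=profiles.index, name="cluster")
    centroids = pd.DataFrame(
        km.cluster_centers_,
        index=pd.RangeIndex(1, k + 1, name="cluster"),
        columns=profiles.columns,
    )
    cs = ClusterSet(cluster_of_gene, centroids, wss=float(km.inertia_))
    cs.stage_of_cluster = {
        c: assign_cluster_stage(centroids.loc[c].to_numpy()) for c in centroids.index
    }
    return cs


def assign_cluster_stage(centroid: np.ndarray) -> int:
    """Stage of a cluster = argmax of its 6-point centroid, earliest on ties."""
    centroid = np.asarray(centroid, dtype=float)
    if centroid.shape != (N_STAGES,):
        raise ValueError("centroid must have one value per stage")
    peak = int(np.argmax(centroid)) + 1
    if np.count_nonzero(centroid == centroid.max()) > 1:
        logger.info("centroid peak tie resolved to earliest stage %d", peak)
    return peak


def merge_superclusters(clusters: ClusterSet, n_super: int = 9) -> dict[int, int]:
    """Merge cluster centroids into exactly ``n_super`` superclusters.

    Average-linkage hierarchical clustering of centroids with distance
    1 - Pearson correlation, tree cut to the requested group count.
    Supercluster ids are renumbered 1..n_super in order of first appearance.
    """
    if n_super < 1:
        raise ValueError("n_super must be >= 1")
    k = clusters.k
    if n_super > k:
        raise ValueError("n_super cannot exceed the number of clusters")
    x = clusters.centroids.to_numpy()
    corr = np.corrcoef(x)
    dist = np.clip(1.0 - corr, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    raw = hierarchy.cut_tree(link, n_clusters=n_super).ravel()
    remap: dict[int, int] = {}
    out: dict[int, int] = {}
    for cid, lab in zip(clusters.centroids.index, raw):
        if lab not in remap:
            remap[lab] = len(remap) + 1
        out[int(cid)] = remap[lab]
    clusters.supercluster_of_cluster = out
    return out


def single_stage_genes(expr: ExpressionMatrix, tau_fpkm: float = 1.0) -> dict[str, int]:
    """Genes whose stage-mean FPKM reaches ``tau_fpkm`` at exactly one stage.

    Returns gene -> the single expressed stage.
    """
    means = expr.stage_means()
    on = means >= tau_fpkm
    single = on.sum(axis=1) == 1
    stages = on.loc[single].idxmax(axis=1)
    return {g: int(s) for g, s in stages.items()}
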