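"""Pooling base clusters and meta-clustering their geometric medians.

Every cluster from every base partition becomes one row of an m x d
*median matrix* (its geometric median in marker space).  Meta-clustering
this small matrix -- rather than the N x N co-association structure --
is what keeps consensus formation tractable for millions of events.
The number of consensus clusters can be chosen from a range by
consensus-resampling (the ConsensusClusterPlus idea): repeatedly
subsample median rows, recluster, and pick the k whose co-clustering
proportions are most binary (minimum PAC).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import (
    AffinityPropagation,
    AgglomerativeClustering,
    KMeans,
    MeanShift,
)

from .data import SENTINEL, BasePartitionSet, EventMatrix
from .median import geometric_median

META_METHODS = ("agglomerative", "kmeans", "affinity_propagation", "mean_shift")
LINKAGES = ("average", "complete", "ward", "single")
METRICS = ("euclidean", "manhattan", "cosine", "correlation")


@dataclass(frozen=True)
class ClusterRecord:
    """One pooled base cluster: a voter in the consensus."""

    partition_index: int
    cluster_id: int
    member_indices: np.ndarray
    median: np.ndarray

    @property
    def size(self) -> int:
        return len(self.member_indices)


@dataclass(frozen=True)
class ClusterTable:
    """The m pooled clusters with their geometric medians.

    ``median_matrix`` rows follow record order: partition index ascending,
    then cluster id ascending within a partition.
    """

    records: tuple
    median_matrix: np.ndarray
    marker_names: tuple

    @property
    def n_clusters(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        """Median matrix as a DataFrame with partition/cluster id columns."""
        df = pd.DataFrame(self.median_matrix, columns=list(self.marker_names))
        df.insert(0, "cluster_id", [r.cluster_id for r in self.records])
        df.insert(0, "partition_index", [r.partition_index for r in self.records])
        df.insert(2, "size", [r.size for r in self.records])
        return df


@dataclass(frozen=True)
class ConsensusMap:
    """Assignment of each pooled cluster to exactly one consensus cluster."""

    consensus_of: np.ndarray  # length m, values in 0..K-1
    n_consensus: int

    def __post_init__(self):
        labels = np.asarray(self.consensus_of, dtype=np.int64)
        object.__setattr__(self, "consensus_of", labels)
        present = np.unique(labels)
        if not np.array_equal(present, np.arange(self.n_consensus)):
            raise ValueError("consensus labels must cover 0..K-1 with no gaps")

    def members(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.consensus_of == label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"record_index": np.arange(len(self.consensus_of)),
             "consensus_label": self.consensus_of}
        )


def pool_clusters(
    events: EventMatrix,
    partitions: BasePartitionSet,
    tol: float = 1e-7,
    max_iter: int = 500,
) -> ClusterTable:
    """Pool all base clusters and compute each one's geometric median.

    One record per (partition, non-sentinel cluster id); the median is the
    Weiszfeld geometric median of the member events' marker vectors.
    """
    partitions.check_aligned(events)
    records = []
    rows = []
    for b in range(partitions.n_partitions):
        labels = partitions.labels[b]
        ids = np.unique(labels[labels != SENTINEL])
        if ids.size == 0:
            raise ValueError(f"partition {b} has no non-sentinel clusters")
        for cid in ids:
            members = np.flatnonzero(labels == cid)
            med = geometric_median(events.values[members], tol=tol, max_iter=max_iter)
            records.append(
                ClusterRecord(
                    partition_index=b,
                    cluster_id=int(cid),
                    member_indices=members,
                    median=med.median,
                )
            )
            rows.append(med.median)
    return ClusterTable(tuple(records), np.vstack(rows), events.marker_names)


def _densify(labels: np.ndarray) -> tuple[np.ndarray, int]:
    uniq, inv = np.unique(labels, return_inverse=True)
    return inv.astype(np.int64), len(uniq)


def metacluster(
    table: ClusterTable,
    method: str = "agglomerative",
    k: int | None = None,
    linkage: str = "average",
    metric: str = "euclidean",
    scale: str = "none",
    seed: int = 42,
) -> ConsensusMap:
    """Cluster the m median rows into K consensus clusters.

    ``agglomerative`` and ``kmeans`` require ``k`` (2 <= k <= m);
    ``affinity_propagation`` and ``mean_shift`` determine K themselves.
    ``scale="zscore"`` standardises each marker column of the median
    matrix first (off by default: medians are clustered on the raw
    transformed scale).
    """
    if method not in META_METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {META_METHODS}")
    X = np.asarray(table.median_matrix, dtype=float)
    m = X.shape[0]
    if scale == "zscore":
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    elif scale != "none":
        raise ValueError(f"unknown scale {scale!r}")

    if method in ("agglomerative", "kmeans"):
        if k is None:
            raise ValueError(f"{method} requires k")
        if not (1 <= k <= m):
            raise ValueError(f"k={k} outside valid range 1..{m}")

    if method == "agglomerative":
        if linkage not in LINKAGES:
            raise ValueError(f"unknown linkage {linkage!r}")
        if metric not in METRICS:
            raise ValueError(f"unknown metric {metric!r}")
        if linkage == "ward":
            if metric != "euclidean":
                raise ValueError("ward linkage requires the euclidean metric")
            model = AgglomerativeClustering(n_clusters=k, linkage="ward")
            labels = model.fit_predict(X)
        else:
            dist = squareform(pdist(X, metric={"manhattan": "cityblock"}.get(metric, metric)))
            dist = np.nan_to_num(dist, nan=0.0)  # correlation of constant rows
            model = AgglomerativeClustering(
                n_clusters=k, linkage=linkage, metric="precomputed"
            )
            labels = model.fit_predict(dist)
    elif method == "kmeans":
        model = KMeans(n_clusters=k, random_state=seed, n_init=10)
        labels = model.fit_predict(X)
    elif method == "affinity_propagation":
        model = AffinityPropagation(random_state=seed)
        labels = model.fit_predict(X)
        if (labels < 0).any():  # non-convergence marks all points -1
            raise RuntimeError("affinity propagation failed to converge")
    else:  # mean_shift
        model = MeanShift()
        labels = model.fit_predict(X)

    dense, n_consensus = _densify(labels)
    return ConsensusMap(dense, n_consensus)


def _recluster_once(X, method, k, linkage, metric, seed):
    """One resample reclustering; stochastic methods use a single init."""
    if method == "kmeans":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # duplicate rows can collapse clusters
            return KMeans(n_clusters=k, random_state=seed, n_init=1).fit_predict(X)
    if method == "agglomerative":
        if linkage == "ward":
            return AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(X)
        dist = squareform(pdist(X, metric={"manhattan": "cityblock"}.get(metric, metric)))
        dist = np.nan_to_num(dist, nan=0.0)
        return AgglomerativeClustering(
            n_clusters=k, linkage=linkage, metric="precomputed"
        ).fit_predict(dist)
    raise ValueError(f"select_k supports agglomerative or kmeans, not {method!r}")


def select_k(
    table: ClusterTable,
    k_range,
    method: str = "kmeans",
    linkage: str = "average",
    metric: str = "euclidean",
    scale: str = "none",
    resample_fraction: float = 0.8,
    n_resamples: int = 100,
    pac_bounds: tuple = (0.1, 0.9),
    seed: int = 42,
):
    """Choose the number of consensus clusters by consensus resampling.

    For each k in ``k_range``: repeatedly subsample
    ``ceil(resample_fraction * m)`` median rows, cluster them, and
    accumulate the m x m consensus matrix (proportion of co-clusterings
    among co-sampled pairs).  PAC -- the proportion of ambiguous
    consensus entries strictly inside ``pac_bounds`` -- is minimised;
    ties break to the smaller k.

    With ``method="kmeans"`` each resample is reclustered from a single
    fresh k-means++ initialisation: at the wrong k the forced merges or
    splits vary between initialisations, which is exactly the
    instability PAC measures.  Deterministic methods (agglomerative)
    draw instability only from the row subsampling and discriminate
    poorly on cleanly separated medians, so ``kmeans`` is the default
    here.

    Returns ``(k_best, stats)`` where ``stats`` is a DataFrame with one
    row per k (columns ``k``, ``pac``, ``mean_consensus``).
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("empty k range")
    m = table.n_clusters
    if ks[0] < 2 or ks[-1] > m:
        raise ValueError(f"k range {ks[0]}..{ks[-1]} outside 2..m={m}")
    if not (0 < resample_fraction <= 1):
        raise ValueError("resample_fraction must be in (0, 1]")
    sub_n = int(np.ceil(resample_fraction * m))
    lo, hi = pac_bounds
    rng = np.random.default_rng(seed)
    X = np.asarray(table.median_matrix, dtype=float)
    if scale == "zscore":
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd

    rows = []
    best_k, best_pac = None, np.inf
    iu = np.triu_indices(m, k=1)
    for k in ks:
        co = np.zeros((m, m))
        both = np.zeros((m, m))
        for _ in range(n_resamples):
            idx = rng.choice(m, size=sub_n, replace=False)
            lab = _recluster_once(
                X[idx], method, min(k, sub_n), linkage, metric,
                int(rng.integers(0, 2**31 - 1)),
            )
            same = lab[:, None] == lab[None, :]
            both[np.ix_(idx, idx)] += 1
            co[np.ix_(idx, idx)] += same
        with np.errstate(invalid="ignore"):
            consensus = np.where(both > 0, co / np.maximum(both, 1), np.nan)
        vals = consensus[iu]
        vals = vals[np.isfinite(vals)]
        pac = float(np.mean((vals > lo) & (vals < hi))) if vals.size else 1.0
        rows.append({"k": k, "pac": pac, "mean_consensus": float(np.mean(vals))})
        if pac < best_pac:  # strict: ties keep the smaller k seen first
            best_pac, best_k = pac, k
    return best_k, pd.DataFrame(rows)
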