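"""Model/Results interface tying the consensus pipeline together.

``GeoWaVe`` is constructed from an event matrix and an ensemble of base
partitions; ``fit()`` pools the base clusters, meta-clusters their
geometric medians (optionally choosing k from a range by consensus
resampling) and resolves every event by distance-weighted voting,
returning a :class:`GeoWaVeResults` with the labels, per-event vote
diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import BasePartitionSet, EventMatrix
from .ensemble import metacluster, pool_clusters, select_k
from .metrics import summary_scores
from .voting import assign_events, relabel_contiguous


class GeoWaVe:
    """Geometric-median consensus clustering with weighted voting.

    Parameters
    ----------
    events : EventMatrix
        N x d transformed marker intensities.
    partitions : BasePartitionSet
        B >= 2 base clusterings of the same events.
    meta_method : {"agglomerative", "kmeans", "affinity_propagation", "mean_shift"}
        Algorithm applied to the m x d geometric-median matrix.
    k : int, optional
        Number of consensus clusters (required by agglomerative/kmeans
        unless ``k_range`` is given).
    k_range : iterable of int, optional
        Candidate k values searched by consensus resampling (minimum
        proportion of ambiguous co-clustering, PAC).
    linkage, metric, scale : agglomerative options; ``scale="zscore"``
        standardises median-matrix columns before meta-clustering.
    seed : int
        Seed for every stochastic step.

    Examples
    --------
    >>> model = GeoWaVe(events, partitions, meta_method="kmeans", k=10)
    >>> res = model.fit()
    >>> res.labels
    """

    def __init__(
        self,
        events: EventMatrix,
        partitions: BasePartitionSet,
        meta_method: str = "agglomerative",
        k: int | None = None,
        k_range=None,
        linkage: str = "average",
        metric: str = "euclidean",
        scale: str = "none",
        resample_fraction: float = 0.8,
        n_resamples: int = 100,
        seed: int = 42,
    ):
        partitions.check_aligned(events)
        self.events = events
        self.partitions = partitions
        self.meta_method = meta_method
        self.k = k
        self.k_range = list(k_range) if k_range is not None else None
        self.linkage = linkage
        self.metric = metric
        self.scale = scale
        self.resample_fraction = resample_fraction
        self.n_resamples = n_resamples
        self.seed = seed

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, marker_columns, label_columns, **kwargs):
        """Build from one DataFrame holding markers and base-label columns."""
        events = EventMatrix(
            frame[list(marker_columns)].to_numpy(dtype=float), tuple(marker_columns)
        )
        labels = np.vstack(
            [frame[c].to_numpy(dtype=np.int64) for c in label_columns]
        )
        return cls(events, BasePartitionSet(labels, tuple(label_columns)), **kwargs)

    def fit(self, n_workers: int = 1, relabel: bool = True) -> "GeoWaVeResults":
        """Run pool -> (select k) -> meta-cluster -> vote."""
        table = pool_clusters(self.events, self.partitions)
        k = self.k
        k_stats = None
        if self.k_range is not None:
            k, k_stats = select_k(
                table,
                self.k_range,
                method=self.meta_method,
                linkage=self.linkage,
                metric=self.metric,
                scale=self.scale,
                resample_fraction=self.resample_fraction,
                n_resamples=self.n_resamples,
                seed=self.seed,
            )
        cmap = metacluster(
            table,
            method=self.meta_method,
            k=k,
            linkage=self.linkage,
            metric=self.metric,
            scale=self.scale,
            seed=self.seed,
        )
        result = assign_events(
            self.events, self.partitions, table, cmap, n_workers=n_workers
        )
        if relabel:
            result = relabel_contiguous(result)
        return GeoWaVeResults(self, result, selected_k=k, k_stats=k_stats)


class GeoWaVeResults:
    """Fitted consensus clustering.

    Attributes
    ----------
    labels : per-event consensus labels (0..K-1, largest cluster first).
    consensus_result : the full :class:`~geowave.voting.ConsensusResult`
        with candidate counts, winning scores and the cluster table.
    selected_k : the k actually used (chosen from ``k_range`` if given).
    k_stats : per-k resampling statistics, or None.
    """

    def __init__(self, model: GeoWaVe, consensus_result, selected_k, k_stats=None):
        self.model = model
        self.consensus_result = consensus_result
        self.selected_k = selected_k
        self.k_stats = k_stats

    @property
    def labels(self) -> np.ndarray:
        return self.consensus_result.labels

    @property
    def n_consensus(self) -> int:
        return self.consensus_result.n_consensus

    @property
    def ambiguous_fraction(self) -> float:
        """Fraction of events whose base clusters disagreed (vote needed)."""
        return float(np.mean(self.consensus_result.candidates_per_event >= 2))

    def median_matrix_frame(self) -> pd.DataFrame:
        """Pooled-cluster geometric medians (heatmap-ready)."""
        return self.consensus_result.cluster_table.to_frame()

    def evaluate(self, truth) -> dict:
        """ARI/AMI/FMI/average-F1 against ground-truth labels."""
        return summary_scores(truth, self.labels)

    def summary(self) -> pd.DataFrame:
        """Per-consensus summary: event counts, vote statistics."""
        labels = self.labels
        res = self.consensus_result
        rows = []
        for lab in range(self.n_consensus):
            mask = labels == lab
            scores = res.winning_scores[mask]
            finite = scores[np.isfinite(scores)]
            rows.append(
                {
                    "consensus": lab,
                    "n_events": int(mask.sum()),
                    "fraction": float(mask.mean()),
                    "n_voted": int(np.sum(res.candidates_per_event[mask] >= 2)),
                    "median_winning_score": float(np.median(finite))
                    if finite.size
                    else np.nan,
                }
            )
        return pd.DataFrame(rows)

    def __repr__(self):
        return (
            f"<GeoWaVeResults: {self.n_consensus} consensus clusters, "
            f"N={len(self.labels)}, ambiguous={self.ambiguous_fraction:.3f}>"
        )
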