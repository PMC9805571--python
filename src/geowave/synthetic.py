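"""Seeded synthetic benchmarks: Gaussian clouds with controllable overlap.

Emulates the statistical structure of cytometry benchmark data at the
level that matters for consensus clustering: a mixture of isotropic
Gaussian point clouds in ~15 dimensions, with controllable cloud spread
(hence inter-cloud overlap), class imbalance including rare populations,
and event counts from 10^4 to 10^6.  Built-in k-means base runs stand in
for external clustering tools so the whole pipeline is testable with no
download.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .data import BasePartitionSet, EventMatrix
from .ensemble import metacluster, pool_clusters
from .metrics import adjusted_rand_index
from .voting import assign_events


@dataclass(frozen=True)
class BlobSpec:
    """Parameters of a Gaussian-cloud benchmark dataset.

    Cloud centers are placed uniformly in a hypercube of side
    ``center_spread``; events are isotropic Gaussians around them with
    standard deviation ``sd``.  The default geometry (side 10, d = 15)
    puts typical center separations near 15 units, so ``sd = 1`` gives
    essentially disjoint clouds and ``sd = 4`` substantial overlap.
    """

    n_events: int = 10_000
    n_dims: int = 15
    n_clusters: int = 10
    sd: float = 1.0
    weights: tuple | None = None
    center_spread: float = 10.0
    seed: int = 42

    def __post_init__(self):
        if self.n_clusters > self.n_events:
            raise ValueError("n_clusters cannot exceed n_events")
        if self.sd <= 0 or self.center_spread <= 0:
            raise ValueError("sd and center_spread must be positive")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if len(w) != self.n_clusters:
                raise ValueError("weights length must equal n_clusters")
            if (w <= 0).any() or abs(w.sum() - 1.0) > 1e-9:
                raise ValueError("weights must be positive and sum to 1")
            object.__setattr__(self, "weights", tuple(w))


def _allocate_counts(n: int, weights: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of n events to the weight vector."""
    raw = weights * n
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:short]] += 1
    return counts


def make_blobs(spec: BlobSpec):
    """Generate one Gaussian-cloud dataset.

    Returns ``(EventMatrix, truth)`` where truth labels are 0-based cloud
    indices.  Reproducible per seed.
    """
    rng = np.random.default_rng(spec.seed)
    k, d = spec.n_clusters, spec.n_dims
    centers = rng.uniform(0.0, spec.center_spread, size=(k, d))
    weights = (
        np.full(k, 1.0 / k) if spec.weights is None else np.asarray(spec.weights)
    )
    counts = _allocate_counts(spec.n_events, weights)
    values = np.empty((spec.n_events, d))
    truth = np.empty(spec.n_events, dtype=np.int64)
    pos = 0
    for c in range(k):
        values[pos:pos + counts[c]] = centers[c] + rng.normal(
            0.0, spec.sd, size=(counts[c], d)
        )
        truth[pos:pos + counts[c]] = c
        pos += counts[c]
    markers = tuple(f"M{i + 1}" for i in range(d))
    return EventMatrix(values, markers), truth


def add_rare_population(
    events: EventMatrix,
    truth: np.ndarray,
    fraction: float,
    offset,
    sd: float = 1.0,
    seed: int = 42,
):
    """Append a rare population (<= 5% of events) as a new Gaussian cloud.

    Adds ``ceil(fraction * N)`` events centred at ``offset`` with label
    ``max(truth) + 1``.
    """
    if not (0 < fraction <= 0.05):
        raise ValueError("fraction must be in (0, 0.05]")
    offset = np.asarray(offset, dtype=float)
    if offset.shape != (events.n_markers,):
        raise ValueError("offset dimension must match the event matrix")
    n_new = int(np.ceil(fraction * events.n_events))
    rng = np.random.default_rng(seed)
    new_values = offset + rng.normal(0.0, sd, size=(n_new, events.n_markers))
    values = np.vstack([events.values, new_values])
    new_truth = np.concatenate(
        [np.asarray(truth), np.full(n_new, int(np.max(truth)) + 1)]
    )
    return EventMatrix(values, events.marker_names), new_truth


def builtin_base_partitions(events: EventMatrix, ks, seeds) -> BasePartitionSet:
    """A diverse ensemble of k-means base runs, one per (k, seed) pair.

    Stands in for external clustering tools (FlowSOM, SPADE, Phenograph,
    ...), whose outputs the consensus consumes as opaque label vectors.
    Empty k-means clusters are dropped by dense re-encoding.
    """
    ks = list(ks)
    seeds = list(seeds)
    if len(ks) != len(seeds):
        raise ValueError("ks and seeds must have equal length")
    if len(ks) < 2:
        raise ValueError("an ensemble needs at least 2 base runs")
    vectors = []
    names = []
    for k, seed in zip(ks, seeds):
        if k > events.n_events:
            raise ValueError(f"k={k} exceeds N={events.n_events}")
        labels = KMeans(n_clusters=k, random_state=seed, n_init=3).fit_predict(
            events.values
        )
        _, dense = np.unique(labels, return_inverse=True)
        vectors.append(dense.astype(np.int64))
        names.append(f"kmeans_k{k}_s{seed}")
    return BasePartitionSet(np.vstack(vectors), tuple(names))


def scaling_suite(
    sizes=(10_000, 100_000),
    sds=(1.0, 2.0, 3.0, 4.0),
    seed: int = 42,
    base_ks=(8, 10, 12, 15),
    meta_method: str = "kmeans",
    meta_k: int = 10,
    n_workers: int = 1,
) -> pd.DataFrame:
    """Run the consensus pipeline over a size x spread grid.

    For each (n_events, sd) cell: generate clouds, run the built-in base
    ensemble, pool + meta-cluster + vote, and record wall time, the
    fraction of ambiguous events (those scored by the vote), and ARI
    against the generating labels.  Timings are informational only.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for n in sizes:
        for sd in sds:
            cell_seed = int(rng.integers(0, 2**31 - 1))
            spec = BlobSpec(n_events=int(n), sd=float(sd), seed=cell_seed)
            events, truth = make_blobs(spec)
            t0 = time.perf_counter()
            parts = builtin_base_partitions(
                events, base_ks, [cell_seed + i for i in range(len(base_ks))]
            )
            table = pool_clusters(events, parts)
            cmap = metacluster(table, method=meta_method, k=meta_k, seed=cell_seed)
            result = assign_events(events, parts, table, cmap, n_workers=n_workers)
            elapsed = time.perf_counter() - t0
            rows.append(
                {
                    "n_events": int(n),
                    "sd": float(sd),
                    "seed": cell_seed,
                    "wall_time_s": elapsed,
                    "ambiguous_fraction": float(
                        np.mean(result.candidates_per_event >= 2)
                    ),
                    "ari": adjusted_rand_index(truth, result.labels),
                }
            )
    return pd.DataFrame(rows)
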