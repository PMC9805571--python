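"""External evaluation of clusterings against ground truth.

Chance-adjusted pair/information indices (ARI, AMI, FMI) are computed
from the truth x prediction contingency table.  For per-population
reporting, clusters are matched one-to-one to ground-truth populations
with the Hungarian (linear assignment) algorithm so that the summed F1
across populations is maximal, and precision (PPV), recall (sensitivity)
and F1 are reported per population.

``coassociation_consensus`` is the exact-but-memory-hungry classical
consensus (average-linkage agglomerative clustering of the N x N
co-association matrix); it is capped at small N and exists as an
independent reference for the median-based consensus.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import AgglomerativeClustering

from .data import SENTINEL, BasePartitionSet

COASSOC_CAP = 5000


@dataclass(frozen=True)
class ContingencyTable:
    counts: np.ndarray  # (R, S) ints
    truth_labels: np.ndarray
    pred_labels: np.ndarray

    @property
    def n(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class MatchReport:
    """One-to-one Hungarian matching of truth populations to clusters."""

    mapping: dict  # truth label -> matched cluster label or None
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    truth_labels: np.ndarray
    population_sizes: np.ndarray

    @property
    def average_f1(self) -> float:
        return float(self.f1.mean())

    @property
    def sd_f1(self) -> float:
        return float(self.f1.std())

    def to_frame(self) -> pd.DataFrame:
        """Per-population report with a min-max normalised size column."""
        sizes = self.population_sizes.astype(float)
        span = sizes.max() - sizes.min()
        norm = (sizes - sizes.min()) / span if span > 0 else np.ones_like(sizes)
        return pd.DataFrame(
            {
                "population": self.truth_labels,
                "matched_cluster": [self.mapping[t] for t in self.truth_labels],
                "precision": self.precision,
                "recall": self.recall,
                "f1": self.f1,
                "size_fraction": sizes / sizes.sum(),
                "size_normalized": norm,
            }
        )


def _joint_mask(truth, pred):
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    if truth.shape != pred.shape:
        raise ValueError(f"length mismatch: {truth.shape} vs {pred.shape}")
    mask = (truth != SENTINEL) & (pred != SENTINEL)
    if not mask.any():
        raise ValueError("no jointly labelled events")
    return truth[mask], pred[mask]


def contingency(truth, pred) -> ContingencyTable:
    """Truth x prediction count matrix over jointly labelled events."""
    truth, pred = _joint_mask(truth, pred)
    t_labels, t_inv = np.unique(truth, return_inverse=True)
    p_labels, p_inv = np.unique(pred, return_inverse=True)
    counts = np.zeros((len(t_labels), len(p_labels)), dtype=np.int64)
    np.add.at(counts, (t_inv, p_inv), 1)
    return ContingencyTable(counts, t_labels, p_labels)


def _comb2(x):
    x = np.asarray(x, dtype=float)
    return x * (x - 1) / 2.0


def adjusted_rand_index(truth, pred) -> float:
    """Permutation-model adjusted Rand index in [-1, 1]."""
    table = contingency(truth, pred)
    if table.n < 2:
        raise ValueError("ARI is undefined for fewer than two events")
    nij = table.counts
    a = nij.sum(axis=1)
    b = nij.sum(axis=0)
    n = table.n
    sum_ij = _comb2(nij).sum()
    sum_a = _comb2(a).sum()
    sum_b = _comb2(b).sum()
    expected = sum_a * sum_b / _comb2(n)
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:  # both partitions trivial
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def _entropy(counts, n):
    p = counts[counts > 0] / n
    return float(-(p * np.log(p)).sum())


def _mutual_info(nij, a, b, n):
    nz = nij > 0
    terms = nij[nz] / n * (
        np.log(nij[nz]) + np.log(n) - np.log(np.outer(a, b)[nz])
    )
    return float(terms.sum())


def _expected_mutual_info(a, b, n):
    # hypergeometric model expectation of MI for fixed marginals
    emi = 0.0
    log_n = np.log(n)
    gln_n = gammaln(n + 1)
    for ai in a:
        for bj in b:
            lo = max(1, ai + bj - n)
            hi = min(ai, bj)
            if hi < lo:
                continue
            k = np.arange(lo, hi + 1, dtype=float)
            term1 = k / n * (np.log(k) + log_n - np.log(ai) - np.log(bj))
            log_prob = (
                gammaln(ai + 1) + gammaln(bj + 1)
                + gammaln(n - ai + 1) + gammaln(n - bj + 1)
                - gln_n - gammaln(k + 1) - gammaln(ai - k + 1)
                - gammaln(bj - k + 1) - gammaln(n - ai - bj + k + 1)
            )
            emi += float((term1 * np.exp(log_prob)).sum())
    return emi


def adjusted_mutual_info(truth, pred) -> float:
    """AMI with the hypergeometric expected-MI correction, max-entropy norm."""
    table = contingency(truth, pred)
    if table.n < 2:
        raise ValueError("AMI is undefined for fewer than two events")
    nij = table.counts
    a = nij.sum(axis=1)
    b = nij.sum(axis=0)
    n = table.n
    h_t = _entropy(a, n)
    h_p = _entropy(b, n)
    if h_t == 0.0 and h_p == 0.0:  # both single-cluster: identical partitions
        return 1.0
    mi = _mutual_info(nij, a, b, n)
    emi = _expected_mutual_info(a, b, n)
    denom = max(h_t, h_p) - emi
    if denom == 0.0:
        return 0.0
    return float((mi - emi) / denom)


def fowlkes_mallows(truth, pred) -> float:
    """FMI = TP / sqrt((TP+FP)(TP+FN)) over event pairs."""
    table = contingency(truth, pred)
    if table.n < 2:
        raise ValueError("FMI is undefined for fewer than two events")
    nij = table.counts
    tp = _comb2(nij).sum()
    tp_fp = _comb2(nij.sum(axis=0)).sum()
    tp_fn = _comb2(nij.sum(axis=1)).sum()
    if tp_fp == 0 or tp_fn == 0:
        return 0.0
    return float(tp / np.sqrt(tp_fp * tp_fn))


def _f1_matrix(table: ContingencyTable):
    nij = table.counts.astype(float)
    col = nij.sum(axis=0)  # cluster sizes
    row = nij.sum(axis=1)  # population sizes
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = nij / col[None, :]
        recall = nij / row[:, None]
        f1 = np.where(nij > 0, 2 * precision * recall / (precision + recall), 0.0)
    return np.nan_to_num(precision), np.nan_to_num(recall), f1


def hungarian_f1(truth, pred) -> MatchReport:
    """Match clusters to truth populations maximising total F1 (one-to-one).

    Unmatched truth populations (when there are fewer clusters) score
    precision = recall = F1 = 0.
    """
    table = contingency(truth, pred)
    precision, recall, f1 = _f1_matrix(table)
    rows, cols = linear_sum_assignment(-f1)
    r = len(table.truth_labels)
    mapping = {}
    prec = np.zeros(r)
    rec = np.zeros(r)
    f1s = np.zeros(r)
    matched = dict(zip(rows.tolist(), cols.tolist()))
    for i, t in enumerate(table.truth_labels):
        if i in matched:
            j = matched[i]
            mapping[t] = table.pred_labels[j]
            prec[i], rec[i], f1s[i] = precision[i, j], recall[i, j], f1[i, j]
        else:
            mapping[t] = None
    return MatchReport(
        mapping=mapping,
        precision=prec,
        recall=rec,
        f1=f1s,
        truth_labels=table.truth_labels,
        population_sizes=table.counts.sum(axis=1),
    )


def brute_force_best_f1(table: ContingencyTable) -> float:
    """Exhaustive maximum of summed F1 over injective mappings (tiny tables)."""
    _, _, f1 = _f1_matrix(table)
    r, s = f1.shape
    best = 0.0
    if r <= s:
        for perm in itertools.permutations(range(s), r):
            best = max(best, sum(f1[i, j] for i, j in enumerate(perm)))
    else:
        for perm in itertools.permutations(range(r), s):
            best = max(best, sum(f1[i, j] for j, i in enumerate(perm)))
    return best


def coassociation_consensus(partitions: BasePartitionSet, k: int) -> np.ndarray:
    """Classical consensus: average-linkage cut of the co-association matrix.

    The (i, j) entry is the fraction of partitions placing events i and j
    in the same cluster (sentinel assignments never co-cluster).  The
    N x N matrix restricts this to small N (<= 5000); larger inputs are
    refused because the quadratic memory footprint is the very cost the
    median-based consensus avoids.
    """
    n = partitions.n_events
    if n > COASSOC_CAP:
        raise ValueError(
            f"co-association consensus materialises an N x N matrix; "
            f"N={n} exceeds the {COASSOC_CAP}-event cap"
        )
    b = partitions.n_partitions
    co = np.zeros((n, n))
    for i in range(b):
        lab = partitions.labels[i]
        same = (lab[:, None] == lab[None, :]) & (lab[:, None] != SENTINEL)
        co += same
    co /= b
    np.fill_diagonal(co, 1.0)
    model = AgglomerativeClustering(n_clusters=k, linkage="average", metric="precomputed")
    return model.fit_predict(1.0 - co)


def summary_scores(truth, pred) -> dict:
    """ARI/AMI/FMI/average-F1 in one machine-readable dict."""
    report = hungarian_f1(truth, pred)
    return {
        "ari": adjusted_rand_index(truth, pred),
        "ami": adjusted_mutual_info(truth, pred),
        "fmi": fowlkes_mallows(truth, pred),
        "average_f1": report.average_f1,
        "sd_f1": report.sd_f1,
    }
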