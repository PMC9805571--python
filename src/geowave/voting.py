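"""Event assignment by distance-weighted consensus voting.

Because every base algorithm saw the same events, the pooled clusters
overlap: an event's clusters may land in different consensus clusters.
Such *ambiguous* events are resolved by a score.  For a candidate
consensus C and event t,

    p(C, t)  =  ( sum over member clusters c of C of || t - u^(c) ||_1 ) / |C|
    score(C, t)  =  |C| / p(C, t)

so the winning consensus is the one with many supporting clusters whose
medians sit close to the event (maximum score; p = 0 scores +inf).
Scoring work is O(|ambiguous| x m x d): no N x N structure is ever built,
and ambiguous events are scored in fixed-size chunks that can be
distributed over workers without changing the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from joblib import Parallel, delayed
from scipy.spatial.distance import cdist

from .data import SENTINEL, BasePartitionSet, EventMatrix
from .ensemble import ClusterTable, ConsensusMap
from .median import manhattan_distance

_CHUNK = 4096  # scoring chunk size; fixed so results never depend on n_workers


@dataclass(frozen=True)
class AssignmentScore:
    """Score of one candidate consensus for one event."""

    consensus_label: int
    p: float
    score: float
    consensus_size: int


@dataclass(frozen=True)
class ConsensusResult:
    """Final per-event consensus labels with voting diagnostics.

    ``candidates_per_event`` is the number of distinct consensus clusters
    the event's base clusters pointed at (0 for events every partition
    left unassigned).  ``winning_scores`` holds the vote score of the
    winning consensus for scored events and NaN where no vote was needed
    (a unanimous candidate set).
    """

    labels: np.ndarray
    candidates_per_event: np.ndarray
    winning_scores: np.ndarray
    map: ConsensusMap
    cluster_table: ClusterTable
    event_ids: np.ndarray
    relabel_mapping: dict | None = field(default=None)

    @property
    def n_consensus(self) -> int:
        return int(self.labels.max()) + 1


def _consensus_by_event(
    partitions: BasePartitionSet, table: ClusterTable, cmap: ConsensusMap
) -> np.ndarray:
    """(N, B) matrix of the consensus label each partition votes for (-1 = sentinel)."""
    n, b = partitions.n_events, partitions.n_partitions
    out = np.full((n, b), SENTINEL, dtype=np.int64)
    # per partition: cluster_id -> record row -> consensus label
    for pi in range(b):
        rows = [
            (rec.cluster_id, idx)
            for idx, rec in enumerate(table.records)
            if rec.partition_index == pi
        ]
        if not rows:
            raise ValueError(f"consensus map lacks clusters for partition {pi}")
        max_cid = max(cid for cid, _ in rows)
        lut = np.full(max_cid + 2, SENTINEL, dtype=np.int64)
        for cid, idx in rows:
            lut[cid] = cmap.consensus_of[idx]
        labels = partitions.labels[pi]
        assigned = labels != SENTINEL
        if labels[assigned].max(initial=-1) > max_cid:
            raise ValueError(
                f"partition {pi} contains cluster ids missing from the cluster table"
            )
        out[assigned, pi] = lut[labels[assigned]]
    return out


def candidate_consensuses(
    event_index: int,
    partitions: BasePartitionSet,
    table: ClusterTable,
    cmap: ConsensusMap,
) -> set:
    """Consensus labels the event's own base clusters map to (1..B of them)."""
    votes = _consensus_by_event(partitions, table, cmap)[event_index]
    cands = set(int(v) for v in votes if v != SENTINEL)
    if not cands:
        raise ValueError(f"event {event_index} is unassigned in every partition")
    return cands


def score_consensus(
    event, consensus_label: int, table: ClusterTable, cmap: ConsensusMap
) -> AssignmentScore:
    """Evaluate the voting score of one consensus for one event vector.

    p is the mean Manhattan distance from the event to the medians of ALL
    member clusters of the consensus; score = |C| / p (+inf when p = 0).
    """
    members = cmap.members(consensus_label)
    if members.size == 0:
        raise ValueError(f"consensus {consensus_label} has no member clusters")
    event = np.asarray(event, dtype=float)
    total = sum(manhattan_distance(event, table.median_matrix[i]) for i in members)
    size = int(members.size)
    p = total / size
    score = np.inf if p == 0 else size / p
    return AssignmentScore(int(consensus_label), p, score, size)


def _score_chunk(values, median_matrix, sizes, membership):
    """Voting scores of every consensus for one chunk of events."""
    d = cdist(values, median_matrix, metric="cityblock")  # (chunk, m)
    sumdist = d @ membership  # (chunk, K): per-consensus summed distance
    with np.errstate(divide="ignore", invalid="ignore"):
        p = sumdist / sizes[None, :]
        score = np.where(sumdist == 0.0, np.inf, sizes[None, :] / p)
    return score


def assign_events(
    events: EventMatrix,
    partitions: BasePartitionSet,
    table: ClusterTable,
    cmap: ConsensusMap,
    n_workers: int = 1,
) -> ConsensusResult:
    """Assign every event to exactly one consensus cluster.

    Events whose base clusters all point at one consensus take that label
    without scoring.  Events with several candidates take the candidate
    with the maximum voting score (finite ties and +inf ties both break
    to the smallest consensus label).  Events left unassigned by every
    partition fall back to the consensus of the nearest pooled median
    (Manhattan distance).  Output is identical for any ``n_workers``.
    """
    partitions.check_aligned(events)
    n = events.n_events
    k = cmap.n_consensus
    votes = _consensus_by_event(partitions, table, cmap)  # (N, B)

    # candidate bitmap (N, K) and candidate counts
    cand = np.zeros((n, k), dtype=bool)
    row_idx = np.repeat(np.arange(n), votes.shape[1])
    flat = votes.ravel()
    ok = flat != SENTINEL
    cand[row_idx[ok], flat[ok]] = True
    n_cand = cand.sum(axis=1).astype(np.int64)

    labels = np.full(n, -1, dtype=np.int64)
    winning = np.full(n, np.nan)

    unanimous = n_cand == 1
    labels[unanimous] = np.argmax(cand[unanimous], axis=1)

    # consensus membership indicator over pooled clusters and |C| sizes
    member = np.zeros((table.n_clusters, k))
    member[np.arange(table.n_clusters), cmap.consensus_of] = 1.0
    sizes = member.sum(axis=0)

    ambiguous = np.flatnonzero(n_cand >= 2)
    if ambiguous.size:
        chunks = [ambiguous[i:i + _CHUNK] for i in range(0, ambiguous.size, _CHUNK)]

        def run(idx):
            return _score_chunk(events.values[idx], table.median_matrix, sizes, member)

        if n_workers > 1 and len(chunks) > 1:
            scored = Parallel(n_jobs=n_workers)(delayed(run)(c) for c in chunks)
        else:
            scored = [run(c) for c in chunks]
        for idx, score in zip(chunks, scored):
            masked = np.where(cand[idx], score, -np.inf)
            win = np.argmax(masked, axis=1)  # first max -> smallest label
            labels[idx] = win
            winning[idx] = masked[np.arange(len(idx)), win]

    orphans = np.flatnonzero(n_cand == 0)
    if orphans.size:
        d = cdist(events.values[orphans], table.median_matrix, metric="cityblock")
        nearest = np.argmin(d, axis=1)
        labels[orphans] = cmap.consensus_of[nearest]
        for j, ev in enumerate(orphans):
            winning[ev] = score_consensus(
                events.values[ev], int(labels[ev]), table, cmap
            ).score

    return ConsensusResult(
        labels=labels,
        candidates_per_event=n_cand,
        winning_scores=winning,
        map=cmap,
        cluster_table=table,
        event_ids=events.event_ids,
    )


def relabel_contiguous(result: ConsensusResult) -> ConsensusResult:
    """Re-encode consensus labels 0..K'-1 by decreasing event count.

    Consensus clusters that received zero events are dropped from the
    label vocabulary; the old -> new mapping is recorded on the result.
    Idempotent.
    """
    counts = np.bincount(result.labels, minlength=result.map.n_consensus)
    present = np.flatnonzero(counts > 0)
    # decreasing count, ties broken by original label for determinism
    order = present[np.lexsort((present, -counts[present]))]
    mapping = {int(old): new for new, old in enumerate(order)}
    lut = np.full(result.map.n_consensus, -1, dtype=np.int64)
    for old, new in mapping.items():
        lut[old] = new
    return ConsensusResult(
        labels=lut[result.labels],
        candidates_per_event=result.candidates_per_event,
        winning_scores=result.winning_scores,
        map=result.map,
        cluster_table=result.cluster_table,
        event_ids=result.event_ids,
        relabel_mapping=mapping,
    )
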