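"""Candidate resolution and the distance-weighted voting score."""

import numpy as np
import pytest

import geowave as gw
from geowave.ensemble import ClusterRecord, ClusterTable, ConsensusMap


def _table_from_medians(medians, partition_of=None):
    medians = np.asarray(medians, dtype=float)
    m = len(medians)
    partition_of = partition_of or [0] * m
    recs = tuple(
        ClusterRecord(partition_of[i], i, np.array([i]), medians[i])
        for i in range(m)
    )
    return ClusterTable(recs, medians, tuple(f"m{j}" for j in range(medians.shape[1])))


class TestScoreConsensus:
    def test_hand_evaluable_case(self):
        # t=(0,0), member medians {(1,0),(0,2)}: p = (1+2)/2, score = 2/p
        table = _table_from_medians([[1.0, 0.0], [0.0, 2.0]])
        cmap = ConsensusMap(np.array([0, 0]), 1)
        s = gw.score_consensus([0.0, 0.0], 0, table, cmap)
        assert s.p == 1.5
        assert s.score == 2 / 1.5
        assert s.consensus_size == 2

    def test_zero_distance_scores_infinite(self):
        table = _table_from_medians([[3.0, 4.0]])
        cmap = ConsensusMap(np.array([0]), 1)
        s = gw.score_consensus([3.0, 4.0], 0, table, cmap)
        assert s.p == 0.0 and np.isinf(s.score)

    def test_linearity_in_distances(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            medians = rng.normal(size=(3, 5))
            t = rng.normal(size=5)
            table1 = _table_from_medians(medians)
            table2 = _table_from_medians(t + 2 * (medians - t))  # doubled gaps
            cmap = ConsensusMap(np.zeros(3, dtype=int), 1)
            s1 = gw.score_consensus(t, 0, table1, cmap)
            s2 = gw.score_consensus(t, 0, table2, cmap)
            assert np.isclose(s2.p, 2 * s1.p)
            assert np.isclose(s2.score, s1.score / 2)

    def test_dominance_equal_size_smaller_distance_wins(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            t = rng.normal(size=4)
            near = t + rng.normal(scale=0.5, size=(2, 4))
            far = t + rng.normal(scale=0.5, size=(2, 4))
            d_near = np.abs(near - t).sum()
            d_far = np.abs(far - t).sum()
            if d_near == d_far:
                continue
            if d_near > d_far:
                near, far = far, near
            table = _table_from_medians(np.vstack([near, far]))
            cmap = ConsensusMap(np.array([0, 0, 1, 1]), 2)
            s0 = gw.score_consensus(t, 0, table, cmap)
            s1 = gw.score_consensus(t, 1, table, cmap)
            assert s0.score > s1.score


class TestCandidates:
    def test_candidate_sets(self, blob_data):
        events, _, parts = blob_data
        table = gw.pool_clusters(events, parts)
        cmap = gw.metacluster(table, "kmeans", k=5, seed=0)
        b = parts.n_partitions
        for ev in range(0, events.n_events, 97):
            cands = gw.candidate_consensuses(ev, parts, table, cmap)
            assert 1 <= len(cands) <= b

    def test_mapping_to_fewer_consensuses(self):
        events = gw.EventMatrix(np.zeros((1, 2)), ("a", "b"))
        parts = gw.BasePartitionSet(np.array([[0], [0], [0]]), ("p", "q", "r"))
        table = gw.pool_clusters(events, parts)
        # clusters of p,q -> consensus 0; cluster of r -> consensus 2... must be dense
        cmap = ConsensusMap(np.array([0, 0, 1]), 2)
        assert gw.candidate_consensuses(0, parts, table, cmap) == {0, 1}


class TestAssignEvents:
    def test_unanimous_ensemble_reproduces_base(self, blob_data):
        events, _, parts = blob_data
        base = parts.labels[1]  # the k=5 run
        dup = gw.BasePartitionSet(np.vstack([base, base]), ("a", "b"))
        table = gw.pool_clusters(events, dup)
        cmap = gw.metacluster(table, "agglomerative", k=5)
        res = gw.assign_events(events, dup, table, cmap)
        assert gw.adjusted_rand_index(base, res.labels) == 1.0
        assert np.all(res.candidates_per_event == 1)

    def test_max_score_rule_prefers_infinite(self):
        # event sits exactly on the sole median of consensus 1
        events = gw.EventMatrix(np.array([[5.0, 5.0]]), ("a", "b"))
        parts = gw.BasePartitionSet(np.array([[0], [0]]), ("p", "q"))
        table = gw.pool_clusters(events, parts)  # both medians = (5,5)
        # force the two pooled clusters into different consensuses
        cmap = ConsensusMap(np.array([0, 1]), 2)
        res = gw.assign_events(events, parts, table, cmap)
        # both score +inf -> tie breaks to smallest label
        assert res.labels[0] == 0
        assert np.isinf(res.winning_scores[0])

    def test_infinite_score_beats_finite(self):
        # event 0 sits exactly on the median of the consensus-1 cluster
        events = gw.EventMatrix(np.array([[5.0, 5.0], [0.0, 0.0]]), ("a", "b"))
        parts = gw.BasePartitionSet(np.array([[0, 0], [0, 1]]), ("p", "q"))
        table = gw.pool_clusters(events, parts)
        cmap = ConsensusMap(np.array([0, 1, 0]), 2)
        res = gw.assign_events(events, parts, table, cmap)
        assert res.labels[0] == 1
        assert np.isinf(res.winning_scores[0])

    def test_all_sentinel_fallback_nearest_median(self):
        values = np.array([[0.0, 0.0], [10.0, 10.0], [9.0, 9.0]])
        events = gw.EventMatrix(values, ("a", "b"))
        parts = gw.BasePartitionSet(
            np.array([[0, 1, -1], [0, 1, -1]]), ("p", "q")
        )
        table = gw.pool_clusters(events, parts)
        cmap = gw.metacluster(table, "agglomerative", k=2)
        res = gw.assign_events(events, parts, table, cmap)
        assert res.labels[2] == res.labels[1]  # nearest median is the (10,10) cluster
        assert res.candidates_per_event[2] == 0

    def test_permutation_invariance(self, blob_data):
        events, _, parts = blob_data
        table = gw.pool_clusters(events, parts)
        cmap = gw.metacluster(table, "kmeans", k=5, seed=3)
        res = gw.assign_events(events, parts, table, cmap)
        rng = np.random.default_rng(0)
        perm = rng.permutation(events.n_events)
        ev_p = gw.EventMatrix(events.values[perm], events.marker_names)
        parts_p = gw.BasePartitionSet(parts.labels[:, perm], parts.partition_names)
        table_p = gw.pool_clusters(ev_p, parts_p)
        res_p = gw.assign_events(ev_p, parts_p, table_p, cmap)
        assert np.array_equal(res.labels[perm], res_p.labels)

    @pytest.mark.parametrize("workers", [2, 8])
    def test_worker_count_never_changes_output(self, blob_data, workers):
        events, _, parts = blob_data
        table = gw.pool_clusters(events, parts)
        cmap = gw.metacluster(table, "kmeans", k=5, seed=1)
        serial = gw.assign_events(events, parts, table, cmap, n_workers=1)
        parallel = gw.assign_events(events, parts, table, cmap, n_workers=workers)
        assert np.array_equal(serial.labels, parallel.labels)
        assert np.array_equal(
            serial.winning_scores, parallel.winning_scores, equal_nan=True
        )


class TestRelabel:
    def test_relabel_by_decreasing_count_and_idempotence(self, blob_data):
        events, _, parts = blob_data
        res = gw.GeoWaVe(events, parts, meta_method="kmeans", k=5, seed=0).fit(
            relabel=False
        ).consensus_result
        rel = gw.relabel_contiguous(res)
        counts = np.bincount(rel.labels)
        assert np.all(np.diff(counts) <= 0)
        again = gw.relabel_contiguous(rel)
        assert np.array_equal(rel.labels, again.labels)
        # event counts preserved under re-encoding
        assert sorted(np.bincount(res.labels, minlength=res.map.n_consensus),
                      reverse=True)[: len(counts)] == counts.tolist()

    def test_hand_case(self):
        labels = np.array([5, 5, 9])
        res = gw.ConsensusResult(
            labels=labels,
            candidates_per_event=np.ones(3, dtype=int),
            winning_scores=np.full(3, np.nan),
            map=ConsensusMap(np.arange(10), 10),
            cluster_table=_table_from_medians(np.zeros((10, 2))),
            event_ids=np.arange(3),
        )
        rel = gw.relabel_contiguous(res)
        assert rel.labels.tolist() == [0, 0, 1]
        assert rel.relabel_mapping == {5: 0, 9: 1}
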