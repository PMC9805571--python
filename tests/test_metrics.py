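"""External metrics: chance-adjusted indices, Hungarian F1, co-association oracle."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import (
    adjusted_mutual_info_score,
    adjusted_rand_score,
    fowlkes_mallows_score,
)

import geowave as gw
from geowave.metrics import brute_force_best_f1, contingency


def _random_pair(rng, n=60, kt=4, kp=5):
    return rng.integers(0, kt, size=n), rng.integers(0, kp, size=n)


class TestContingency:
    def test_direct_count(self):
        table = contingency([0, 0, 1, 1], [0, 0, 1, 2])
        assert table.counts.tolist() == [[2, 0, 0], [0, 1, 1]]

    def test_marginals_equal_label_frequencies(self):
        rng = np.random.default_rng(0)
        truth, pred = _random_pair(rng)
        table = contingency(truth, pred)
        assert np.array_equal(table.counts.sum(axis=1), np.bincount(truth))
        assert np.array_equal(table.counts.sum(axis=0), np.bincount(pred))

    def test_sentinels_excluded_pairwise(self):
        table = contingency([0, -1, 1, 1], [0, 0, -1, 1])
        assert table.n == 2

    def test_all_sentinel_rejected(self):
        with pytest.raises(ValueError, match="jointly labelled"):
            contingency([-1, -1], [0, 1])


class TestIndices:
    def test_identical_partitions_attain_maxima(self):
        labels = np.array([0, 0, 1, 1, 2, 2, 2])
        assert gw.adjusted_rand_index(labels, labels) == 1.0
        assert gw.adjusted_mutual_info(labels, labels) == pytest.approx(1.0)
        assert gw.fowlkes_mallows(labels, labels) == 1.0

    def test_hand_computed_ari_four_sevenths(self):
        assert gw.adjusted_rand_index([0, 0, 1, 1], [0, 0, 1, 2]) == pytest.approx(4 / 7)

    def test_chance_level_zeros(self):
        truth = np.array([0, 0, 1, 1, 2, 2])
        constant = np.zeros(6, dtype=int)
        assert gw.adjusted_rand_index(truth, constant) == 0.0
        assert gw.adjusted_mutual_info(truth, constant) == 0.0

    def test_fmi_no_shared_pairs(self):
        assert gw.fowlkes_mallows([0, 0, 1, 1], [0, 1, 0, 1]) == 0.0

    def test_relabelling_and_symmetry_invariance(self):
        rng = np.random.default_rng(1)
        truth, pred = _random_pair(rng)
        renamed = (pred + 3) * 7  # injective relabelling
        for fn in (gw.adjusted_rand_index, gw.adjusted_mutual_info, gw.fowlkes_mallows):
            assert fn(truth, pred) == pytest.approx(fn(truth, renamed))
        for fn in (gw.adjusted_rand_index, gw.fowlkes_mallows):
            assert fn(truth, pred) == pytest.approx(fn(pred, truth))

    @pytest.mark.parametrize("seed", range(20))
    def test_agrees_with_independent_implementation(self, seed):
        """Own contingency-table formulas vs the scikit-learn implementations."""
        rng = np.random.default_rng(seed)
        truth, pred = _random_pair(rng, n=int(rng.integers(20, 200)))
        assert gw.adjusted_rand_index(truth, pred) == pytest.approx(
            adjusted_rand_score(truth, pred), abs=1e-9
        )
        assert gw.adjusted_mutual_info(truth, pred) == pytest.approx(
            adjusted_mutual_info_score(truth, pred, average_method="max"), abs=1e-9
        )
        assert gw.fowlkes_mallows(truth, pred) == pytest.approx(
            fowlkes_mallows_score(truth, pred), abs=1e-9
        )

    def test_fmi_equals_pair_counting_brute_force(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            n = int(rng.integers(10, 51))
            truth = rng.integers(0, 4, size=n)
            pred = rng.integers(0, 4, size=n)
            tp = fp = fn = 0
            for i, j in itertools.combinations(range(n), 2):
                same_t = truth[i] == truth[j]
                same_p = pred[i] == pred[j]
                tp += same_t and same_p
                fp += (not same_t) and same_p
                fn += same_t and (not same_p)
            expected = tp / np.sqrt((tp + fp) * (tp + fn)) if tp else 0.0
            assert gw.fowlkes_mallows(truth, pred) == pytest.approx(expected)

    def test_single_event_undefined(self):
        with pytest.raises(ValueError):
            gw.adjusted_rand_index([0], [0])


class TestHungarianF1:
    def test_perfect_prediction(self):
        labels = np.array([0, 0, 1, 1, 2])
        report = gw.hungarian_f1(labels, labels)
        assert np.all(report.f1 == 1.0)
        assert report.average_f1 == 1.0 and report.sd_f1 == 0.0

    @pytest.mark.parametrize("seed", range(30))
    def test_total_f1_is_exhaustive_maximum(self, seed):
        rng = np.random.default_rng(seed)
        kt, kp = int(rng.integers(2, 7)), int(rng.integers(2, 7))
        truth = rng.integers(0, kt, size=40)
        pred = rng.integers(0, kp, size=40)
        report = gw.hungarian_f1(truth, pred)
        assert report.f1.sum() == pytest.approx(
            brute_force_best_f1(contingency(truth, pred)), abs=1e-12
        )

    def test_more_clusters_than_truth(self):
        truth = np.array([0, 0, 0, 1, 1, 1])
        pred = np.array([0, 0, 1, 2, 3, 3])
        report = gw.hungarian_f1(truth, pred)
        matched = [c for c in report.mapping.values() if c is not None]
        assert len(matched) == 2  # exactly |truth| clusters matched
        assert len(set(matched)) == 2  # one-to-one

    def test_unmatched_truth_scores_zero(self):
        truth = np.array([0, 1, 2, 0, 1, 2])
        pred = np.array([0, 1, 0, 0, 1, 1])  # only two clusters
        report = gw.hungarian_f1(truth, pred)
        assert (report.f1 == 0.0).sum() >= 1
        assert None in report.mapping.values()

    def test_report_frame_columns(self):
        truth = np.array([0, 0, 0, 0, 1, 1])
        report = gw.hungarian_f1(truth, truth).to_frame()
        assert {"population", "precision", "recall", "f1",
                "size_fraction", "size_normalized"} <= set(report.columns)
        assert report["size_fraction"].sum() == pytest.approx(1.0)
        assert report["size_normalized"].max() == 1.0


class TestCoassociation:
    def test_identical_partitions_recovered(self):
        base = np.array([0, 0, 1, 1, 2, 2])
        parts = gw.BasePartitionSet(np.vstack([base, base]), ("a", "b"))
        labels = gw.coassociation_consensus(parts, k=3)
        assert gw.adjusted_rand_index(base, labels) == 1.0

    def test_cap_enforced(self):
        from geowave.metrics import COASSOC_CAP
        labels = np.zeros((2, COASSOC_CAP + 1), dtype=int)
        labels[:, 0] = 1
        parts = gw.BasePartitionSet(labels, ("a", "b"))
        with pytest.raises(ValueError, match="cap"):
            gw.coassociation_consensus(parts, k=2)

    def test_agrees_with_median_consensus_on_blobs(self, blob_data):
        events, truth, parts = blob_data
        coassoc = gw.coassociation_consensus(parts, k=5)
        geow = gw.GeoWaVe(events, parts, meta_method="agglomerative", k=5).fit()
        assert gw.adjusted_rand_index(coassoc, geow.labels) >= 0.99
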