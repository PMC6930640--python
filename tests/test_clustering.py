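"""Tanimoto similarity, binning clustering, and cluster prioritization."""

import numpy as np
import pandas as pd
import pytest

from fpqsar import clustering, synthetic
from fpqsar.clustering import ClusterSummary


class TestTanimoto:
    def test_identical_fingerprints(self):
        assert clustering.tanimoto([1, 0, 2], [1, 0, 2]) == 1.0

    def test_disjoint_fingerprints(self):
        assert clustering.tanimoto([1, 1, 0, 0], [0, 0, 1, 1]) == 0.0

    def test_partial_overlap_set_arithmetic(self):
        a = [1, 1, 1, 1, 1, 0, 0, 0, 0, 0]
        b = [1, 1, 1, 0, 0, 1, 1, 0, 0, 0]
        assert clustering.tanimoto(a, b) == pytest.approx(3 / 7)

    def test_counts_binarized_by_default(self):
        assert clustering.tanimoto([5, 0], [1, 0]) == 1.0
        assert clustering.tanimoto([5, 0], [1, 0], count_based=True) == pytest.approx(0.2)

    def test_both_empty_rejected(self):
        with pytest.raises(ValueError):
            clustering.tanimoto([0, 0], [0, 0])


class TestBinCluster:
    def test_all_dissimilar_gives_singletons(self):
        X = np.eye(4, dtype=int)
        labels = clustering.bin_cluster(X, cutoff=0.8)
        assert len(set(labels.tolist())) == 4

    def test_chain_merges_transitively(self):
        # a~b and b~c above cutoff, a~c below: one component {a, b, c}
        a = [1] * 8 + [0] * 4
        b = [1] * 6 + [0, 0] + [1, 1] + [0, 0]
        c = [1] * 4 + [0] * 4 + [1] * 4
        sim = clustering.pairwise_tanimoto(np.array([a, b, c]))
        assert sim[0, 1] >= 0.6 and sim[1, 2] >= 0.6 and sim[0, 2] < 0.6
        labels = clustering.bin_cluster(np.array([a, b, c]), cutoff=0.6)
        assert len(set(labels.tolist())) == 1

    def test_recovers_planted_partition(self):
        m, truth = synthetic.generate_clustered_fingerprints(
            [(12, 0.9), (9, 0.9)], n_singletons=4, seed=3
        )
        labels = clustering.bin_cluster(m, cutoff=0.8)
        for cid in (0, 1):
            members = truth == cid
            assert len(set(labels[members].tolist())) == 1
            assert not set(labels[members].tolist()) & set(labels[~members].tolist())

    def test_input_order_invariance(self):
        m, _ = synthetic.generate_clustered_fingerprints([(8, 0.9)], 3, seed=4)
        labels = clustering.bin_cluster(m, cutoff=0.8)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(labels))
        labels_p = clustering.bin_cluster(m.values[perm], cutoff=0.8)
        # same partition up to relabelling
        pairs = {(labels[i] == labels[j]) == (labels_p[pi] == labels_p[pj])
                 for pi, i in enumerate(perm) for pj, j in enumerate(perm)}
        assert pairs == {True}

    def test_raising_cutoff_refines_partition(self):
        m, _ = synthetic.generate_clustered_fingerprints(
            [(10, 0.85), (10, 0.9)], 3, seed=5
        )
        low = clustering.bin_cluster(m, cutoff=0.8)
        high = clustering.bin_cluster(m, cutoff=0.95)
        # any pair together at the high cutoff is together at the low one
        n = len(low)
        for i in range(n):
            for j in range(i + 1, n):
                if high[i] == high[j]:
                    assert low[i] == low[j]


class TestSummarize:
    def _compounds(self, pic50, mw=None):
        n = len(pic50)
        return pd.DataFrame(
            {
                "compound_id": [f"C{i}" for i in range(n)],
                "pIC50": pic50,
                "MW": mw if mw is not None else np.full(n, 400.0),
                "ALogP": np.full(n, 3.0),
            }
        )

    def test_constant_cluster_mean_and_sd(self):
        labels = np.zeros(25, dtype=int)
        comp = self._compounds([7.0] * 25)
        out = clustering.summarize_clusters(labels, comp, min_size=20)
        assert len(out) == 1
        assert out[0].mean_pic50 == 7.0 and out[0].sd_pic50 == 0.0

    def test_retention_rule_drops_small_clusters(self):
        labels = np.array([0] * 25 + [1] * 19 + [2])
        comp = self._compounds(np.linspace(5, 8, 45))
        out = clustering.summarize_clusters(labels, comp, min_size=20)
        assert [s.cluster_id for s in out] == [0]
        assert out[0].N == 25

    def test_delta_against_full_dataset_mean(self):
        labels = np.array([0] * 20 + [-1] * 20)
        pic50 = np.array([8.0] * 20 + [6.0] * 20)
        out = clustering.summarize_clusters(labels, self._compounds(pic50), min_size=20)
        assert out[0].delta_vs_dataset == pytest.approx(8.0 - 7.0)


class TestPrioritize:
    def _summary(self, cid, delta, n=25):
        return ClusterSummary(
            cluster_id=cid, member_ids=[], N=n, mean_pic50=6.5 + delta,
            sd_pic50=0.1, mean_mw=None, sd_mw=None, mean_alogp=None,
            sd_alogp=None, delta_vs_dataset=delta,
        )

    def test_descending_delta(self):
        ranked = clustering.prioritize(
            [self._summary(1, 0.5), self._summary(2, 2.0), self._summary(3, -1.0)]
        )
        assert [s.cluster_id for s in ranked] == [2, 1, 3]

    def test_published_style_cluster_table_ordering(self):
        """Typed-in cluster means: the two nanomolar-potency clusters
        (means 10.04 and 9.76 vs dataset mean ~7.3) outrank all others."""
        means = {1: 7.30, 2: 7.57, 3: 7.70, 4: 6.98, 5: 9.76,
                 6: 10.04, 7: 6.48, 8: 8.12, 9: 6.06, 10: 6.97}
        sizes = {1: 876, 2: 491, 3: 137, 4: 23, 5: 58,
                 6: 38, 7: 25, 8: 25, 9: 20, 10: 24}
        dataset_mean = 7.3
        summaries = [
            ClusterSummary(
                cluster_id=c, member_ids=[], N=sizes[c], mean_pic50=means[c],
                sd_pic50=0.5, mean_mw=None, sd_mw=None, mean_alogp=None,
                sd_alogp=None, delta_vs_dataset=means[c] - dataset_mean,
            )
            for c in means
        ]
        ranked = clustering.prioritize(summaries)
        assert [s.cluster_id for s in ranked[:2]] == [6, 5]

    def test_tie_broken_by_larger_n_then_smaller_id(self):
        ranked = clustering.prioritize(
            [self._summary(2, 1.0, n=20), self._summary(1, 1.0, n=30),
             self._summary(3, 1.0, n=30)]
        )
        assert [s.cluster_id for s in ranked] == [1, 3, 2]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            clustering.prioritize([])


def test_retained_sizes_bounded_by_total():
    m, labels, compounds = synthetic.generate_clustered_dataset(
        [(25, 0.9), (20, 0.9)], 5, seed=6
    )
    found = clustering.bin_cluster(m, cutoff=0.8)
    out = clustering.summarize_clusters(found, compounds, min_size=20)
    assert sum(s.N for s in out) <= len(compounds)
    assert all(s.N >= 20 for s in out)
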