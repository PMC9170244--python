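"""Connectivity matrices, per-neuron stats, block sums and thresholding."""

import numpy as np
import pandas as pd
import pytest

import grnseg as g
from grnseg.connectivity import totals_from_table


def table(rows):
    return g.SynapseTable(pd.DataFrame(rows, columns=["pre_id", "post_id", "count"]))


def assignment(ids, labels):
    return g.GroupAssignment(list(ids), np.asarray(labels), k=int(max(labels)))


class TestBuildMatrix:
    def test_duplicate_rows_summed(self):
        m = g.build_matrix(table([("a", "b", 2), ("a", "b", 1), ("b", "c", 4)]),
                           ["a", "b", "c"])
        assert m.counts[0, 1] == 3 and m.counts[1, 2] == 4
        assert m.counts.sum() == 7

    def test_empty_table_zero_matrix(self):
        m = g.build_matrix(g.SynapseTable(pd.DataFrame()), ["a", "b"])
        assert m.total == 0

    def test_unknown_id_raises_with_name(self):
        with pytest.raises(KeyError, match="x"):
            g.build_matrix(table([("a", "x", 1)]), ["a", "b"])

    def test_drop_unknown_counts_dropped_rows(self):
        m = g.build_matrix(
            table([("a", "b", 2), ("a", "x", 9)]), ["a", "b"], drop_unknown=True
        )
        assert m.total == 2 and m.n_dropped_rows == 1

    def test_dropped_rows_still_in_table_totals(self):
        t = table([("a", "b", 2), ("a", "x", 9), ("y", "a", 3)])
        tot = totals_from_table(t)
        tot = tot.set_index("neuron_id")
        assert tot.loc["a", "n_pre"] == 11 and tot.loc["a", "n_post"] == 3


class TestNeuronStats:
    def test_input_fraction_direct_ratio(self):
        m = g.build_matrix(table([("a", "b", 39)]), ["a", "b"])
        totals = pd.DataFrame(
            {"neuron_id": ["a", "b"], "n_pre": [50, 10], "n_post": [20, 100]}
        )
        df, _ = g.neuron_stats(m, totals)
        df = df.set_index("neuron_id")
        assert df.loc["b", "input_fraction_from_cohort"] == pytest.approx(0.39)
        assert df.loc["a", "input_fraction_from_cohort"] == 0.0

    def test_zero_postsyn_total_gives_zero_fraction(self):
        m = g.build_matrix(g.SynapseTable(pd.DataFrame()), ["a"])
        df, summary = g.neuron_stats(m)
        assert df.loc[0, "input_fraction_from_cohort"] == 0.0
        assert summary["totals_defaulted_to_matrix_sums"]

    def test_means_and_standard_errors_match_hand_computation(self):
        m = g.build_matrix(table([("a", "b", 10), ("b", "c", 6), ("a", "c", 4)]),
                           ["a", "b", "c"])
        totals = pd.DataFrame(
            {"neuron_id": ["a", "b", "c"], "n_pre": [20, 8, 2], "n_post": [5, 25, 30]}
        )
        _, s = g.neuron_stats(m, totals)
        pre = np.array([20, 8, 2])
        post = np.array([5, 25, 30])
        frac = np.array([0 / 5, 10 / 25, 10 / 30])
        assert s["mean_n_presyn_sites"] == pytest.approx(pre.mean())
        assert s["se_n_presyn_sites"] == pytest.approx(pre.std(ddof=1) / np.sqrt(3))
        assert s["mean_n_postsyn_sites"] == pytest.approx(post.mean())
        assert s["mean_input_fraction_from_cohort"] == pytest.approx(frac.mean())

    def test_totals_below_cohort_sums_rejected(self):
        m = g.build_matrix(table([("a", "b", 10)]), ["a", "b"])
        totals = pd.DataFrame(
            {"neuron_id": ["a", "b"], "n_pre": [10, 0], "n_post": [0, 5]}
        )
        with pytest.raises(ValueError, match="below"):
            g.neuron_stats(m, totals)


class TestGroupBlockSums:
    def test_four_neuron_two_group_arithmetic(self):
        t = table(
            [("a", "b", 9), ("c", "d", 6), ("a", "c", 10), ("c", "b", 3)]
        )
        m = g.build_matrix(t, ["a", "b", "c", "d"])
        s = g.group_block_sums(m, assignment(["a", "b", "c", "d"], [1, 1, 2, 2]))
        assert s.total == 28
        np.testing.assert_array_equal(s.block_sums, [[9, 10], [3, 6]])
        assert s.within_fraction == pytest.approx(15 / 28)
        assert s.within_fraction + s.between_fraction == pytest.approx(1.0)

    def test_single_group_all_within(self):
        m = g.build_matrix(table([("a", "b", 5), ("b", "a", 2)]), ["a", "b"])
        s = g.group_block_sums(m, assignment(["a", "b"], [1, 1]))
        assert s.within_fraction == 1.0

    def test_incoming_within_share_on_block_column(self):
        # a group receiving 1468 within and 38+156+130 from three others:
        # its incoming within-share is 1468/1792
        block = np.array(
            [
                [50, 0, 0, 38],
                [0, 60, 0, 156],
                [0, 0, 70, 130],
                [0, 0, 0, 1468],
            ]
        )
        col = block[:, 3]
        assert col.sum() == 1792
        assert col[3] / col.sum() == pytest.approx(1468 / 1792)
        assert 1468 / 1792 == pytest.approx(0.8192, abs=5e-5)

    def test_unlabeled_neuron_rejected(self):
        m = g.build_matrix(table([("a", "b", 1)]), ["a", "b"])
        partial = g.GroupAssignment(["a"], np.array([1]), k=1)
        with pytest.raises(KeyError):
            g.group_block_sums(m, partial)

    def test_conservation_over_random_partitions(self, rng):
        counts = rng.integers(0, 9, size=(10, 10))
        np.fill_diagonal(counts, 0)
        m = g.ConnectivityMatrix([f"n{i}" for i in range(10)], counts)
        for _ in range(5):
            labels = rng.integers(1, 4, size=10)
            labels[:3] = [1, 2, 3]  # keep labels contiguous
            s = g.group_block_sums(m, assignment(m.neuron_ids, labels))
            assert s.block_sums.sum() == m.total == s.total

    def test_refinement_never_increases_within_fraction(self, rng):
        counts = rng.integers(0, 7, size=(12, 12))
        np.fill_diagonal(counts, 0)
        m = g.ConnectivityMatrix([f"n{i}" for i in range(12)], counts)
        coarse = np.array([1] * 6 + [2] * 6)
        s0 = g.group_block_sums(m, assignment(m.neuron_ids, coarse))
        fine = np.array([1] * 3 + [3] * 3 + [2] * 6)
        s1 = g.group_block_sums(m, assignment(m.neuron_ids, fine))
        assert s1.within_fraction <= s0.within_fraction + 1e-12


class TestThresholdEdges:
    def test_entries_below_threshold_zeroed(self):
        m = g.ConnectivityMatrix(["a", "b"], np.array([[0, 4], [5, 0]]))
        t = g.threshold_edges(m, 5)
        np.testing.assert_array_equal(t.counts, [[0, 0], [5, 0]])

    def test_threshold_one_is_identity(self):
        m = g.ConnectivityMatrix(["a", "b"], np.array([[0, 4], [5, 0]]))
        np.testing.assert_array_equal(g.threshold_edges(m, 1).counts, m.counts)

    def test_monotonicity_in_threshold(self, rng):
        counts = rng.integers(0, 12, size=(8, 8))
        np.fill_diagonal(counts, 0)
        m = g.ConnectivityMatrix([f"n{i}" for i in range(8)], counts)
        prev = m
        for t in range(1, 14):
            cur = g.threshold_edges(m, t)
            assert (cur.counts <= prev.counts).all()
            assert cur.total <= prev.total
            assert (cur.counts > 0).sum() <= (prev.counts > 0).sum()
            prev = cur

    def test_thresholded_between_share_on_planted_toy(self):
        # hand-enumerated: edges >=5 are a->b (6, within) and c->a (7, between)
        t = table(
            [("a", "b", 6), ("b", "a", 2), ("c", "a", 7), ("a", "c", 4), ("c", "d", 3)]
        )
        m = g.build_matrix(t, ["a", "b", "c", "d"])
        s = g.group_block_sums(
            g.threshold_edges(m, 5), assignment(["a", "b", "c", "d"], [1, 1, 2, 2])
        )
        assert s.total == 13
        assert s.between_fraction == pytest.approx(7 / 13)
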