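"""Feature merging, min-max scaling, Ward linkage, elbow selection, cuts."""

import warnings

import numpy as np
import pytest

import grnseg as g
from conftest import naive_ward, partition_sets


def features_1d(xs):
    n = len(xs)
    ids = [f"n{i}" for i in range(n)]
    return g.MergedFeatureMatrix(
        ids, np.asarray(xs, float).reshape(-1, 1), {"x": (0, 1)}
    )


def sim_conn(n, rng):
    vals = rng.uniform(0, 1, size=(n, n))
    vals = (vals + vals.T) / 2
    np.fill_diagonal(vals, 1.0)
    sim = g.SimilarityMatrix([f"n{i}" for i in range(n)], vals)
    counts = rng.integers(0, 20, size=(n, n))
    np.fill_diagonal(counts, 0)
    conn = g.ConnectivityMatrix([f"n{i}" for i in range(n)], counts)
    return sim, conn


class TestMergeFeatures:
    def test_out_mode_shape_and_unit_diagonal(self, rng):
        sim, conn = sim_conn(3, rng)
        m = g.merge_features(sim, conn, mode="out")
        assert m.features.shape == (3, 6)
        np.testing.assert_allclose(np.diag(m.features[:, :3]), 1.0)
        assert m.column_blocks == {"similarity": (0, 3), "conn_out": (3, 6)}

    def test_both_mode_shape(self, rng):
        sim, conn = sim_conn(3, rng)
        assert g.merge_features(sim, conn, mode="both").features.shape == (3, 9)

    def test_in_mode_transposes(self, rng):
        sim, conn = sim_conn(3, rng)
        m = g.merge_features(sim, conn, mode="in")
        np.testing.assert_array_equal(m.features[:, 3:], conn.counts.T)

    def test_order_mismatch_rejected(self, rng):
        sim, conn = sim_conn(3, rng)
        conn2 = g.ConnectivityMatrix(list(reversed(conn.neuron_ids)), conn.counts)
        with pytest.raises(ValueError, match="mismatch"):
            g.merge_features(sim, conn2)

    def test_permutation_consistency(self, rng):
        sim, conn = sim_conn(5, rng)
        perm = rng.permutation(5)
        sim_p = g.SimilarityMatrix(
            [sim.neuron_ids[i] for i in perm], sim.values[np.ix_(perm, perm)]
        )
        conn_p = g.ConnectivityMatrix(
            [conn.neuron_ids[i] for i in perm], conn.counts[np.ix_(perm, perm)]
        )
        m = g.merge_features(sim, conn)
        mp = g.merge_features(sim_p, conn_p)
        # row i of the permuted output is row perm[i] of the original with
        # both column blocks permuted the same way
        expected = np.hstack(
            [sim.values[np.ix_(perm, perm)], conn.counts[np.ix_(perm, perm)]]
        )
        np.testing.assert_allclose(mp.features, expected)
        assert mp.neuron_ids == [m.neuron_ids[i] for i in perm]


class TestMinMaxScale:
    def test_global_formula(self):
        m = g.MergedFeatureMatrix(
            ["a", "b"], np.array([[1.0, 3.0], [2.0, 5.0]]), {"x": (0, 2)}
        )
        out = g.minmax_scale(m, scope="global")
        np.testing.assert_allclose(out.features, [[0, 0.5], [0.25, 1.0]])

    def test_constant_column_maps_to_zero(self):
        m = g.MergedFeatureMatrix(
            ["a", "b"], np.array([[7.0, 1.0], [7.0, 3.0]]), {"x": (0, 2)}
        )
        out = g.minmax_scale(m, scope="per_column")
        np.testing.assert_allclose(out.features[:, 0], 0.0)
        np.testing.assert_allclose(out.features[:, 1], [0.0, 1.0])

    def test_per_block_leaves_already_scaled_block_unchanged(self, rng):
        sim, conn = sim_conn(4, rng)
        sim.values[0, 1] = sim.values[1, 0] = 0.0  # ensure block min 0, max 1
        m = g.merge_features(sim, conn)
        out = g.minmax_scale(m, scope="per_block")
        np.testing.assert_allclose(out.features[:, :4], m.features[:, :4])

    @pytest.mark.parametrize("scope", ["global", "per_block", "per_column"])
    def test_output_always_in_unit_interval(self, rng, scope):
        sim, conn = sim_conn(6, rng)
        out = g.minmax_scale(g.merge_features(sim, conn), scope=scope)
        assert out.features.min() >= 0.0 and out.features.max() <= 1.0


class TestWardLinkage:
    def test_two_point_closed_form(self):
        d = g.ward_linkage(features_1d([0.0, 2.0]))
        assert d.joining_costs == pytest.approx([2.0])

    def test_three_point_closed_form(self):
        d = g.ward_linkage(features_1d([0.0, 2.0, 10.0]))
        # {0,2} first (cost 2), then centroid 1 vs 10: (2*1/3)*81 = 54
        assert d.joining_costs == pytest.approx([2.0, 54.0])

    def test_matches_naive_oracle_on_random_instances(self, rng):
        for _ in range(60):
            n = int(rng.integers(2, 9))
            x = rng.normal(size=(n, int(rng.integers(1, 4))))
            ids = [f"n{i}" for i in range(n)]
            m = g.MergedFeatureMatrix(ids, x, {"x": (0, x.shape[1])})
            dend = g.ward_linkage(m)
            merges, partitions = naive_ward(x)
            np.testing.assert_allclose(
                dend.joining_costs, [c for *_, c, _ in merges], rtol=1e-9
            )
            for k in range(1, n + 1):
                cut_sets = {
                    frozenset(np.flatnonzero(g.cut(dend, k).labels == lab))
                    for lab in range(1, k + 1)
                }
                assert cut_sets == partitions[k]

    def test_costs_nondecreasing(self, rng):
        x = rng.normal(size=(20, 3))
        d = g.ward_linkage(
            g.MergedFeatureMatrix([f"n{i}" for i in range(20)], x, {"x": (0, 3)})
        )
        assert (np.diff(d.joining_costs) >= -1e-12).all()

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            g.MergedFeatureMatrix(["a", "b"], np.array([[np.nan], [1.0]]), {"x": (0, 1)})


class TestJoiningCostProfile:
    def test_three_point_profile(self):
        d = g.ward_linkage(features_1d([0.0, 2.0, 10.0]))
        assert g.joining_cost_profile(d) == [(1, pytest.approx(54.0)),
                                             (2, pytest.approx(2.0))]

    def test_length_and_monotone(self, rng):
        x = rng.normal(size=(15, 2))
        d = g.ward_linkage(
            g.MergedFeatureMatrix([f"n{i}" for i in range(15)], x, {"x": (0, 2)})
        )
        prof = g.joining_cost_profile(d)
        assert len(prof) == 14
        J = [j for _, j in prof]
        assert all(a >= b - 1e-12 for a, b in zip(J, J[1:]))


class TestSelectK:
    def test_single_dominant_drop(self):
        prof = list(zip([1, 2, 3, 4], [100.0, 10.0, 8.0, 7.0]))
        assert g.select_k(prof, k_max=4) == 2
        assert g.select_k(prof, k_max=4, criterion="absolute") == 2

    def test_absolute_tie_goes_to_smallest_k(self):
        # equal maximal drops of 40 at k=3 and k=5
        prof = list(zip(range(1, 7), [100.0, 90.0, 50.0, 45.0, 5.0, 4.0]))
        assert g.select_k(prof, k_max=6, criterion="absolute") == 3

    def test_relative_tie_goes_to_smallest_k(self):
        # D/J = 2 at both k=2 (6/3) and k=3 (2/1); k=4 far lower
        prof = list(zip([1, 2, 3, 4], [9.0, 3.0, 1.0, 0.9]))
        assert g.select_k(prof, k_max=4, criterion="relative") == 2

    def test_k_max_clipped_with_warning(self):
        prof = list(zip([1, 2, 3], [50.0, 4.0, 3.0]))
        with pytest.warns(UserWarning, match="clipping"):
            assert g.select_k(prof, k_max=99) == 2

    def test_planted_three_clusters_recovered(self):
        xs = [0.0, 0.1, 0.2, 5.0, 5.1, 5.2, 11.0, 11.1, 11.3]
        d = g.ward_linkage(features_1d(xs))
        assert g.select_k(g.joining_cost_profile(d)) == 3


class TestCut:
    def test_extremes(self, rng):
        x = rng.normal(size=(6, 2))
        d = g.ward_linkage(
            g.MergedFeatureMatrix([f"n{i}" for i in range(6)], x, {"x": (0, 2)})
        )
        assert g.cut(d, 6).k == 6 and len(set(g.cut(d, 6).labels)) == 6
        assert set(g.cut(d, 1).labels) == {1}

    def test_three_point_two_groups(self):
        d = g.ward_linkage(features_1d([0.0, 2.0, 10.0]))
        a = g.cut(d, 2)
        assert a.labels[0] == a.labels[1] != a.labels[2]

    def test_groups_numbered_by_leaf_order(self, rng):
        x = rng.normal(size=(10, 2)) + np.repeat([[0, 0], [20, 0]], 5, axis=0)
        d = g.ward_linkage(
            g.MergedFeatureMatrix([f"n{i}" for i in range(10)], x, {"x": (0, 2)})
        )
        a = g.cut(d, 2)
        first_leaf = d.leaf_order()[0]
        assert a.labels[first_leaf] == 1

    def test_permutation_equivariance_of_partitions(self, rng):
        x = rng.normal(size=(9, 3))
        ids = [f"n{i}" for i in range(9)]
        perm = rng.permutation(9)
        d1 = g.ward_linkage(g.MergedFeatureMatrix(ids, x, {"x": (0, 3)}))
        d2 = g.ward_linkage(
            g.MergedFeatureMatrix([ids[i] for i in perm], x[perm], {"x": (0, 3)})
        )
        for k in (2, 3, 5):
            p1 = {
                frozenset(
                    np.asarray(ids)[np.asarray(g.cut(d1, k).labels) == lab].tolist()
                )
                for lab in range(1, k + 1)
            }
            p2 = {
                frozenset(
                    np.asarray([ids[i] for i in perm])[
                        np.asarray(g.cut(d2, k).labels) == lab
                    ].tolist()
                )
                for lab in range(1, k + 1)
            }
            assert p1 == p2


class TestExports:
    def test_newick_parses_and_names_leaves(self, rng):
        import dendropy

        x = rng.normal(size=(7, 2))
        ids = [f"neuron{i}" for i in range(7)]
        d = g.ward_linkage(g.MergedFeatureMatrix(ids, x, {"x": (0, 2)}))
        tree = dendropy.Tree.get(data=d.to_newick(), schema="newick")
        assert sorted(t.label for t in tree.taxon_namespace) == sorted(ids)

    def test_merge_table_shape(self, rng):
        x = rng.normal(size=(5, 2))
        d = g.ward_linkage(
            g.MergedFeatureMatrix([f"n{i}" for i in range(5)], x, {"x": (0, 2)})
        )
        t = d.to_merge_table()
        assert list(t.columns) == ["cluster_a", "cluster_b", "joining_cost", "new_size"]
        assert len(t) == 4
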