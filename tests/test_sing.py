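import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from singnet import (
    ExpressionMatrix,
    GeneSetCollection,
    ValidationError,
    annotation_distance_matrix,
    build_sample_profile,
    degree_vector,
    sing_transform,
    threshold_top_edges,
)

from _oracle import (
    oracle_adjacency,
    oracle_degrees,
    oracle_sing,
    oracle_symmetric_difference_sq,
)
from conftest import random_instance


class TestBuildSampleProfile:
    def test_membership_mask_fill_rule(self, tiny_sets):
        column = pd.Series([1.0, 2.0, 3.0], index=["g1", "g2", "g3"], name="s1")
        profile = build_sample_profile(column, tiny_sets)
        frame = profile.to_frame()
        assert frame["A"].tolist() == [1.0, 2.0, 0.0]
        assert frame["B"].tolist() == [0.0, 2.0, 3.0]

    def test_disjoint_set_gives_zero_column(self):
        sets = GeneSetCollection(
            set_names=("A", "NONE"),
            members={"A": ("g1",), "NONE": ("x1", "x2")},
        )
        column = pd.Series([5.0, 7.0], index=["g1", "g2"], name="s")
        profile = build_sample_profile(column, sets)
        assert profile.to_frame()["NONE"].tolist() == [0.0, 0.0]

    def test_zero_expression_gives_zero_profile(self, tiny_sets):
        column = pd.Series([0.0, 0.0, 0.0], index=["g1", "g2", "g3"], name="s")
        assert not build_sample_profile(column, tiny_sets).values.any()

    def test_fully_disjoint_universe_is_an_error(self):
        sets = GeneSetCollection(set_names=("A",), members={"A": ("x1",)})
        column = pd.Series([1.0], index=["g1"], name="s")
        with pytest.raises(ValidationError, match="disjoint"):
            build_sample_profile(column, sets)


class TestAnnotationDistance:
    def test_hand_computed_distance(self, tiny_sets):
        # columns A=(1,2,0), B=(0,2,3): distance = sqrt(1 + 0 + 9) = sqrt(10)
        column = pd.Series([1.0, 2.0, 3.0], index=["g1", "g2", "g3"], name="s1")
        d = annotation_distance_matrix(build_sample_profile(column, tiny_sets))
        assert d[0, 1] == pytest.approx(np.sqrt(10.0), abs=1e-12)
        assert d[0, 0] == 0.0 and d[1, 0] == d[0, 1]

    def test_identical_member_sets_have_zero_distance(self):
        sets = GeneSetCollection(
            set_names=("A", "B"), members={"A": ("g1", "g2"), "B": ("g1", "g2")}
        )
        column = pd.Series([3.0, 4.0], index=["g1", "g2"], name="s")
        d = annotation_distance_matrix(build_sample_profile(column, sets))
        assert d[0, 1] == 0.0

    def test_squared_distance_is_symmetric_difference_energy(self, rng):
        """d^2(q, q*) = sum of e_p^2 over genes in exactly one of the sets."""
        for _ in range(30):
            expr, sets = random_instance(rng, n_samples=1)
            column = expr.sample_column(expr.sample_ids[0])
            profile = build_sample_profile(column, sets)
            d = annotation_distance_matrix(profile)
            names = sets.set_names
            for a in range(len(names)):
                for b in range(a + 1, len(names)):
                    expected = oracle_symmetric_difference_sq(
                        column.to_numpy(),
                        expr.gene_ids,
                        set(sets.members[names[a]]),
                        set(sets.members[names[b]]),
                    )
                    assert d[a, b] ** 2 == pytest.approx(expected, abs=1e-10)

    def test_single_annotation_rejected(self):
        sets = GeneSetCollection(set_names=("A",), members={"A": ("g1",)})
        column = pd.Series([1.0], index=["g1"], name="s")
        with pytest.raises(ValidationError, match="at least 2"):
            annotation_distance_matrix(build_sample_profile(column, sets))


class TestThresholdTopEdges:
    def test_q5_fraction_010_keeps_exactly_one_edge(self, rng):
        d = np.abs(rng.normal(size=(5, 5)))
        d = d + d.T
        np.fill_diagonal(d, 0.0)
        adjacency = threshold_top_edges(d, 0.10)
        assert np.triu(adjacency, 1).sum() == 1  # floor(0.1 * 10) = 1

    def test_fraction_one_gives_complete_graph(self, rng):
        d = np.abs(rng.normal(size=(6, 6)))
        d = d + d.T
        np.fill_diagonal(d, 0.0)
        adjacency = threshold_top_edges(d, 1.0)
        assert np.array_equal(adjacency, 1 - np.eye(6, dtype=int))

    def test_all_equal_distances_tie_break_by_node_index(self):
        d = np.ones((4, 4)) - np.eye(4)
        adjacency = threshold_top_edges(d, 0.5)  # k = floor(0.5 * 6) = 3
        expected_edges = {(0, 1), (0, 2), (0, 3)}
        edges = {tuple(e) for e in np.argwhere(np.triu(adjacency, 1))}
        assert edges == expected_edges

    def test_smallest_distance_rule_inverts_selection(self):
        d = np.array(
            [[0.0, 1.0, 9.0], [1.0, 0.0, 5.0], [9.0, 5.0, 0.0]]
        )
        largest = threshold_top_edges(d, 0.34, rule="largest_distance")
        smallest = threshold_top_edges(d, 0.34, rule="smallest_distance")
        assert largest[0, 2] == 1 and largest[0, 1] == 0
        assert smallest[0, 1] == 1 and smallest[0, 2] == 0

    @given(st.integers(0, 2**32 - 1), st.floats(0.05, 1.0))
    @settings(max_examples=30, deadline=None)
    def test_matches_brute_force_selection(self, seed, fraction):
        rng = np.random.default_rng(seed)
        q = int(rng.integers(3, 9))
        d = np.abs(rng.normal(size=(q, q)))
        d = d + d.T
        np.fill_diagonal(d, 0.0)
        adjacency = threshold_top_edges(d, fraction)
        assert adjacency.tolist() == oracle_adjacency(d.tolist(), fraction)

    def test_invalid_fraction_rejected(self):
        d = np.zeros((3, 3))
        for fraction in (0.0, -0.1, 1.5):
            with pytest.raises(ValidationError):
                threshold_top_edges(d, fraction)


class TestDegreeVector:
    def test_complete_graph_degrees(self):
        adjacency = (1 - np.eye(4)).astype(int)
        assert degree_vector(adjacency).tolist() == [3, 3, 3, 3]

    def test_empty_graph_degrees(self):
        assert degree_vector(np.zeros((5, 5), dtype=int)).tolist() == [0] * 5

    def test_matches_neighbour_enumeration(self, rng):
        upper = np.triu(rng.integers(0, 2, size=(8, 8)), 1)
        adjacency = upper + upper.T
        assert degree_vector(adjacency).tolist() == oracle_degrees(
            adjacency.tolist()
        )

    def test_asymmetric_input_rejected(self):
        bad = np.zeros((3, 3), dtype=int)
        bad[0, 1] = 1
        with pytest.raises(ValidationError, match="symmetric"):
            degree_vector(bad)


class TestSingTransform:
    def test_identical_samples_give_identical_rows(self, rng):
        column = rng.lognormal(size=12)
        expr = ExpressionMatrix(
            gene_ids=tuple(f"g{i}" for i in range(12)),
            sample_ids=("s1", "s2", "s3"),
            values=np.column_stack([column] * 3),
        )
        _, sets = random_instance(rng, n_genes=12, n_sets=5)
        sets = GeneSetCollection(
            set_names=sets.set_names, members=sets.members
        )
        features = sing_transform(expr, sets, n_top_genes=12)
        assert np.array_equal(features.degrees[0], features.degrees[1])
        assert np.array_equal(features.degrees[0], features.degrees[2])

    @pytest.mark.parametrize("scale", [0.1, 3.0, 100.0])
    def test_per_sample_scale_invariance(self, rng, scale):
        expr, sets = random_instance(rng, n_genes=15, n_sets=6)
        features = sing_transform(expr, sets, n_top_genes=15)
        values = expr.values.copy()
        values[:, 2] *= scale
        scaled = ExpressionMatrix(
            gene_ids=expr.gene_ids, sample_ids=expr.sample_ids, values=values
        )
        rescaled = sing_transform(scaled, sets, n_top_genes=15)
        assert np.array_equal(features.degrees[2], rescaled.degrees[2])

    def test_matches_end_to_end_oracle(self, rng):
        for _ in range(5):
            expr, sets = random_instance(rng, n_genes=20, n_sets=6)
            features, networks = sing_transform(
                expr, sets, n_top_genes=10, return_networks=True
            )
            degree_rows, distance_mats = oracle_sing(
                expr.values.tolist(),
                list(expr.gene_ids),
                list(sets.set_names),
                {k: set(v) for k, v in sets.members.items()},
                n_top=10,
                fraction=0.10,
            )
            assert features.degrees.tolist() == degree_rows
            for network, expected in zip(networks, distance_mats):
                assert np.allclose(
                    network.distances, np.array(expected), atol=1e-12
                )

    def test_degree_rows_sum_to_twice_edge_count(self, rng):
        expr, sets = random_instance(rng, n_genes=18, n_sets=7)
        features, networks = sing_transform(
            expr, sets, n_top_genes=18, return_networks=True
        )
        for row, network in zip(features.degrees, networks):
            assert row.sum() == 2 * network.n_edges

    def test_annotation_permutation_equivariance(self, rng):
        expr, sets = random_instance(rng, n_genes=15, n_sets=6)
        features = sing_transform(expr, sets, n_top_genes=15)
        perm = rng.permutation(len(sets))
        permuted_sets = GeneSetCollection(
            set_names=tuple(sets.set_names[i] for i in perm),
            members=sets.members,
        )
        permuted = sing_transform(expr, permuted_sets, n_top_genes=15)
        assert np.array_equal(permuted.degrees, features.degrees[:, perm])

    def test_sample_permutation_equivariance(self, rng):
        expr, sets = random_instance(rng, n_genes=15, n_sets=6)
        features = sing_transform(expr, sets, n_top_genes=15)
        perm = rng.permutation(expr.n_samples)
        shuffled = ExpressionMatrix(
            gene_ids=expr.gene_ids,
            sample_ids=tuple(expr.sample_ids[j] for j in perm),
            values=expr.values[:, perm],
        )
        permuted = sing_transform(shuffled, sets, n_top_genes=15)
        assert np.array_equal(permuted.degrees, features.degrees[perm])

    def test_edge_list_export_is_consistent(self, rng):
        expr, sets = random_instance(rng, n_genes=15, n_sets=6)
        _, networks = sing_transform(
            expr, sets, n_top_genes=15, return_networks=True
        )
        network = networks[0]
        edges = network.edge_list()
        assert len(edges) == network.n_edges
        for _, row in edges.iterrows():
            a = network.set_names.index(row.node_a)
            b = network.set_names.index(row.node_b)
            assert network.adjacency[a, b] == 1
            assert row.distance == network.distances[a, b]
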