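import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fanp import datasets
from fanp.network import (
    ANPNetwork,
    Cluster,
    ClusterMatrix,
    Dependency,
    Supermatrix,
    assemble_supermatrix,
    default_cluster_matrix,
    limit_supermatrix,
    synthesize_priorities,
    weight_supermatrix,
)
from fanp.priority import PriorityVector


def pv(labels, weights):
    return PriorityVector.from_certain(labels, np.asarray(weights, dtype=float))


@pytest.fixture
def hierarchy_network():
    return ANPNetwork(
        [Cluster("Criteria", ("c1", "c2", "c3"))],
        [Dependency("goal", "Criteria")],
        goal="goal",
    )


class TestNetworkModel:
    def test_duplicate_elements_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            ANPNetwork(
                [Cluster("A", ("x",)), Cluster("B", ("x",))],
                [],
            )

    def test_unknown_dependency_target_rejected(self):
        with pytest.raises(ValueError, match="unknown cluster"):
            ANPNetwork([Cluster("A", ("x",))], [Dependency("x", "B")])

    def test_cluster_source_expands_to_elements(self):
        net = ANPNetwork(
            [Cluster("A", ("a1", "a2")), Cluster("B", ("b1",))],
            [Dependency("A", "B")],
        )
        assert net.edges_by_source_element() == [("a1", "B"), ("a2", "B")]

    def test_bundled_network_matches_taxonomy(self):
        net = datasets.allocation_network()
        assert [c.name for c in net.clusters] == [
            "Efficiency",
            "Equity and Access",
            "Effectiveness",
        ]
        assert sum(len(c.elements) for c in net.clusters) == 8
        assert net.goal == "Scarce drug allocation"


class TestAssemble:
    def test_pure_hierarchy_single_block(self, hierarchy_network):
        vec = pv(["c1", "c2", "c3"], [0.6, 0.3, 0.1])
        sm = assemble_supermatrix(hierarchy_network, {("goal", "Criteria"): vec})
        m = sm.matrix
        assert sm.labels == ["goal", "c1", "c2", "c3"]
        assert m[1:, 0] == pytest.approx([0.6, 0.3, 0.1])
        assert np.all(m[:, 1:] == 0) and m[0, 0] == 0

    def test_mutual_single_element_clusters(self):
        net = ANPNetwork(
            [Cluster("A", ("a",)), Cluster("B", ("b",))],
            [Dependency("a", "B"), Dependency("b", "A")],
        )
        sm = assemble_supermatrix(
            net,
            {("a", "B"): pv(["b"], [1.0]), ("b", "A"): pv(["a"], [1.0])},
        )
        assert sm.matrix == pytest.approx(np.array([[0, 1], [1, 0]]))

    def test_missing_vector_names_edge(self, hierarchy_network):
        with pytest.raises(KeyError, match="goal.*Criteria"):
            assemble_supermatrix(hierarchy_network, {})

    def test_label_mismatch_names_cluster(self, hierarchy_network):
        bad = pv(["c1", "c2", "zz"], [0.5, 0.3, 0.2])
        with pytest.raises(ValueError, match="Criteria"):
            assemble_supermatrix(hierarchy_network, {("goal", "Criteria"): bad})

    def test_bundled_network_zero_blocks_match_edges(self):
        net = datasets.allocation_network()
        vectors = {}
        for source, target in net.edges_by_source_element():
            els = list(net.cluster_elements(target))
            vectors[(source, target)] = pv(els, np.ones(len(els)) / len(els))
        sm = assemble_supermatrix(net, vectors)
        order = sm.labels
        influenced = set(net.edges_by_source_element())
        for j, src in enumerate(order):
            for cname in net.cluster_order:
                rows = [order.index(e) for e in net.cluster_elements(cname)]
                block = sm.matrix[rows, j]
                if (src, cname) in influenced:
                    assert block.sum() > 0
                else:
                    assert np.all(block == 0)


class TestWeighting:
    def test_single_cluster_unchanged(self):
        net = ANPNetwork(
            [Cluster("A", ("a1", "a2"))],
            [Dependency("A", "A", kind="inner")],
        )
        vecs = {
            ("a1", "A"): pv(["a1", "a2"], [0.5, 0.5]),
            ("a2", "A"): pv(["a1", "a2"], [0.7, 0.3]),
        }
        sm = assemble_supermatrix(net, vecs)
        weighted = weight_supermatrix(sm, default_cluster_matrix(net))
        assert weighted.matrix == pytest.approx(sm.matrix)

    def test_two_equal_clusters_columns_sum_to_one(self):
        net = ANPNetwork(
            [Cluster("A", ("a",)), Cluster("B", ("b",))],
            [
                Dependency("a", "A", kind="inner"),
                Dependency("a", "B"),
                Dependency("b", "A"),
                Dependency("b", "B", kind="inner"),
            ],
        )
        vecs = {
            ("a", "A"): pv(["a"], [1.0]),
            ("a", "B"): pv(["b"], [1.0]),
            ("b", "A"): pv(["a"], [1.0]),
            ("b", "B"): pv(["b"], [1.0]),
        }
        weighted = weight_supermatrix(
            assemble_supermatrix(net, vecs), default_cluster_matrix(net)
        )
        assert weighted.matrix.sum(axis=0) == pytest.approx([1.0, 1.0])

    def test_hierarchy_goal_column_already_stochastic(self, hierarchy_network):
        vec = pv(["c1", "c2", "c3"], [0.6, 0.3, 0.1])
        sm = assemble_supermatrix(hierarchy_network, {("goal", "Criteria"): vec})
        weighted = weight_supermatrix(sm, default_cluster_matrix(hierarchy_network))
        assert weighted.matrix == pytest.approx(sm.matrix)
        assert weighted.is_column_stochastic()

    def test_sink_policy_uniform_fills_zero_columns(self, hierarchy_network):
        vec = pv(["c1", "c2", "c3"], [0.6, 0.3, 0.1])
        sm = assemble_supermatrix(hierarchy_network, {("goal", "Criteria"): vec})
        weighted = weight_supermatrix(
            sm, default_cluster_matrix(hierarchy_network), sink_policy="uniform"
        )
        assert np.all(weighted.matrix.sum(axis=0) == pytest.approx(1.0))

    def test_cluster_matrix_columns_must_be_stochastic(self):
        with pytest.raises(ValueError, match="sum to 1"):
            ClusterMatrix(["A", "B"], np.array([[0.5, 0.0], [0.2, 0.0]]))


def weighted_sm(matrix, labels=None):
    matrix = np.asarray(matrix, dtype=float)
    labels = labels or [f"e{i}" for i in range(matrix.shape[0])]
    return Supermatrix(labels, matrix, "weighted")


class TestLimit:
    def test_two_state_chain_stationary_vector(self):
        lim = limit_supermatrix(weighted_sm([[0.9, 0.2], [0.1, 0.8]]))
        for j in range(2):
            assert lim.matrix[:, j] == pytest.approx([2 / 3, 1 / 3], abs=1e-9)

    def test_idempotent_matrix_unchanged(self):
        a = [[0.5, 0.5], [0.5, 0.5]]
        lim = limit_supermatrix(weighted_sm(a))
        assert lim.matrix == pytest.approx(np.array(a))

    def test_periodic_chain_cesaro_average(self):
        lim = limit_supermatrix(weighted_sm([[0.0, 1.0], [1.0, 0.0]]))
        assert lim.matrix == pytest.approx(np.full((2, 2), 0.5), abs=1e-9)

    def test_non_stochastic_input_rejected(self):
        with pytest.raises(ValueError, match="stochastic"):
            limit_supermatrix(weighted_sm([[0.5, 0.2], [0.2, 0.2]]))

    def test_requires_weighted_stage(self):
        sm = Supermatrix(["a"], np.array([[1.0]]), "unweighted")
        with pytest.raises(ValueError, match="weighted"):
            limit_supermatrix(sm)

    @settings(max_examples=60, deadline=None)
    @given(st.integers(0, 100_000), st.integers(2, 6))
    def test_limit_matches_dense_eigensolve_on_primitive_chains(self, seed, n):
        # independent Markov oracle: the limit column of a primitive
        # column-stochastic matrix is its dominant eigenvector
        rng = np.random.default_rng(seed)
        a = rng.uniform(0.05, 1.0, size=(n, n))
        a /= a.sum(axis=0)
        lim = limit_supermatrix(weighted_sm(a), tol=1e-14)
        vals, vecs = np.linalg.eig(a)
        k = int(np.argmax(vals.real))
        stat = np.abs(vecs[:, k].real)
        stat /= stat.sum()
        for j in range(n):
            assert np.max(np.abs(lim.matrix[:, j] - stat)) < 1e-8

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 100_000), st.integers(2, 5))
    def test_conservation_under_squaring(self, seed, n):
        # column sums stay 1 at every squaring step of a stochastic matrix
        rng = np.random.default_rng(seed)
        a = rng.uniform(0.05, 1.0, size=(n, n))
        a /= a.sum(axis=0)
        b = a.copy()
        for _ in range(8):
            b = b @ b
            assert b.sum(axis=0) == pytest.approx(np.ones(n), abs=1e-9)
        lim = limit_supermatrix(weighted_sm(a))
        assert lim.is_column_stochastic(tol=1e-8)


class TestSynthesis:
    def test_arithmetic_rollup(self):
        net = ANPNetwork(
            [Cluster("A", ("e1", "e2")), Cluster("B", ("e3", "e4"))],
            [Dependency("A", "B"), Dependency("B", "A")],
        )
        col = np.array([0.1, 0.2, 0.3, 0.4])
        lim = Supermatrix(
            ["e1", "e2", "e3", "e4"], np.tile(col[:, None], (1, 4)), "limit"
        )
        res = synthesize_priorities(lim, net)
        assert res.cluster_priorities == pytest.approx([0.3, 0.7])
        assert res.within_cluster["A"]["e1"] == pytest.approx(1 / 3)
        assert res.within_cluster["A"]["e2"] == pytest.approx(2 / 3)
        assert res.cluster_ranks == [2, 1]
        assert res.element_ranks == [4, 3, 2, 1]

    def test_pure_hierarchy_reproduces_criteria_vector(self, hierarchy_network):
        vec = pv(["c1", "c2", "c3"], [0.6, 0.3, 0.1])
        sm = assemble_supermatrix(hierarchy_network, {("goal", "Criteria"): vec})
        weighted = weight_supermatrix(sm, default_cluster_matrix(hierarchy_network))
        lim = limit_supermatrix(weighted)
        res = synthesize_priorities(lim, hierarchy_network)
        assert res.overall == pytest.approx([0.6, 0.3, 0.1], abs=1e-12)

    def test_two_level_hierarchy_top_down_products(self):
        net = ANPNetwork(
            [Cluster("Criteria", ("c1", "c2")), Cluster("Options", ("o1", "o2"))],
            [
                Dependency("goal", "Criteria"),
                Dependency("c1", "Options"),
                Dependency("c2", "Options"),
            ],
            goal="goal",
        )
        vecs = {
            ("goal", "Criteria"): pv(["c1", "c2"], [0.7, 0.3]),
            ("c1", "Options"): pv(["o1", "o2"], [0.9, 0.1]),
            ("c2", "Options"): pv(["o1", "o2"], [0.2, 0.8]),
        }
        sm = assemble_supermatrix(net, vecs)
        weighted = weight_supermatrix(sm, default_cluster_matrix(net))
        res = synthesize_priorities(limit_supermatrix(weighted), net)
        expected_options = np.array([0.7 * 0.9 + 0.3 * 0.2, 0.7 * 0.1 + 0.3 * 0.8])
        got = {e: w for e, w in zip(res.element_labels, res.overall)}
        opts = np.array([got["o1"], got["o2"]])
        assert opts / opts.sum() == pytest.approx(expected_options, abs=1e-9)

    def test_permutation_equivariance(self):
        w = np.array([0.5, 0.3, 0.2])
        for order in ([0, 1, 2], [2, 0, 1]):
            labels = [f"c{i}" for i in order]
            net = ANPNetwork(
                [Cluster("Criteria", tuple(labels))],
                [Dependency("goal", "Criteria")],
                goal="goal",
            )
            vec = pv(labels, w[order])
            sm = assemble_supermatrix(net, {("goal", "Criteria"): vec})
            weighted = weight_supermatrix(sm, default_cluster_matrix(net))
            res = synthesize_priorities(limit_supermatrix(weighted), net)
            got = dict(zip(res.element_labels, res.overall))
            for idx, lbl in zip(order, labels):
                assert got[lbl] == pytest.approx(w[idx], abs=1e-12)

    def test_zero_limit_mass_is_degeneracy_error(self):
        net = ANPNetwork(
            [Cluster("A", ("a", "b"))], [Dependency("A", "A", kind="inner")]
        )
        lim = Supermatrix(["a", "b"], np.zeros((2, 2)), "limit")
        with pytest.raises(ValueError, match="zero"):
            synthesize_priorities(lim, net)
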