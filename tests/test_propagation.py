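"""Propagation scoring: Laplacian normalization, the RWR iteration, and
fixed-point equivalence against a dense linear-solve oracle."""

import numpy as np
import pytest
from scipy import sparse

from conftest import make_drugs, make_network, oracle_fixed_point, random_case
from panacea.errors import NoEdgesError, NoPriorSignalError
from panacea.fixtures import FixtureSpec, generate_fixture
from panacea.network_io import DrugTargetMap, extend_network, merge_equivalent_drugs
from panacea.propagation import (
    NormalizedAdjacency,
    alpha_sweep,
    build_prior,
    laplacian_normalize,
    node_order,
    propagate,
    propagation_fixed_point,
    score_propagation,
)


def two_node_adjacency():
    return NormalizedAdjacency(
        nodes=["A", "B"],
        matrix=sparse.csr_array(np.array([[0.0, 1.0], [1.0, 0.0]])),
    )


class TestLaplacianNormalize:
    def test_single_edge(self):
        net = make_network([("A", "B")])
        xnet = extend_network(net, make_drugs({}))
        wn = laplacian_normalize(xnet)
        dense = wn.matrix.toarray()
        assert dense == pytest.approx(np.array([[0, 1], [1, 0]]))

    def test_path_graph_values(self):
        net = make_network([("A", "B"), ("B", "C")])
        xnet = extend_network(net, make_drugs({}))
        dense = laplacian_normalize(xnet).matrix.toarray()
        r = 1 / np.sqrt(2)
        assert dense[0, 1] == pytest.approx(r)
        assert dense[1, 2] == pytest.approx(r)
        assert dense[0, 2] == 0.0
        assert dense == pytest.approx(dense.T)

    @pytest.mark.parametrize("k", [1, 2, 3, 4, 5])
    def test_star_closed_form_matches_dense_product(self, k):
        edges = [("HUB", f"L{i}") for i in range(k)]
        xnet = extend_network(make_network(edges), make_drugs({}))
        wn = laplacian_normalize(xnet)
        dense = wn.matrix.toarray()
        # closed form: every edge entry is 1/sqrt(k)
        for i, node in enumerate(wn.nodes):
            for j in range(i + 1, len(wn.nodes)):
                expected = 1 / np.sqrt(k) if "HUB" in (node, wn.nodes[j]) else 0
                assert dense[i, j] == pytest.approx(expected)
        # independent dense oracle: D^(-1/2) W D^(-1/2)
        w = (dense > 0).astype(float)
        d = np.diag(1 / np.sqrt(w.sum(axis=1)))
        assert dense == pytest.approx(d @ w @ d)

    def test_node_order_sorted_genes_then_drugs(self):
        net = make_network([("B", "A")])
        xnet = extend_network(net, make_drugs({"ZDRUG": {"A"}, "ADRUG": {"B"}}))
        assert laplacian_normalize(xnet).nodes == [
            "A", "B", "drug::ADRUG", "drug::ZDRUG"]

    def test_edgeless_network_raises(self):
        net = make_network([])
        net.graph.add_node("A")
        xnet = extend_network(net, make_drugs({}))
        with pytest.raises(NoEdgesError):
            laplacian_normalize(xnet)

    def test_isolated_node_zero_row(self):
        net = make_network([("A", "B")])
        net.graph.add_node("LONER")
        xnet = extend_network(net, make_drugs({}))
        wn = laplacian_normalize(xnet)
        i = wn.nodes.index("LONER")
        assert wn.matrix.toarray()[i].sum() == 0.0


class TestBuildPrior:
    def test_direct_mapping(self):
        net = make_network([("A", "B")])
        xnet = extend_network(net, make_drugs({"D": {"B"}}))
        y = build_prior(xnet, {"A": 0.9})
        assert dict(zip(node_order(xnet), y)) == {
            "A": 0.9, "B": 0.0, "drug::D": 0.0}

    def test_absent_genes_only_raises(self):
        net = make_network([("A", "B")])
        xnet = extend_network(net, make_drugs({}))
        with pytest.raises(NoPriorSignalError):
            build_prior(xnet, {"Z": 0.9})

    def test_no_threshold_by_default(self):
        net = make_network([("A", "B")])
        xnet = extend_network(net, make_drugs({}))
        y = build_prior(xnet, {"A": 0.01})  # below the distance-method cut
        assert y.max() == pytest.approx(0.01)


class TestPropagate:
    def test_alpha_one_is_restart_only(self):
        wn = two_node_adjacency()
        res = propagate(wn, np.array([1.0, 0.0]), alpha=1.0)
        assert res.iterations == 1 and res.converged
        assert res.f == pytest.approx([1.0, 0.0])

    def test_two_node_fixed_point(self):
        wn = two_node_adjacency()
        y = np.array([1.0, 0.0])
        res = propagate(wn, y, alpha=0.05, tol=1e-10)
        # closed form: (1/0.0975) * 0.05 * (1, 0.95)
        assert res.f == pytest.approx([0.05 / 0.0975, 0.0475 / 0.0975],
                                      abs=1e-6)
        assert res.f == pytest.approx([0.512820, 0.487179], abs=1e-6)
        fp = propagation_fixed_point(wn, y, alpha=0.05)
        assert fp == pytest.approx(res.f, abs=1e-8)

    def test_linearity_in_prior(self):
        wn = two_node_adjacency()
        y = np.array([0.3, 0.7])
        f1 = propagation_fixed_point(wn, y, 0.05)
        f2 = propagation_fixed_point(wn, 2.5 * y, 0.05)
        assert f2 == pytest.approx(2.5 * f1)

    @pytest.mark.parametrize("alpha", [0.0, -0.1, 1.5])
    def test_bad_alpha_rejected(self, alpha):
        with pytest.raises(ValueError):
            propagate(two_node_adjacency(), np.array([1.0, 0.0]), alpha=alpha)

    def test_iteration_cap_flags_not_raises(self):
        wn = two_node_adjacency()
        res = propagate(wn, np.array([1.0, 0.0]), alpha=0.05, tol=1e-12,
                        max_iter=3)
        assert not res.converged and res.iterations == 3

    def test_geometric_error_decay(self):
        """The iterate's distance to the fixed point shrinks by at least
        (1 - alpha) per step."""
        wn = two_node_adjacency()
        y = np.array([1.0, 0.0])
        alpha = 0.05
        fstar = propagation_fixed_point(wn, y, alpha)
        f = y.copy()
        prev_err = np.linalg.norm(f - fstar)
        for _ in range(50):
            f = (1 - alpha) * (wn.matrix @ f) + alpha * y
            err = np.linalg.norm(f - fstar)
            assert err <= (1 - alpha) * prev_err + 1e-15
            prev_err = err


class TestFixedPointEquivalence:
    @pytest.mark.parametrize("seed", range(8))
    def test_iterative_matches_dense_solve(self, seed):
        spec = FixtureSpec(n_genes=60 + 10 * seed, n_drugs=10, n_altered=8,
                           seed=seed)
        net, drugs, drivers = generate_fixture(spec)
        xnet = extend_network(net, merge_equivalent_drugs(drugs))
        result = score_propagation(xnet, drivers, alpha=0.05, tol=1e-4)
        assert result.params["converged"]
        assert result.params["iterations"] < 1000
        oracle = oracle_fixed_point(xnet, drivers, alpha=0.05)
        for drug, score in result.scores.items():
            assert score == pytest.approx(
                oracle[xnet.drug_node_name(drug)], abs=10 * 1e-4)

    @pytest.mark.parametrize("seed", range(5))
    def test_monotone_in_prior(self, seed):
        """Raising one prior entry never decreases any fixed-point entry."""
        xnet, drivers = random_case(seed)
        candidates = [g for g in drivers if g in xnet.gene_network.nodes]
        if not candidates:
            pytest.skip("no altered gene in network")
        base = oracle_fixed_point(xnet, drivers, 0.05)
        drivers2 = dict(drivers)
        drivers2[candidates[0]] = min(1.0, drivers2[candidates[0]] + 0.2)
        bumped = oracle_fixed_point(xnet, drivers2, 0.05)
        assert all(bumped[n] >= base[n] - 1e-12 for n in base)


class TestScorePropagation:
    def test_signal_flows_to_connected_drug(self):
        net = make_network([("A", "B")])
        xnet = extend_network(net, make_drugs({"D": {"B"}}))
        result = score_propagation(xnet, {"A": 0.9})
        assert result.scores["D"] > 0

    def test_disconnected_drug_scores_zero(self):
        net = make_network([("A", "B"), ("X", "Y")])
        xnet = extend_network(net, make_drugs({"D": {"X"}, "E": {"A"}}))
        result = score_propagation(xnet, {"A": 0.9})
        assert result.scores["D"] == 0.0
        assert result.scores["E"] > 0

    def test_orphan_drug_scores_exactly_zero(self):
        net = make_network([("A", "B")])
        xnet = extend_network(net, make_drugs({"D": {"A"}, "ORPH": {"Z"}}))
        result = score_propagation(xnet, {"A": 0.9})
        assert result.scores["ORPH"] == 0.0

    def test_relabeling_permutes_scores(self):
        """Graph isomorphism: renaming genes leaves drug scores unchanged."""
        net = make_network([("A", "B"), ("B", "C")])
        xnet = extend_network(net, make_drugs({"D": {"C"}}))
        s1 = score_propagation(xnet, {"A": 0.8}).scores
        renamed = make_network([("Q", "R"), ("R", "S")])
        xnet2 = extend_network(renamed, make_drugs({"D": {"S"}}))
        s2 = score_propagation(xnet2, {"Q": 0.8}).scores
        assert s1["D"] == pytest.approx(s2["D"], abs=1e-12)

    def test_alpha_sweep_shapes(self):
        net = make_network([("A", "B"), ("B", "C")])
        xnet = extend_network(net, make_drugs({"D": {"C"}, "E": {"B"}}))
        sweep = alpha_sweep(xnet, {"A": 0.8}, alphas=[0.05, 0.5, 1.0])
        assert set(sweep) == {0.05, 0.5, 1.0}
        # with full restart, no signal ever reaches the drugs
        assert all(v == 0.0 for v in sweep[1.0].scores.values())
        assert sweep[0.05].scores["E"] > sweep[0.5].scores["E"]
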