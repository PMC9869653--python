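"""Shared builders and independent oracles for the test suite.

The oracles deliberately take a different route from the library code:
distances come from networkx Floyd–Warshall all-pairs (or from literal BFS
on a copy of the extended graph with other drug nodes deleted), and the
propagation fixed point comes from a dense numpy solve.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from panacea.network_io import DrugTargetMap, ExtendedNetwork, GeneNetwork


def make_network(edges, confidences=None) -> GeneNetwork:
    """Build a GeneNetwork from an edge list (and optional parallel confidences)."""
    g = nx.Graph()
    if confidences is None:
        g.add_edges_from(edges)
        return GeneNetwork(graph=g)
    for (u, v), c in zip(edges, confidences):
        g.add_edge(u, v, confidence=c)
    return GeneNetwork(graph=g, min_confidence=None, has_confidence=True)


def make_drugs(entries: dict) -> DrugTargetMap:
    return DrugTargetMap({d: frozenset(t) for d, t in entries.items()})


def random_case(seed: int, n_genes=30, n_drugs=6, n_altered=6,
                edge_prob=0.12) -> tuple[ExtendedNetwork, dict[str, float]]:
    """A small random extended network + driverness map for property tests."""
    from panacea.network_io import extend_network, merge_equivalent_drugs

    rng = np.random.default_rng(seed)
    g = nx.gnp_random_graph(n_genes, edge_prob, seed=int(rng.integers(2**31)))
    g = nx.relabel_nodes(g, {i: f"G{i}" for i in range(n_genes)})
    g.add_nodes_from(f"G{i}" for i in range(n_genes))
    net = GeneNetwork(graph=g)
    genes = sorted(net.nodes)
    entries = {}
    for i in range(n_drugs):
        k = int(rng.integers(1, 4))
        entries[f"D{i}"] = frozenset(
            str(x) for x in rng.choice(genes, size=k, replace=False))
    drugs = merge_equivalent_drugs(DrugTargetMap(entries))
    altered = rng.choice(genes, size=min(n_altered, len(genes)), replace=False)
    drivers = {str(g_): float(rng.uniform(0, 1)) for g_ in altered}
    return extend_network(net, drugs), drivers


# ---------------------------------------------------------------- oracles --

def oracle_distance_scores(xnet: ExtendedNetwork, drivers: dict[str, float],
                           threshold: float = 0.05) -> dict[str, float]:
    """Literal mean of driver_g/(dist+1)^2 using Floyd–Warshall all-pairs
    hop distances on the gene-only graph."""
    g = xnet.gene_network.graph
    fw = nx.floyd_warshall(g)  # dict of dicts of (possibly inf) distances
    gene_nodes = set(g.nodes)
    gstar = {a: s for a, s in drivers.items()
             if s > threshold and a in gene_nodes}
    scores = {}
    for drug, targets in xnet.drug_targets.items():
        total = 0.0
        for gene, s in gstar.items():
            best = min(
                (fw[t][gene] for t in targets if fw[t][gene] != np.inf),
                default=None,
            )
            if best is not None:
                total += s / (best + 1 + 1) ** 2  # +1 drug hop, +1 from Eq. 1
        scores[drug] = total / len(gstar) if gstar else 0.0
    return scores


def oracle_distance_scores_deletion(xnet: ExtendedNetwork,
                                    drivers: dict[str, float],
                                    threshold: float = 0.05) -> dict[str, float]:
    """Naive variant: materialize the full extended graph, delete all other
    drug nodes, and run plain single-source shortest paths per drug."""
    full = xnet.full_graph()
    gene_nodes = xnet.gene_network.nodes
    gstar = {a: s for a, s in drivers.items()
             if s > threshold and a in gene_nodes}
    scores = {}
    for drug in xnet.drug_targets:
        node = xnet.drug_node_name(drug)
        sub = full.copy()
        sub.remove_nodes_from(
            xnet.drug_node_name(d) for d in xnet.drug_targets if d != drug)
        dist = nx.single_source_shortest_path_length(sub, node)
        total = sum(s / (dist[a] + 1) ** 2 for a, s in gstar.items()
                    if a in dist)
        scores[drug] = total / len(gstar) if gstar else 0.0
    return scores


def oracle_fixed_point(xnet: ExtendedNetwork, drivers: dict[str, float],
                       alpha: float = 0.05) -> dict[str, float]:
    """Dense closed-form RWR fixed point F* = a (I - (1-a) W')^-1 Y,
    built entirely with numpy from the raw adjacency."""
    from panacea.propagation import node_order

    order = node_order(xnet)
    idx = {n: i for i, n in enumerate(order)}
    n = len(order)
    w = np.zeros((n, n))
    for u, v in xnet.full_graph().edges:
        w[idx[u], idx[v]] = w[idx[v], idx[u]] = 1.0
    deg = w.sum(axis=1)
    inv_sqrt = np.divide(1.0, np.sqrt(deg), out=np.zeros(n), where=deg > 0)
    wn = np.diag(inv_sqrt) @ w @ np.diag(inv_sqrt)
    y = np.zeros(n)
    gene_nodes = xnet.gene_network.nodes
    for g_, s in drivers.items():
        if g_ in gene_nodes:
            y[idx[g_]] = s
    f = alpha * np.linalg.solve(np.eye(n) - (1 - alpha) * wn, y)
    return {n_: float(v) for n_, v in zip(order, f)}


@pytest.fixture
def path_xnet():
    """Path A–B–C with one drug D targeting A (the worked toy)."""
    from panacea.network_io import extend_network

    net = make_network([("A", "B"), ("B", "C")])
    return extend_network(net, make_drugs({"D": {"A"}}))
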