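"""Seeded synthetic fixtures: gene networks, drug–target maps, driverness vectors.

The generator emulates the three real inputs of the pipeline without any
download: a sparse random gene graph standing in for a STRING/BioGRID PIN
(scale-free by default, since interaction networks are heavy-tailed), drugs
with small random target sets standing in for a DGIdb export (including
deliberate duplicate target sets, to exercise drug merging, and targets
absent from the network, to exercise orphan handling), and a sparse
driverness vector with most scores near 0 and a few high ones, mimicking
the profile a driver-prioritization classifier produces for one tumor
sample.

All randomness flows from a single integer seed through one
``numpy.random.Generator``; identical seed and spec give byte-identical
TSV outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .network_io import DrugTargetMap, GeneNetwork


@dataclass
class FixtureSpec:
    """Parameters of one synthetic dataset.

    Defaults: 100 genes in a scale-free graph (attachment 2), 20 drugs with
    1–3 targets each, 10 altered genes of which 80% score below the 0.05
    driverness filter and 20% score in [0.5, 1] — so the filter path of the
    distance method is exercised meaningfully — plus 20% of drugs sharing a
    duplicate target set and 10% of drug targets pointing outside the
    network.
    """

    n_genes: int = 100
    edge_model: str = "scale_free"  # or "erdos_renyi"
    edge_prob: float = 0.05         # erdos_renyi only
    attachment: int = 2             # scale_free only
    n_drugs: int = 20
    targets_min: int = 1
    targets_max: int = 3
    n_altered: int = 10
    high_fraction: float = 0.2
    low_range: tuple[float, float] = (0.0, 0.05)
    high_range: tuple[float, float] = (0.5, 1.0)
    duplicate_target_fraction: float = 0.2
    orphan_target_fraction: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_drugs < 1:
            raise ValueError("n_genes and n_drugs must be >= 1")
        if not (1 <= self.targets_min <= self.targets_max):
            raise ValueError("need 1 <= targets_min <= targets_max")
        if self.targets_max > self.n_genes:
            raise ValueError(
                f"targets_per_drug up to {self.targets_max} exceeds "
                f"n_genes={self.n_genes}")
        for frac in (self.high_fraction, self.duplicate_target_fraction,
                     self.orphan_target_fraction):
            if not (0.0 <= frac <= 1.0):
                raise ValueError(f"fraction {frac} outside [0, 1]")
        if self.n_altered < 0 or self.n_altered > self.n_genes:
            raise ValueError("n_altered must be in [0, n_genes]")
        if self.edge_model not in ("scale_free", "erdos_renyi"):
            raise ValueError(f"unknown edge_model {self.edge_model!r}")


def _gene_name(i: int) -> str:
    return f"G{i:04d}"


def _orphan_name(i: int) -> str:
    return f"X{i:04d}"  # symbols deliberately outside the network


def generate_fixture(
    spec: FixtureSpec,
) -> tuple[GeneNetwork, DrugTargetMap, dict[str, float]]:
    """Generate (gene network, pre-merge drug–target map, driverness map).

    The network gets per-edge confidences uniform in [0.4, 1] (all above the
    default load threshold, so written fixtures survive reloading intact).
    A ``duplicate_target_fraction`` of drugs are arranged in pairs sharing
    an identical target set; an ``orphan_target_fraction`` of target slots
    are drawn from symbols absent from the network.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    if spec.edge_model == "erdos_renyi":
        raw = nx.gnp_random_graph(
            spec.n_genes, spec.edge_prob, seed=int(rng.integers(2**31)))
    else:
        m = min(spec.attachment, spec.n_genes - 1) if spec.n_genes > 1 else 0
        if m < 1:
            raw = nx.empty_graph(spec.n_genes)
        else:
            raw = nx.barabasi_albert_graph(
                spec.n_genes, m, seed=int(rng.integers(2**31)))

    graph = nx.Graph()
    graph.add_nodes_from(_gene_name(i) for i in range(spec.n_genes))
    for u, v in sorted(raw.edges):
        conf = round(float(rng.uniform(0.4, 1.0)), 3)
        graph.add_edge(_gene_name(u), _gene_name(v), confidence=conf)
    net = GeneNetwork(graph=graph, min_confidence=0.4, has_confidence=True)

    gene_names = [_gene_name(i) for i in range(spec.n_genes)]
    drug_names = [f"DRUG_{i:03d}" for i in range(spec.n_drugs)]
    entries: dict[str, frozenset[str]] = {}
    orphan_counter = 0
    for drug in drug_names:
        k = int(rng.integers(spec.targets_min, spec.targets_max + 1))
        targets = {str(g) for g in rng.choice(gene_names, size=k, replace=False)}
        swapped = set()
        for t in sorted(targets):
            if rng.random() < spec.orphan_target_fraction:
                targets.discard(t)
                swapped.add(_orphan_name(orphan_counter))
                orphan_counter += 1
        entries[drug] = frozenset(targets | swapped)

    # pair up a configured fraction of drugs to share identical target sets
    n_shared = int(round(spec.duplicate_target_fraction * spec.n_drugs))
    shared = [str(d) for d in rng.choice(drug_names, size=n_shared, replace=False)]
    for a, b in zip(shared[0::2], shared[1::2]):
        entries[b] = entries[a]

    drugs = DrugTargetMap(entries=entries)
    drugs.validate()

    altered = [str(g) for g in rng.choice(gene_names, size=spec.n_altered,
                                          replace=False)]
    n_high = int(round(spec.high_fraction * spec.n_altered))
    drivers: dict[str, float] = {}
    for i, g in enumerate(altered):
        lo, hi = spec.high_range if i < n_high else spec.low_range
        drivers[g] = round(float(rng.uniform(lo, hi)), 6)
    return net, drugs, drivers


def planted_signal_fixture(
    seed: int,
) -> tuple[GeneNetwork, DrugTargetMap, dict[str, float], str]:
    """A fixture with a known winner, for recovery tests.

    One "planted" drug directly targets the single high-driverness gene
    (driverness 0.95); every other drug's targets lie at least 3 hops away
    from every altered gene on a fixed tree topology. Both scoring methods
    must rank the planted drug first. The seed only permutes gene labels
    and drug names — both scorers are invariant under relabeling, so the
    winner is the same for every seed.
    """
    rng = np.random.default_rng(seed)
    # tree on 10 abstract positions; position 0 is the altered hub
    edges = [(0, 1), (0, 2), (1, 3), (3, 4), (4, 5), (5, 6),
             (2, 7), (7, 8), (8, 9)]
    labels = [f"GENE{i:02d}" for i in range(10)]
    rng.shuffle(labels)
    graph = nx.Graph()
    graph.add_nodes_from(labels)
    for u, v in edges:
        graph.add_edge(labels[u], labels[v])
    net = GeneNetwork(graph=graph)

    drug_names = [f"CMPD_{i}" for i in range(4)]
    rng.shuffle(drug_names)
    planted = drug_names[0]
    entries = {
        planted: frozenset({labels[0]}),           # 1 hop to the driver
        drug_names[1]: frozenset({labels[5]}),     # 4 hops from the hub
        drug_names[2]: frozenset({labels[8]}),     # 3 hops from the hub
        drug_names[3]: frozenset({labels[6], labels[9]}),  # 5 and 4 hops
    }
    drugs = DrugTargetMap(entries=entries)
    drivers = {labels[0]: 0.95}
    return net, drugs, drivers, planted


def write_fixture(
    out_dir,
    net: GeneNetwork,
    drugs: DrugTargetMap,
    drivers: dict[str, float],
    spec: FixtureSpec | None = None,
) -> dict:
    """Write pin.tsv, drug_targets.tsv, driver_scores.tsv and manifest.json.

    The manifest records the spec (if given) plus SHA-256 checksums of the
    three TSVs, so regenerated fixtures can be verified byte-for-byte.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    net.to_tsv(out / "pin.tsv")
    rows = [
        {"drug_claim_name": d, "gene_name": g}
        for d in sorted(drugs.entries)
        for g in sorted(drugs.entries[d])
    ]
    pd.DataFrame(rows).to_csv(out / "drug_targets.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"gene_symbol": g, "driverness_prob": s}
         for g, s in sorted(drivers.items())],
        columns=["gene_symbol", "driverness_prob"],
    ).to_csv(out / "driver_scores.tsv", sep="\t", index=False)

    manifest = {
        "spec": asdict(spec) if spec is not None else None,
        "checksums": {
            name: hashlib.sha256((out / name).read_bytes()).hexdigest()
            for name in ("pin.tsv", "drug_targets.tsv", "driver_scores.tsv")
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
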