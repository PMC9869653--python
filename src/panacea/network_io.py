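"""Loading, validation and assembly of the drug-extended protein interaction network.

Three ingredients are handled here:

* a gene–gene interaction network (STRING-links-style TSV edge list, with an
  optional per-edge combined-confidence column, or a plain two-column
  BioGRID-style list),
* a drug → target-gene interaction table (DGIdb-export-style TSV),
* the "extended PIN": the gene network augmented with one node per drug,
  wired to its in-network target genes.

Interactions are undirected; directionality is never considered. Low
confidence edges (combined score below ``min_confidence``, default 0.4) are
discarded at load time. Drugs targeting completely overlapping sets of genes
are merged and treated as a single drug.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Mapping

import networkx as nx
import pandas as pd

from .errors import EmptyNetworkError, ParseError

logger = logging.getLogger(__name__)

#: Prefix separating the drug-node namespace from gene symbols in the
#: combined graph, so a drug named like a gene can never collide with it.
DRUG_PREFIX = "drug::"

#: Header tokens recognized when auto-detecting a header row in edge lists.
_EDGE_HEADER_TOKENS = {
    "node1", "node2", "protein1", "protein2", "gene1", "gene2",
    "source", "target", "combined_score", "score", "confidence",
    "official symbol interactor a", "official symbol interactor b",
}

_DEFAULT_DRUG_COLUMNS = ("drug_claim_name", "drug", "drug_name")
_DEFAULT_GENE_COLUMNS = ("gene_name", "gene", "gene_symbol")


def _open_text(path) -> IO[str]:
    """Open a possibly gzip-compressed text file transparently."""
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


@dataclass
class GeneNetwork:
    """Undirected gene–gene interaction graph after confidence filtering.

    Parameters
    ----------
    graph
        ``networkx.Graph`` whose nodes are gene symbols. Edges may carry a
        ``confidence`` attribute in (0, 1].
    min_confidence
        The load-time confidence threshold applied, if any.
    has_confidence
        Whether per-edge confidence scores are present.
    """

    graph: nx.Graph
    min_confidence: float | None = None
    has_confidence: bool = False

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset((u, v)) for u, v in self.graph.edges}

    def confidence(self, u: str, v: str) -> float | None:
        return self.graph.edges[u, v].get("confidence")

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def validate(self) -> None:
        """Check structural invariants; raise ``ValueError`` on violation."""
        for u, v, data in self.graph.edges(data=True):
            if u == v:
                raise ValueError(f"self-loop edge on {u!r}")
            if not u or not v:
                raise ValueError("empty gene symbol in edge")
            conf = data.get("confidence")
            if self.has_confidence:
                if conf is None:
                    raise ValueError(f"edge {u!r}-{v!r} lacks confidence")
                if not (0.0 < conf <= 1.0):
                    raise ValueError(f"confidence {conf} outside (0, 1]")
                if self.min_confidence is not None and conf < self.min_confidence:
                    raise ValueError(
                        f"edge {u!r}-{v!r} below threshold {self.min_confidence}"
                    )

    def to_tsv(self, path, header: bool = True) -> None:
        """Write the edge list (with confidence column if present) as TSV."""
        rows = []
        for u, v in sorted(tuple(sorted(e)) for e in self.graph.edges):
            if self.has_confidence:
                rows.append((u, v, self.graph.edges[u, v]["confidence"]))
            else:
                rows.append((u, v))
        if self.has_confidence:
            df = pd.DataFrame(rows, columns=["node1", "node2", "combined_score"])
        else:
            df = pd.DataFrame(rows, columns=["node1", "node2"])
        df.to_csv(path, sep="\t", index=False, header=header)


@dataclass
class DrugTargetMap:
    """Map from drug identifier to its (non-empty) set of target gene symbols.

    After :func:`merge_equivalent_drugs` no two identifiers map to the same
    target set, and ``merge_ledger`` records merged-name → original names.
    """

    entries: dict[str, frozenset[str]]
    merge_ledger: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[str]:
        return iter(self.entries)

    def __getitem__(self, drug: str) -> frozenset[str]:
        return self.entries[drug]

    def validate(self) -> None:
        for drug, targets in self.entries.items():
            if not drug:
                raise ValueError("empty drug identifier")
            if not targets:
                raise ValueError(f"drug {drug!r} has an empty target set")
            if any(not t for t in targets):
                raise ValueError(f"drug {drug!r} has an empty gene symbol")


@dataclass
class ExtendedNetwork:
    """The gene network plus drug nodes wired to their in-network targets.

    Drug nodes live in a separate namespace (:data:`DRUG_PREFIX`); the
    gene–gene edge set is exactly that of ``gene_network``. Drugs whose
    targets are all absent from the network are kept as isolated nodes and
    listed in ``orphan_drugs``.
    """

    gene_network: GeneNetwork
    drug_targets: dict[str, frozenset[str]]  # in-network targets only
    orphan_drugs: frozenset[str]
    n_dropped_targets: int = 0
    merge_ledger: dict[str, tuple[str, ...]] = field(default_factory=dict)

    @property
    def drug_nodes(self) -> set[str]:
        return set(self.drug_targets)

    @property
    def drug_edges(self) -> set[tuple[str, str]]:
        return {
            (drug, gene)
            for drug, targets in self.drug_targets.items()
            for gene in targets
        }

    def drug_node_name(self, drug: str) -> str:
        return DRUG_PREFIX + drug

    def full_graph(self) -> nx.Graph:
        """Combined graph with namespaced drug nodes, for propagation."""
        g = self.gene_network.graph.copy()
        for drug, targets in self.drug_targets.items():
            name = self.drug_node_name(drug)
            g.add_node(name)
            for t in targets:
                g.add_edge(name, t)
        return g

    def validate(self) -> None:
        gene_nodes = self.gene_network.nodes
        for drug, targets in self.drug_targets.items():
            if drug in gene_nodes:
                # the namespace prefix keeps graph nodes distinct regardless
                pass
            for t in targets:
                if t not in gene_nodes:
                    raise ValueError(
                        f"drug edge ({drug!r}, {t!r}) points outside the network"
                    )
            if not targets and drug not in self.orphan_drugs:
                raise ValueError(f"target-less drug {drug!r} not flagged as orphan")


def _detect_edge_header(fields: list[str]) -> bool:
    if any(f.strip().lower() in _EDGE_HEADER_TOKENS for f in fields):
        return True
    if len(fields) >= 3:
        try:
            float(fields[2])
        except ValueError:
            return True
    return False


def load_gene_network(
    path,
    min_confidence: float = 0.4,
    dialect: str = "unit",
    header: bool | None = None,
    undirected: bool = True,
) -> GeneNetwork:
    """Read a TSV edge list into a validated :class:`GeneNetwork`.

    Parameters
    ----------
    path
        TSV (optionally gzipped) with two node columns and an optional
        numeric confidence column.
    min_confidence
        Edges with confidence below this value are discarded. Ignored when
        the file has no confidence column.
    dialect
        ``"unit"`` — confidences already in (0, 1]; ``"string1000"`` —
        STRING-style integer scores 0–1000, divided by 1000 before
        thresholding.
    header
        ``True``/``False`` to declare a header row, ``None`` to auto-detect.
    undirected
        Kept for interface symmetry; interactions are always undirected.

    Raises
    ------
    ParseError
        On a row with the wrong column count or a non-numeric confidence,
        naming the offending line number.
    EmptyNetworkError
        If no edges survive filtering.
    """
    if dialect not in ("unit", "string1000"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if not undirected:
        raise ValueError("directed interaction networks are not supported")

    graph = nx.Graph()
    n_rows = n_self = n_low = 0
    has_conf: bool | None = None

    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if lineno == 1:
                is_header = header if header is not None else _detect_edge_header(fields)
                if is_header:
                    continue
            if len(fields) < 2:
                raise ParseError(
                    f"{path}: line {lineno}: expected >=2 tab-separated "
                    f"columns, got {len(fields)}"
                )
            u, v = fields[0].strip(), fields[1].strip()
            if not u or not v:
                raise ParseError(f"{path}: line {lineno}: empty gene symbol")
            row_has_conf = len(fields) >= 3 and fields[2].strip() != ""
            if has_conf is None:
                has_conf = row_has_conf
            elif row_has_conf != has_conf:
                raise ParseError(
                    f"{path}: line {lineno}: inconsistent column count"
                )
            n_rows += 1
            if u == v:
                n_self += 1
                continue
            if has_conf:
                try:
                    conf = float(fields[2])
                except ValueError:
                    raise ParseError(
                        f"{path}: line {lineno}: non-numeric confidence "
                        f"{fields[2]!r}"
                    ) from None
                if dialect == "string1000":
                    conf = conf / 1000.0
                if conf < min_confidence:
                    n_low += 1
                    continue
                if graph.has_edge(u, v):
                    # duplicate rows collapse; keep the max confidence
                    conf = max(conf, graph.edges[u, v]["confidence"])
                graph.add_edge(u, v, confidence=conf)
            else:
                graph.add_edge(u, v)

    if graph.number_of_edges() == 0:
        raise EmptyNetworkError(
            f"{path}: empty network after filtering "
            f"({n_rows} rows, {n_low} below confidence {min_confidence}, "
            f"{n_self} self-loops)"
        )
    logger.info(
        "loaded %s: %d rows -> %d nodes / %d edges "
        "(%d self-loops removed, %d below confidence %.3g)",
        path, n_rows, graph.number_of_nodes(), graph.number_of_edges(),
        n_self, n_low, min_confidence,
    )
    net = GeneNetwork(
        graph=graph,
        min_confidence=min_confidence if has_conf else None,
        has_confidence=bool(has_conf),
    )
    net.validate()
    return net


def _pick_column(columns: Iterable[str], candidates: tuple[str, ...], which: str) -> str:
    cols = list(columns)
    lowered = {c.lower(): c for c in cols}
    for cand in candidates:
        if cand in lowered:
            return lowered[cand]
    raise ParseError(
        f"could not find a {which} column among {cols}; "
        f"expected one of {list(candidates)} (or pass the column name explicitly)"
    )


def load_drug_targets(
    path,
    drug_column: str | None = None,
    gene_column: str | None = None,
) -> DrugTargetMap:
    """Read a DGIdb-style drug–gene interaction TSV into a :class:`DrugTargetMap`.

    Rows are grouped by drug, duplicate (drug, gene) pairs collapsed, and
    names whitespace-trimmed. Rows with an empty drug or gene field are
    skipped with a logged warning count. Column names default to the DGIdb
    export conventions but can be overridden.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if drug_column is None:
        drug_column = _pick_column(df.columns, _DEFAULT_DRUG_COLUMNS, "drug-name")
    if gene_column is None:
        gene_column = _pick_column(df.columns, _DEFAULT_GENE_COLUMNS, "gene-symbol")
    for col in (drug_column, gene_column):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")

    entries: dict[str, set[str]] = {}
    n_skipped = 0
    for drug, gene in zip(df[drug_column], df[gene_column]):
        drug = drug.strip() if isinstance(drug, str) else ""
        gene = gene.strip() if isinstance(gene, str) else ""
        if not drug or not gene:
            n_skipped += 1
            continue
        entries.setdefault(drug, set()).add(gene)
    if n_skipped:
        logger.warning("%s: skipped %d rows with empty drug/gene fields",
                       path, n_skipped)
    if not entries:
        raise ParseError(f"{path}: no valid drug-target rows")
    logger.info("loaded %s: %d drugs, %d interactions",
                path, len(entries),
                sum(len(t) for t in entries.values()))
    dmap = DrugTargetMap({d: frozenset(t) for d, t in entries.items()})
    dmap.validate()
    return dmap


def merge_equivalent_drugs(drug_map: DrugTargetMap) -> DrugTargetMap:
    """Merge drugs targeting completely overlapping (identical) gene sets.

    The merged identifier is the lexicographically sorted member names joined
    by ``"/"``; the returned map's ``merge_ledger`` records merged name →
    original names so per-drug annotations remain resolvable. Idempotent.
    """
    by_targets: dict[frozenset[str], list[str]] = {}
    for drug, targets in drug_map.entries.items():
        by_targets.setdefault(targets, []).append(drug)

    entries: dict[str, frozenset[str]] = {}
    ledger = dict(drug_map.merge_ledger)
    for targets, drugs in by_targets.items():
        if len(drugs) == 1:
            entries[drugs[0]] = targets
            continue
        # expand any already-merged member so re-merging stays flat
        members = sorted({m for d in drugs for m in ledger.get(d, (d,))})
        merged = "/".join(members)
        entries[merged] = targets
        for d in drugs:
            ledger.pop(d, None)
        ledger[merged] = tuple(members)
    if len(drug_map.entries) != len(entries):
        logger.info("merged %d drugs with identical target sets into %d entries",
                    len(drug_map.entries), len(entries))
    return DrugTargetMap(entries=entries, merge_ledger=ledger)


def extend_network(net: GeneNetwork, drugs: DrugTargetMap) -> ExtendedNetwork:
    """Wire each drug to its in-network target genes, producing the extended PIN.

    Targets absent from the network are dropped per-edge (count logged); a
    drug with zero in-network targets is retained as an isolated, flagged
    node so that every drug still receives a (zero) score downstream.
    """
    gene_nodes = net.nodes
    drug_targets: dict[str, frozenset[str]] = {}
    orphans: set[str] = set()
    n_dropped = 0
    for drug, targets in drugs.entries.items():
        present = frozenset(t for t in targets if t in gene_nodes)
        n_dropped += len(targets) - len(present)
        drug_targets[drug] = present
        if not present:
            orphans.add(drug)
    if n_dropped:
        logger.info("dropped %d drug-target edges to genes absent from the "
                    "network; %d drugs left isolated", n_dropped, len(orphans))
    xnet = ExtendedNetwork(
        gene_network=net,
        drug_targets=drug_targets,
        orphan_drugs=frozenset(orphans),
        n_dropped_targets=n_dropped,
        merge_ledger=dict(drugs.merge_ledger),
    )
    xnet.validate()
    return xnet


def load_driver_scores(
    path,
    gene_column: str | None = None,
    score_column: str | None = None,
) -> dict[str, float]:
    """Read a per-sample driverness-score TSV into ``{gene: score}``.

    The file matches driveR's output shape: a gene-symbol column and a
    driverness-probability column in [0, 1]. Genes absent from the map are
    treated as driverness 0 everywhere downstream.
    """
    df = pd.read_csv(path, sep="\t")
    if gene_column is None:
        gene_column = _pick_column(
            df.columns, ("gene_symbol", "gene", "gene_name"), "gene-symbol")
    if score_column is None:
        score_column = _pick_column(
            df.columns,
            ("driverness_prob", "driverness", "score", "prediction"),
            "driverness-score")
    scores: dict[str, float] = {}
    for gene, score in zip(df[gene_column], df[score_column]):
        gene = str(gene).strip()
        score = float(score)
        if not gene:
            raise ParseError(f"{path}: empty gene symbol")
        if not (0.0 <= score <= 1.0):
            raise ParseError(f"{path}: driverness {score} for {gene!r} "
                             "outside [0, 1]")
        scores[gene] = score
    return scores
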