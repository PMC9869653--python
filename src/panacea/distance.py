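"""Distance-based drug scoring.

Each drug d is scored against each altered gene g as

    s(d, g) = driver_g / (dist(d, g) + 1)^2

where dist(d, g) is the shortest-path hop count between the drug node and
the gene on the extended PIN, and driver_g is the gene's driverness score.
The +1 in the denominator guards division by zero; the square makes the
contribution decay quickly with distance, emphasizing genes close to the
drug's targets. The drug score is the mean of s(d, g) over the altered-gene
set, restricted to genes with driverness strictly above a threshold
(default 0.05) to drop genes that contribute no driver signal.

Drug nodes are never used as intermediary nodes: drug–target edges count as
one (terminal) hop, so dist(d, g) = 1 + min over in-network targets t of the
gene-only hop distance from t to g. Genes unreachable from every target
contribute 0 (the dist → ∞ limit of the formula) but still count in the
denominator.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .network_io import ExtendedNetwork

logger = logging.getLogger(__name__)

#: Genes with driverness strictly above this are kept in the altered-gene set.
DEFAULT_DRIVER_THRESHOLD = 0.05


@dataclass
class DrugScoreVector:
    """Nonnegative per-drug scores from one scoring method.

    Covers every drug in the drug–target map; isolated/unreachable drugs
    score exactly 0. ``empty_driver_set`` flags a sample whose filtered
    altered-gene set was empty (all scores are then 0 by construction).
    """

    scores: dict[str, float]
    method: str
    params: dict = field(default_factory=dict)
    empty_driver_set: bool = False

    def __getitem__(self, drug: str) -> float:
        return self.scores[drug]

    def __len__(self) -> int:
        return len(self.scores)

    def ranked(self) -> pd.DataFrame:
        """Scores sorted descending (lexicographic name tie-break), with
        min-rank ties sharing the same rank."""
        df = pd.DataFrame(
            sorted(self.scores.items(), key=lambda kv: (-kv[1], kv[0])),
            columns=["drug", "score"],
        )
        df["rank"] = df["score"].rank(method="min", ascending=False).astype(int)
        return df

    def to_tsv(self, path) -> None:
        self.ranked().to_csv(path, sep="\t", index=False)

    def validate(self) -> None:
        for drug, score in self.scores.items():
            if score < 0:
                raise ValueError(f"negative score {score} for {drug!r}")


def gene_distances_from_targets(
    xnet: ExtendedNetwork, targets: frozenset[str]
) -> dict[str, int]:
    """Multi-source BFS hop distances on the gene-only graph.

    Returns ``{gene: hops}`` from the nearest member of ``targets``;
    genes in no target's component are absent (unreachable).
    """
    adj = xnet.gene_network.graph.adj
    dist: dict[str, int] = {t: 0 for t in targets}
    queue = deque(targets)
    while queue:
        u = queue.popleft()
        du = dist[u]
        for v in adj[u]:
            if v not in dist:
                dist[v] = du + 1
                queue.append(v)
    return dist


def drug_gene_distances(xnet: ExtendedNetwork, drug: str) -> dict[str, int]:
    """Shortest-path hop counts from one drug to every reachable gene.

    dist(d, g) = 1 + min over the drug's in-network targets t of the
    gene-graph hop distance t → g, so direct targets sit at distance 1 and
    paths never pass through other drug nodes. Unreachable genes are absent
    from the returned map.
    """
    if drug not in xnet.drug_targets:
        raise KeyError(f"unknown drug {drug!r}")
    targets = xnet.drug_targets[drug]
    if not targets:
        return {}
    return {g: d + 1 for g, d in gene_distances_from_targets(xnet, targets).items()}


def pair_score(dist: int | None, driver: float) -> float:
    """Single drug–gene score driver / (dist + 1)^2; unreachable (None) → 0."""
    if dist is None:
        return 0.0
    return driver / (dist + 1) ** 2


def score_distance_based(
    xnet: ExtendedNetwork,
    drivers: Mapping[str, float],
    driver_threshold: float | None = DEFAULT_DRIVER_THRESHOLD,
) -> DrugScoreVector:
    """Score every drug by the mean distance-decayed driverness.

    Parameters
    ----------
    xnet
        The drug-extended network.
    drivers
        Per-gene driverness scores in [0, 1]; genes absent score 0.
    driver_threshold
        Strict lower bound on driverness for a gene to enter the altered-gene
        set; ``None`` disables the filter (all genes with a score > 0 or not
        are kept as given).

    Returns
    -------
    DrugScoreVector
        One score per drug (including merged and orphan drugs). If the
        filtered altered-gene set is empty, every score is 0 and
        ``empty_driver_set`` is set.
    """
    if driver_threshold is not None and not (0.0 <= driver_threshold < 1.0):
        raise ValueError(f"driver_threshold {driver_threshold} outside [0, 1)")

    gene_nodes = xnet.gene_network.nodes
    if driver_threshold is None:
        eligible = dict(drivers)
    else:
        eligible = {g: s for g, s in drivers.items() if s > driver_threshold}
    missing = [g for g in eligible if g not in gene_nodes]
    if missing:
        logger.warning(
            "%d altered genes above the driverness threshold are absent from "
            "the network and were excluded: %s",
            len(missing), ", ".join(sorted(missing)[:10]),
        )
    gstar = {g: s for g, s in eligible.items() if g in gene_nodes}

    params = {"driver_threshold": driver_threshold, "n_altered_genes": len(gstar)}
    if not gstar:
        logger.warning("no altered genes above the driverness threshold; "
                       "all drug scores are 0")
        return DrugScoreVector(
            scores={d: 0.0 for d in xnet.drug_targets},
            method="distance", params=params, empty_driver_set=True,
        )

    n = len(gstar)
    scores: dict[str, float] = {}
    for drug in xnet.drug_targets:
        dist = drug_gene_distances(xnet, drug)
        total = sum(
            pair_score(dist.get(g), s) for g, s in gstar.items()
        )
        scores[drug] = total / n
    result = DrugScoreVector(scores=scores, method="distance", params=params)
    result.validate()
    return result
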