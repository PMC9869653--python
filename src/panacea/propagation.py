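"""Network-propagation drug scoring via random walk with restart (RWR).

Driverness scores of altered genes are mapped onto the extended PIN as the
prior vector Y (zero for unaltered genes and for drug nodes). The symmetric
0/1 adjacency W of the extended network is Laplacian-normalized,

    W' = D^(-1/2) W D^(-1/2),    D_ii = sum_j W_ij,

and propagation scores F are obtained by iterating

    F(t) = (1 - alpha) W' F(t-1) + alpha Y,     F(0) = Y,

until ||F(t) - F(t-1)||_2 < tol (default 1e-4) or the iteration count
exceeds 1000. alpha is the restart parameter (default 0.05). Because W' is
a symmetric normalized adjacency its spectral radius is at most 1, so the
update is a contraction with factor (1 - alpha) and converges to the fixed
point alpha (I - (1 - alpha) W')^(-1) Y. The score of a drug is its final
propagation score F at the drug node.

Isolated nodes (degree 0) get zero rows/columns in W' — they neither send
nor receive signal — so orphan drugs score exactly 0, mirroring the
distance method's unreachable ⇒ 0 contract.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import sparse

from .distance import DrugScoreVector
from .errors import NoEdgesError, NoPriorSignalError
from .network_io import ExtendedNetwork

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
DEFAULT_TOL = 1e-4
DEFAULT_MAX_ITER = 1000


def node_order(xnet: ExtendedNetwork) -> list[str]:
    """Fixed deterministic node ordering: sorted genes, then sorted drug nodes."""
    genes = sorted(xnet.gene_network.nodes)
    drugs = [xnet.drug_node_name(d) for d in sorted(xnet.drug_targets)]
    return genes + drugs


@dataclass
class NormalizedAdjacency:
    """Laplacian-normalized sparse adjacency of the extended network.

    ``matrix`` is symmetric with entries 1/sqrt(deg_i * deg_j) on edges;
    rows/columns of isolated nodes are zero. ``nodes`` fixes the coordinate
    order (sorted gene symbols followed by sorted, namespaced drug nodes).
    """

    nodes: list[str]
    matrix: sparse.csr_array

    @property
    def index(self) -> dict[str, int]:
        return {n: i for i, n in enumerate(self.nodes)}


def laplacian_normalize(xnet: ExtendedNetwork) -> NormalizedAdjacency:
    """Build W' = D^(-1/2) W D^(-1/2) over the extended network.

    Raises :class:`NoEdgesError` if the extended network has no edges at all.
    """
    order = node_order(xnet)
    idx = {n: i for i, n in enumerate(order)}
    graph = xnet.full_graph()
    if graph.number_of_edges() == 0:
        raise NoEdgesError("no interactions to propagate over")

    rows, cols = [], []
    for u, v in graph.edges:
        i, j = idx[u], idx[v]
        rows.extend((i, j))
        cols.extend((j, i))
    n = len(order)
    w = sparse.csr_array(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    )
    deg = np.asarray(w.sum(axis=1)).ravel()
    with np.errstate(divide="ignore"):
        inv_sqrt = 1.0 / np.sqrt(deg)
    inv_sqrt[deg == 0] = 0.0  # isolated nodes: zero row/column
    d_inv = sparse.diags_array(inv_sqrt)
    wn = sparse.csr_array(d_inv @ w @ d_inv)
    return NormalizedAdjacency(nodes=order, matrix=wn)


def build_prior(
    xnet: ExtendedNetwork,
    drivers: Mapping[str, float],
    driver_threshold: float | None = None,
) -> np.ndarray:
    """Map driverness scores onto the extended PIN as the prior vector Y.

    Y_g is the driverness of each altered gene present in the network; all
    other genes and every drug node get 0. No driverness filter is applied
    by default (the >0.05 cut belongs to the distance method only), but one
    can be requested via ``driver_threshold``.

    Raises :class:`NoPriorSignalError` if Y would be identically zero, since
    propagation of a zero prior is identically zero and indistinguishable
    from a real result.
    """
    order = node_order(xnet)
    gene_nodes = xnet.gene_network.nodes
    used = {
        g: s for g, s in drivers.items()
        if driver_threshold is None or s > driver_threshold
    }
    missing = [g for g in used if g not in gene_nodes]
    if missing:
        logger.warning(
            "%d altered genes absent from the network dropped from the prior",
            len(missing))
    y = np.zeros(len(order))
    idx = {n: i for i, n in enumerate(order)}
    for g, s in used.items():
        if g in gene_nodes:
            y[idx[g]] = s
    if not np.any(y):
        raise NoPriorSignalError(
            "no prior signal: no altered gene with nonzero driverness is "
            "present in the network")
    return y


@dataclass
class PropagationResult:
    """Outcome of the RWR iteration.

    ``converged`` is True iff the L2 stopping rule fired at or before the
    iteration cap; a capped, non-converged run is returned (with a warning)
    rather than raised, since it signals pathological input worth inspecting.
    """

    nodes: list[str]
    f: np.ndarray
    iterations: int
    converged: bool
    alpha: float
    tol: float

    def score_of(self, node: str) -> float:
        return float(self.f[self.nodes.index(node)])

    def as_dict(self) -> dict[str, float]:
        return {n: float(v) for n, v in zip(self.nodes, self.f)}


def propagate(
    wn: NormalizedAdjacency,
    y: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> PropagationResult:
    """Iterate F(t) = (1 - alpha) W' F(t-1) + alpha Y from F(0) = Y."""
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"alpha {alpha} outside (0, 1]")
    if y.shape != (len(wn.nodes),):
        raise ValueError("prior vector length does not match the node order")
    if np.any(y < 0):
        raise ValueError("prior vector must be nonnegative")

    f = y.astype(float).copy()
    converged = False
    iterations = 0
    for t in range(1, max_iter + 1):
        f_next = (1.0 - alpha) * (wn.matrix @ f) + alpha * y
        delta = float(np.linalg.norm(f_next - f))
        f = f_next
        iterations = t
        if delta < tol:
            converged = True
            break
    if not converged:
        logger.warning("propagation did not converge within %d iterations "
                       "(last step %.3g >= tol %.3g)", max_iter, delta, tol)
    return PropagationResult(
        nodes=wn.nodes, f=f, iterations=iterations, converged=converged,
        alpha=alpha, tol=tol,
    )


def propagation_fixed_point(wn: NormalizedAdjacency, y: np.ndarray,
                            alpha: float = DEFAULT_ALPHA) -> np.ndarray:
    """Closed-form fixed point alpha (I - (1 - alpha) W')^(-1) Y via a direct
    sparse solve. Exposed for diagnostics and cross-checking the iteration."""
    n = len(wn.nodes)
    a = sparse.eye_array(n, format="csc") - (1.0 - alpha) * sparse.csc_array(wn.matrix)
    return alpha * sparse.linalg.spsolve(a, y)


def score_propagation(
    xnet: ExtendedNetwork,
    drivers: Mapping[str, float],
    alpha: float = DEFAULT_ALPHA,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    driver_threshold: float | None = None,
) -> DrugScoreVector:
    """Run the full propagation pipeline and extract the drug-node scores."""
    wn = laplacian_normalize(xnet)
    y = build_prior(xnet, drivers, driver_threshold=driver_threshold)
    res = propagate(wn, y, alpha=alpha, tol=tol, max_iter=max_iter)
    idx = res.nodes
    f_by_node = dict(zip(idx, res.f))
    scores = {
        drug: float(f_by_node[xnet.drug_node_name(drug)])
        for drug in xnet.drug_targets
    }
    result = DrugScoreVector(
        scores=scores,
        method="propagation",
        params={
            "alpha": alpha, "tol": tol, "max_iter": max_iter,
            "iterations": res.iterations, "converged": res.converged,
            "driver_threshold": driver_threshold,
        },
    )
    result.validate()
    return result


def alpha_sweep(
    xnet: ExtendedNetwork,
    drivers: Mapping[str, float],
    alphas: list[float],
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> dict[float, DrugScoreVector]:
    """One ranked score vector per restart parameter, for manual inspection
    of which alpha yields the most relevant rankings."""
    wn = laplacian_normalize(xnet)
    y = build_prior(xnet, drivers)
    out: dict[float, DrugScoreVector] = {}
    for alpha in alphas:
        res = propagate(wn, y, alpha=alpha, tol=tol, max_iter=max_iter)
        f_by_node = dict(zip(res.nodes, res.f))
        out[alpha] = DrugScoreVector(
            scores={d: float(f_by_node[xnet.drug_node_name(d)])
                    for d in xnet.drug_targets},
            method="propagation",
            params={"alpha": alpha, "tol": tol, "max_iter": max_iter,
                    "iterations": res.iterations, "converged": res.converged},
        )
    return out
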