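"""Node-level and network-level topological statistics.

Definitions (undirected, unweighted, hop distances):

* degree ``k(v)`` — number of incident edges.
* betweenness ``BC(v)`` — fraction of shortest paths between other node
  pairs that pass through ``v`` (Brandes' algorithm; endpoints excluded,
  multiplicity credited fractionally, normalised by ``(N-1)(N-2)/2``).
* closeness ``CC(v) = (N-1) / sum_u d(v, u)`` on a connected graph.
* eigenvector centrality — principal-eigenvector score, scaled so the
  maximum is 1, computed by power iteration (see
  :func:`eigenvector_centrality` for the convergence rule).
* eccentricity / radius / diameter / center — the usual max-distance
  quantities.
* local clustering ``C(v) = 2 t(v) / (k (k-1))`` with ``C = 0`` for
  ``k < 2``.

Global summaries mirror the standard small-world diagnostics: average
degree (mean +/- sample sd), diameter, radius, center, mean shortest path
length over unordered pairs (mspl), and the arithmetic mean of local
clustering coefficients (acc).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import mean
from typing import Mapping

import networkx as nx
import numpy as np

from .errors import DataError, PPINetError

__all__ = [
    "NodeMetrics",
    "GlobalMetrics",
    "SmallWorldResult",
    "degree",
    "betweenness",
    "closeness",
    "eccentricity",
    "eigenvector_centrality",
    "clustering_coefficient",
    "compute_node_metrics",
    "global_metrics",
    "small_world_summary",
]


@dataclass(frozen=True)
class NodeMetrics:
    node: str
    degree: int
    betweenness: float
    closeness: float
    eigenvector: float
    eccentricity: int
    clustering: float


@dataclass(frozen=True)
class EccentricityResult:
    eccentricity: Mapping[str, int]
    radius: int
    diameter: int
    center: tuple[str, ...]


@dataclass(frozen=True)
class GlobalMetrics:
    """Network-level summary: N, E, <k> +/- sd, D, radius, center, mspl, acc."""

    n_nodes: int
    n_edges: int
    avg_degree: float
    sd_degree: float
    diameter: int
    radius: int
    center: tuple[str, ...]
    mspl: float
    avg_clustering: float


def _require_connected(graph: nx.Graph, what: str) -> None:
    if graph.number_of_nodes() == 0:
        raise DataError(f"{what} needs a non-empty network")
    if not nx.is_connected(graph):
        raise DataError(
            f"{what} is defined on a connected network: "
            "extract the giant component first"
        )


def degree(graph: nx.Graph) -> dict[str, int]:
    """Degree of every node; the handshake identity sum(k) = 2E holds."""
    return {v: int(d) for v, d in graph.degree()}


def betweenness(graph: nx.Graph) -> dict[str, float]:
    """Pair-normalised betweenness centrality (Brandes).

    Endpoints are excluded from their own score and shortest-path
    multiplicity is credited fractionally; values are divided by
    ``(N-1)(N-2)/2`` so they lie in ``[0, 1]``.  Graphs with fewer than
    three nodes have all-zero betweenness.
    """
    if graph.number_of_nodes() < 3:
        return {v: 0.0 for v in graph.nodes}
    return dict(nx.betweenness_centrality(graph, normalized=True))


def closeness(graph: nx.Graph) -> dict[str, float]:
    """Closeness ``(N-1)/sum_u d(v,u)`` on a connected graph."""
    _require_connected(graph, "closeness centrality")
    return dict(nx.closeness_centrality(graph))


def eccentricity(graph: nx.Graph) -> EccentricityResult:
    """Per-node eccentricity plus radius, diameter, and center."""
    _require_connected(graph, "eccentricity")
    ecc = {v: int(e) for v, e in nx.eccentricity(graph).items()}
    radius = min(ecc.values())
    diameter = max(ecc.values())
    center = tuple(sorted(v for v, e in ecc.items() if e == radius))
    return EccentricityResult(ecc, radius, diameter, center)


def eigenvector_centrality(
    graph: nx.Graph,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> dict[str, float]:
    """Eigenvector centrality by power iteration, scaled so max = 1.

    Iterates ``x <- (A + I) x`` from the uniform vector, renormalising to
    unit L1 norm each step, and stops when the L1 change between
    successive iterates falls below ``tol``.  The identity shift leaves
    the principal eigenvector of ``A`` unchanged (for a connected graph
    ``A + I`` is primitive) and guarantees convergence on bipartite
    graphs, where plain power iteration oscillates.
    """
    _require_connected(graph, "eigenvector centrality")
    nodes = sorted(graph.nodes)
    if len(nodes) == 1:
        return {nodes[0]: 1.0}
    a = nx.to_numpy_array(graph, nodelist=nodes)
    np.fill_diagonal(a, 1.0)
    x = np.full(len(nodes), 1.0 / len(nodes))
    for _ in range(max_iter):
        x_next = a @ x
        x_next /= x_next.sum()
        residual = float(np.abs(x_next - x).sum())
        x = x_next
        if residual < tol:
            return dict(zip(nodes, x / x.max()))
    raise PPINetError(
        f"eigenvector centrality did not converge in {max_iter} iterations "
        f"(L1 residual {residual:.3e} >= tol {tol:.1e})"
    )


def clustering_coefficient(graph: nx.Graph) -> dict[str, float]:
    """Local clustering ``2t/(k(k-1))``; 0 for nodes of degree < 2."""
    return {v: float(c) for v, c in nx.clustering(graph).items()}


def compute_node_metrics(
    graph: nx.Graph,
    ec_tol: float = 1e-10,
    ec_max_iter: int = 10_000,
) -> list[NodeMetrics]:
    """All node metrics on a connected graph, rows sorted by node label."""
    _require_connected(graph, "node metrics")
    deg = degree(graph)
    bc = betweenness(graph)
    cc = closeness(graph)
    ecc = eccentricity(graph).eccentricity
    ec = eigenvector_centrality(graph, tol=ec_tol, max_iter=ec_max_iter)
    clust = clustering_coefficient(graph)
    return [
        NodeMetrics(
            node=v, degree=deg[v], betweenness=bc[v], closeness=cc[v],
            eigenvector=ec[v], eccentricity=ecc[v], clustering=clust[v],
        )
        for v in sorted(graph.nodes)
    ]


def mean_shortest_path_length(graph: nx.Graph) -> float:
    """Mean hop distance over unordered distinct pairs of a connected graph."""
    _require_connected(graph, "mean shortest path length")
    n = graph.number_of_nodes()
    if n < 2:
        raise DataError("mean shortest path length needs at least two nodes")
    total = sum(
        d for _, dists in nx.all_pairs_shortest_path_length(graph) for d in dists.values()
    )
    return total / (n * (n - 1))  # ordered sum over unordered pairs cancels the 2


def global_metrics(graph: nx.Graph) -> GlobalMetrics:
    """Assemble the network-level summary on a connected graph."""
    _require_connected(graph, "global metrics")
    degrees = np.array([d for _, d in graph.degree()], dtype=float)
    ecc = eccentricity(graph)
    sd = float(degrees.std(ddof=1)) if len(degrees) > 1 else 0.0
    return GlobalMetrics(
        n_nodes=graph.number_of_nodes(),
        n_edges=graph.number_of_edges(),
        avg_degree=float(degrees.mean()),
        sd_degree=sd,
        diameter=ecc.diameter,
        radius=ecc.radius,
        center=ecc.center,
        mspl=mean_shortest_path_length(graph),
        avg_clustering=float(mean(clustering_coefficient(graph).values())),
    )


@dataclass(frozen=True)
class SmallWorldResult:
    """Observed clustering and path length against G(n, m) random graphs."""

    clustering_ratio: float
    mspl_ratio: float
    acc_observed: float
    mspl_observed: float
    acc_random_mean: float
    acc_random_sd: float
    mspl_random_mean: float
    mspl_random_sd: float
    n_random: int
    rng_seed: int


def small_world_summary(
    graph: nx.Graph,
    n_random: int = 20,
    rng_seed: int = 0,
) -> SmallWorldResult:
    """Compare acc and mspl with size-matched ``G(n, m)`` random graphs.

    Each replicate draws a random graph with the observed node and edge
    counts; when a replicate is disconnected its largest component is
    used for the path length.  Requires ``n_random >= 10`` so the null
    mean is stable.
    """
    _require_connected(graph, "small-world summary")
    if n_random < 10:
        raise DataError("small_world_summary needs n_random >= 10")
    n, m = graph.number_of_nodes(), graph.number_of_edges()
    rng = np.random.default_rng(rng_seed)
    accs, mspls = [], []
    for _ in range(n_random):
        random_graph = nx.gnm_random_graph(n, m, seed=int(rng.integers(2**31)))
        accs.append(float(mean(nx.clustering(random_graph).values())))
        if not nx.is_connected(random_graph):
            biggest = max(nx.connected_components(random_graph), key=len)
            random_graph = random_graph.subgraph(biggest)
        mspls.append(float(nx.average_shortest_path_length(random_graph)))
    acc_obs = float(mean(clustering_coefficient(graph).values()))
    mspl_obs = mean_shortest_path_length(graph)
    acc_rand = float(np.mean(accs))
    mspl_rand = float(np.mean(mspls))
    return SmallWorldResult(
        clustering_ratio=acc_obs / acc_rand if acc_rand > 0 else float("inf"),
        mspl_ratio=mspl_obs / mspl_rand,
        acc_observed=acc_obs,
        mspl_observed=mspl_obs,
        acc_random_mean=acc_rand,
        acc_random_sd=float(np.std(accs, ddof=1)),
        mspl_random_mean=mspl_rand,
        mspl_random_sd=float(np.std(mspls, ddof=1)),
        n_random=n_random,
        rng_seed=rng_seed,
    )
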