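"""Hub/bottleneck backbone retrieval, second-shell extension, and comparison.

Hubs are the nodes in the top fraction (default 10%) of the degree
ranking; bottlenecks the top fraction of the betweenness ranking.  The
backbone is their union together with the subgraph it induces.  The
target count is ``floor(fraction * N)`` (at least 1); every node tied
with the cutoff value is included, so the selection is deterministic and
never breaks ties arbitrarily.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx

from .construct import DEFAULT_PRIOR, DEFAULT_THRESHOLD, build_network, filter_interactions
from .errors import DataError
from .io import ScoredInteraction
from .topology import NodeMetrics, compute_node_metrics

logger = logging.getLogger(__name__)

DEFAULT_FRACTION = 0.10


@dataclass(frozen=True)
class Backbone:
    """Selected hub/bottleneck node set with roles and induced subgraph."""

    members: frozenset[str]
    roles: dict[str, str]  # node -> "hub" | "bottleneck" | "both"
    induced_edges: frozenset[tuple[str, str]]
    degree_cutoff_rank: int
    bc_cutoff_rank: int
    source_network_size: int

    @property
    def hubs(self) -> frozenset[str]:
        return frozenset(v for v, r in self.roles.items() if r in ("hub", "both"))

    @property
    def bottlenecks(self) -> frozenset[str]:
        return frozenset(v for v, r in self.roles.items() if r in ("bottleneck", "both"))

    def induced_subgraph(self) -> nx.Graph:
        graph = nx.Graph()
        graph.add_nodes_from(sorted(self.members))
        graph.add_edges_from(sorted(self.induced_edges))
        return graph


def select_top_fraction(
    metrics: Sequence[NodeMetrics],
    key: str,
    fraction: float = DEFAULT_FRACTION,
    target_count: int | None = None,
) -> frozenset[str]:
    """Nodes in the top ``fraction`` of the ``key`` ranking, ties included.

    ``key`` is ``"degree"`` or ``"betweenness"``.  The target count is
    ``max(1, floor(fraction * N))`` unless ``target_count`` overrides it;
    all nodes whose value ties the cutoff value are returned, so the set
    may exceed the target.
    """
    if not metrics:
        raise DataError("cannot select from an empty metric table")
    if key not in ("degree", "betweenness"):
        raise DataError(f"ranking key must be 'degree' or 'betweenness', got {key!r}")
    if target_count is None:
        if not 0.0 < fraction <= 1.0:
            raise DataError(f"fraction must be in (0, 1]: {fraction}")
        target_count = max(1, int(fraction * len(metrics)))
    values = sorted((getattr(m, key) for m in metrics), reverse=True)
    cutoff = values[min(target_count, len(values)) - 1]
    return frozenset(m.node for m in metrics if getattr(m, key) >= cutoff)


def extract_backbone(
    network: nx.Graph,
    metrics: Sequence[NodeMetrics] | None = None,
    fraction: float = DEFAULT_FRACTION,
    target_count: int | None = None,
) -> Backbone:
    """Union of top-fraction hubs and bottlenecks with the induced subgraph."""
    if metrics is None:
        metrics = compute_node_metrics(network)
    hubs = select_top_fraction(metrics, "degree", fraction, target_count)
    bottlenecks = select_top_fraction(metrics, "betweenness", fraction, target_count)
    members = hubs | bottlenecks
    roles = {
        v: ("both" if v in hubs and v in bottlenecks else "hub" if v in hubs else "bottleneck")
        for v in members
    }
    induced = frozenset(
        tuple(sorted((a, b))) for a, b in network.subgraph(members).edges
    )
    n = len(metrics)
    target = target_count if target_count is not None else max(1, int(fraction * n))
    return Backbone(
        members=frozenset(members),
        roles=roles,
        induced_edges=induced,
        degree_cutoff_rank=target,
        bc_cutoff_rank=target,
        source_network_size=n,
    )


def second_extension(
    backbone_members: Iterable[str],
    interactions: Sequence[ScoredInteraction],
    channels: Iterable[str],
    threshold: float = DEFAULT_THRESHOLD,
    prior: float = DEFAULT_PRIOR,
) -> nx.Graph:
    """Re-expand the backbone by one interaction shell under the same filter.

    The node set is the backbone members plus every first neighbour they
    reach through interactions passing the channel/threshold filter; the
    edge set is all qualifying edges among the collected nodes.  Members
    with no qualifying neighbour appear isolated (logged).
    """
    members = set(backbone_members)
    if not members:
        raise DataError("second extension needs a non-empty backbone")
    table_proteins = {p for it in interactions for p in it.pair}
    if not members & table_proteins:
        raise DataError(
            "no backbone member appears in the supplied interaction table"
        )
    passing = filter_interactions(interactions, channels, threshold, prior)
    nodes = set(members)
    for it in passing:
        if it.protein_a in members or it.protein_b in members:
            nodes.update(it.pair)
    qualifying = [it for it in passing if it.protein_a in nodes and it.protein_b in nodes]
    graph = build_network(qualifying)
    isolated = sorted(members - set(graph.nodes))
    graph.add_nodes_from(isolated)
    if isolated:
        logger.info("second extension: %d isolated backbone member(s): %s",
                    len(isolated), ", ".join(isolated))
    # rebuild for deterministic (lexicographic) node order after adding isolates
    out = nx.Graph()
    out.add_nodes_from(sorted(graph.nodes))
    for a, b, attrs in sorted(graph.edges(data=True), key=lambda e: tuple(sorted(e[:2]))):
        out.add_edge(a, b, **attrs)
    return out


@dataclass(frozen=True)
class BackboneComparison:
    """Robustness comparison of two backbones (e.g. with/without coexpression)."""

    common: tuple[str, ...]
    only_a: tuple[str, ...]
    only_b: tuple[str, ...]
    structure_equal: bool
    differing_edges: tuple[tuple[str, str], ...]
    vacuous: bool  # no common members, so structure equality holds trivially

    def to_dict(self) -> dict:
        return {
            "n_common": len(self.common),
            "common": list(self.common),
            "only_a": list(self.only_a),
            "only_b": list(self.only_b),
            "structure_equal": self.structure_equal,
            "differing_edges": [list(e) for e in self.differing_edges],
            "vacuous": self.vacuous,
        }


def compare_backbones(a: Backbone, b: Backbone) -> BackboneComparison:
    """Common members and labeled-edge-set equality of the common subnetwork.

    The two induced subgraphs are restricted to the common member set and
    compared as labeled edge sets; ``differing_edges`` lists the symmetric
    difference.  With no common members the comparison is vacuously equal
    and flagged as such.
    """
    common = a.members & b.members
    edges_a = {e for e in a.induced_edges if e[0] in common and e[1] in common}
    edges_b = {e for e in b.induced_edges if e[0] in common and e[1] in common}
    diff = edges_a ^ edges_b
    return BackboneComparison(
        common=tuple(sorted(common)),
        only_a=tuple(sorted(a.members - b.members)),
        only_b=tuple(sorted(b.members - a.members)),
        structure_equal=not diff,
        differing_edges=tuple(sorted(diff)),
        vacuous=not common,
    )
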