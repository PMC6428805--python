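"""Gene-set membership annotation of network nodes.

Annotation is a pure set intersection between node identifiers and gene
sets (e.g. KEGG addiction pathways read from GMT).  Matching is exact,
case-sensitive string equality by default; no enrichment statistics are
computed — only membership is reported.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .io import GeneSet


def _node_labels(network: nx.Graph | Iterable[str]) -> list[str]:
    if isinstance(network, nx.Graph):
        return list(network.nodes)
    return list(network)


def annotate(
    network: nx.Graph | Iterable[str],
    gene_sets: Sequence[GeneSet],
    case_insensitive: bool = False,
) -> dict[str, list[str]]:
    """Map each gene-set id to the sorted list of member nodes.

    A node may belong to several sets and then appears in each list.
    Empty overlaps are reported as empty lists, never dropped.
    """
    nodes = _node_labels(network)
    out: dict[str, list[str]] = {}
    for gs in gene_sets:
        if case_insensitive:
            members = {m.lower() for m in gs.members}
            hits = [v for v in nodes if v.lower() in members]
        else:
            hits = [v for v in nodes if v in gs.members]
        out[gs.set_id] = sorted(hits)
    return out


def overlap_table(annotations: dict[str, list[str]]) -> pd.DataFrame:
    """One row per gene set: (set_id, count, comma-joined sorted members)."""
    rows = [
        {"set_id": set_id, "count": len(members), "members": ",".join(sorted(members))}
        for set_id, members in annotations.items()
    ]
    return pd.DataFrame(rows, columns=["set_id", "count", "members"])


def attach_membership_attribute(
    network: nx.Graph,
    gene_sets: Sequence[GeneSet],
    attribute: str = "gene_sets",
) -> nx.Graph:
    """Write per-node categorical membership, multi-membership joined with '|'.

    Mutates and returns ``network``; intended for GraphML export so graph
    viewers can colour nodes by set.
    """
    annotations = annotate(network, gene_sets)
    membership: dict[str, list[str]] = {v: [] for v in network.nodes}
    for set_id in sorted(annotations):
        for v in annotations[set_id]:
            membership[v].append(set_id)
    nx.set_node_attributes(
        network, {v: "|".join(ids) for v, ids in membership.items()}, attribute
    )
    return network
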