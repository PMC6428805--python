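"""Readers and writers for every external format the pipeline touches.

Supported formats:

* STRING-dialect scored interaction tables (tab- or whitespace-separated,
  raw per-channel scores as integers 0-999),
* plain two-column edge lists with an optional combined-score column,
* GMT gene-set files,
* per-node metric tables (TSV),
* graph exports (GraphML via networkx, or a plain edge TSV).

Protein identifiers are opaque, case-sensitive strings.  An optional flag
strips STRING species prefixes of the form ``"9606."``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .errors import DataError

logger = logging.getLogger(__name__)

#: Canonical evidence-channel names, in STRING column order.
CHANNELS: tuple[str, ...] = (
    "neighborhood",
    "fusion",
    "cooccurence",
    "coexpression",
    "experimental",
    "database",
    "textmining",
)

#: Accepted spelling variants -> canonical channel name.
CHANNEL_ALIASES: dict[str, str] = {
    "neighbourhood": "neighborhood",
    "cooccurrence": "cooccurence",
    "co-occurrence": "cooccurence",
    "co_occurrence": "cooccurence",
    "coexpression": "coexpression",
    "co-expression": "coexpression",
    "co_expression": "coexpression",
    "experiments": "experimental",
    "experiment": "experimental",
    "experimentally_determined_interaction": "experimental",
    "databases": "database",
    "database_annotated": "database",
    "automated_textmining": "textmining",
}


def normalize_channel(name: str) -> str:
    """Map a channel-name spelling variant to its canonical form.

    Raises :class:`DataError` for names that are not evidence channels.
    """
    key = name.strip().lower()
    key = CHANNEL_ALIASES.get(key, key)
    if key not in CHANNELS:
        raise DataError(f"unknown evidence channel: {name!r}")
    return key


def _strip_prefix(identifier: str) -> str:
    # STRING ids look like "9606.ENSP00000269305"; strip the taxon prefix.
    head, dot, tail = identifier.partition(".")
    if dot and head.isdigit() and tail:
        return tail
    return identifier


@dataclass(frozen=True)
class ScoredInteraction:
    """One candidate edge: an unordered protein pair with per-channel scores.

    Scores live in ``[0, 1]`` (raw STRING integers 0-999 are divided by
    1000 at parse time).  The pair is stored in lexicographic order so
    ``(a, b)`` and ``(b, a)`` compare equal.
    """

    protein_a: str
    protein_b: str
    channel_scores: Mapping[str, float] = field(default_factory=dict)
    combined_score: float = 0.0

    def __post_init__(self) -> None:
        if self.protein_a == self.protein_b:
            raise ValueError(f"self-interaction not allowed: {self.protein_a!r}")
        if self.protein_a > self.protein_b:
            a, b = self.protein_b, self.protein_a
            object.__setattr__(self, "protein_a", a)
            object.__setattr__(self, "protein_b", b)
        for channel, score in self.channel_scores.items():
            if channel not in CHANNELS:
                raise ValueError(f"unknown channel {channel!r}")
            if not 0.0 <= score <= 1.0:
                raise ValueError(f"score out of [0,1] for {channel}: {score}")
        if not 0.0 <= self.combined_score <= 1.0:
            raise ValueError(f"combined score out of [0,1]: {self.combined_score}")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.protein_a, self.protein_b)

    def score(self, channel: str) -> float:
        return self.channel_scores.get(channel, 0.0)


@dataclass(frozen=True)
class GeneSet:
    """A named gene set (e.g. one KEGG pathway) as read from a GMT line."""

    set_id: str
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.set_id!r} has no members")


def _split_row(line: str) -> list[str]:
    return line.split("\t") if "\t" in line else line.split()


def _merge(a: ScoredInteraction, b: ScoredInteraction) -> ScoredInteraction:
    """Merge duplicate unordered pairs by per-channel maximum."""
    scores = dict(a.channel_scores)
    for channel, score in b.channel_scores.items():
        scores[channel] = max(scores.get(channel, 0.0), score)
    return ScoredInteraction(
        a.protein_a,
        a.protein_b,
        channel_scores=scores,
        combined_score=max(a.combined_score, b.combined_score),
    )


def _parse_raw_score(token: str, path: Path, lineno: int) -> float:
    try:
        raw = int(token)
    except ValueError:
        raise DataError(
            f"{path}:{lineno}: expected raw integer score 0-999, got {token!r}"
        ) from None
    if not 0 <= raw <= 1000:
        raise DataError(f"{path}:{lineno}: raw score out of range 0-999: {raw}")
    return raw / 1000.0


def read_interactions(
    path: str | Path,
    dialect: str = "string_tsv",
    strip_species_prefix: bool = False,
) -> list[ScoredInteraction]:
    """Read a scored interaction table.

    ``string_tsv`` expects a header naming two identifier columns followed
    by evidence-channel columns with raw integer scores 0-999 and an
    optional ``combined_score`` column.  ``simple_edge_list`` expects two
    identifier columns and an optional numeric score column already in
    ``[0, 1]`` (used as the combined score).

    Duplicate unordered pairs are merged by per-channel maximum; self-loops
    are dropped and counted in the log.  Unknown columns are ignored with
    a warning; malformed rows raise :class:`DataError` naming the line.
    """
    path = Path(path)
    if dialect not in ("string_tsv", "simple_edge_list"):
        raise DataError(f"unknown dialect: {dialect!r}")
    lines = path.read_text().splitlines()
    rows = [(i + 1, _split_row(ln)) for i, ln in enumerate(lines) if ln.strip()]
    if not rows:
        return []

    header_no, header = rows[0]
    if len(header) < 2:
        raise DataError(f"{path}:{header_no}: header must name at least two identifier columns")
    channel_cols: dict[int, str] = {}
    combined_col: int | None = None
    for idx, col in enumerate(header[2:], start=2):
        key = col.strip().lower()
        if key in ("combined_score", "combined", "score"):
            combined_col = idx
            continue
        try:
            channel_cols[idx] = normalize_channel(col)
        except DataError:
            logger.warning("%s: ignoring unknown column %r", path, col)

    merged: dict[tuple[str, str], ScoredInteraction] = {}
    n_self_loops = 0
    for lineno, row in rows[1:]:
        if len(row) != len(header):
            raise DataError(
                f"{path}:{lineno}: expected {len(header)} fields, got {len(row)}"
            )
        a, b = row[0], row[1]
        if strip_species_prefix:
            a, b = _strip_prefix(a), _strip_prefix(b)
        if a == b:
            n_self_loops += 1
            continue
        if dialect == "string_tsv":
            scores = {
                name: _parse_raw_score(row[idx], path, lineno)
                for idx, name in channel_cols.items()
            }
            combined = (
                _parse_raw_score(row[combined_col], path, lineno)
                if combined_col is not None
                else 0.0
            )
        else:
            scores = {}
            combined = 0.0
            if combined_col is not None:
                try:
                    combined = float(row[combined_col])
                except ValueError:
                    raise DataError(
                        f"{path}:{lineno}: bad score {row[combined_col]!r}"
                    ) from None
                if not 0.0 <= combined <= 1.0:
                    raise DataError(f"{path}:{lineno}: score out of [0,1]: {combined}")
        interaction = ScoredInteraction(a, b, channel_scores=scores, combined_score=combined)
        key = interaction.pair
        merged[key] = _merge(merged[key], interaction) if key in merged else interaction

    if n_self_loops:
        logger.info("%s: dropped %d self-loop row(s)", path, n_self_loops)
    return [merged[key] for key in sorted(merged)]


def write_interactions(interactions: Iterable[ScoredInteraction], path: str | Path) -> Path:
    """Write interactions in the canonical STRING TSV dialect (raw 0-999 scores)."""
    path = Path(path)
    header = ["protein1", "protein2", *CHANNELS, "combined_score"]
    out = ["\t".join(header)]
    for it in sorted(interactions, key=lambda i: i.pair):
        raw = [str(round(it.score(c) * 1000)) for c in CHANNELS]
        out.append("\t".join([it.protein_a, it.protein_b, *raw,
                              str(round(it.combined_score * 1000))]))
    path.write_text("\n".join(out) + "\n")
    return path


def read_gene_sets(path: str | Path) -> list[GeneSet]:
    """Read gene sets from a GMT file (set id, description, members...)."""
    path = Path(path)
    sets: list[GeneSet] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise DataError(f"{path}:{lineno}: GMT line needs id, description and >=1 member")
        members = frozenset(m for m in fields[2:] if m)
        if not members:
            raise DataError(f"{path}:{lineno}: gene set {fields[0]!r} has no members")
        sets.append(GeneSet(set_id=fields[0], name=fields[1], members=members))
    return sets


def write_gene_sets(gene_sets: Iterable[GeneSet], path: str | Path) -> Path:
    path = Path(path)
    lines = [
        "\t".join([gs.set_id, gs.name, *sorted(gs.members)]) for gs in gene_sets
    ]
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    return path


#: Fixed column order of the node-metric table.
METRIC_COLUMNS = (
    "node", "degree", "betweenness", "closeness", "eigenvector",
    "eccentricity", "clustering",
)


def write_node_metrics(metrics: Sequence, path: str | Path) -> Path:
    """Write per-node metrics as a TSV, floats at 9 decimal places.

    ``metrics`` is a sequence of :class:`ppinet.topology.NodeMetrics`.
    """
    if not metrics:
        raise DataError("refusing to write an empty metric table")
    path = Path(path)
    out = ["\t".join(METRIC_COLUMNS)]
    for m in metrics:
        out.append(
            "\t".join(
                [
                    m.node,
                    str(m.degree),
                    f"{m.betweenness:.9f}",
                    f"{m.closeness:.9f}",
                    f"{m.eigenvector:.9f}",
                    str(m.eccentricity),
                    f"{m.clustering:.9f}",
                ]
            )
        )
    path.write_text("\n".join(out) + "\n")
    return path


def read_node_metrics(path: str | Path) -> list:
    """Read a node-metric TSV written by :func:`write_node_metrics`."""
    from .topology import NodeMetrics  # local import: avoid cycle

    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines or tuple(lines[0].split("\t")) != METRIC_COLUMNS:
        raise DataError(f"{path}: not a node-metric table")
    result = []
    for lineno, line in enumerate(lines[1:], start=2):
        f = line.split("\t")
        if len(f) != len(METRIC_COLUMNS):
            raise DataError(f"{path}:{lineno}: expected {len(METRIC_COLUMNS)} fields")
        result.append(
            NodeMetrics(
                node=f[0], degree=int(f[1]), betweenness=float(f[2]),
                closeness=float(f[3]), eigenvector=float(f[4]),
                eccentricity=int(f[5]), clustering=float(f[6]),
            )
        )
    return result


def write_graph(network: nx.Graph, path: str | Path, format: str = "graphml") -> Path:
    """Export a network as GraphML or a plain edge TSV.

    Node labels and the edge set are preserved exactly; re-reading yields
    an identically labeled graph.  Empty graphs are refused.
    """
    path = Path(path)
    if network.number_of_nodes() == 0:
        raise DataError("refusing to write an empty graph")
    if format == "graphml":
        nx.write_graphml(network, path, named_key_ids=True)
    elif format == "edge_tsv":
        out = ["node1\tnode2"]
        out += [f"{a}\t{b}" for a, b in sorted(tuple(sorted(e)) for e in network.edges)]
        isolated = sorted(n for n in network.nodes if network.degree(n) == 0)
        out += [f"{n}\t" for n in isolated]
        path.write_text("\n".join(out) + "\n")
    else:
        raise DataError(f"unknown graph format: {format!r}")
    return path


def read_graph(path: str | Path, format: str = "graphml") -> nx.Graph:
    """Read a graph written by :func:`write_graph`."""
    path = Path(path)
    if format == "graphml":
        return nx.read_graphml(path, node_type=str)
    if format == "edge_tsv":
        graph = nx.Graph()
        lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
        for line in lines[1:]:
            fields = line.split("\t")
            if len(fields) >= 2 and fields[1]:
                graph.add_edge(fields[0], fields[1])
            else:
                graph.add_node(fields[0])
        return graph
    raise DataError(f"unknown graph format: {format!r}")
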