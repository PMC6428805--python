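"""Synthetic STRING-like interaction tables with known ground truth.

The generator emulates the regime of a high-confidence PPI subnetwork
around a set of seed proteins: a scale-free, highly clustered graph whose
edges carry per-evidence-channel confidence scores, such that filtering
on {experimental, database} at 0.90 yields a connected core, and adding
the coexpression channel recovers strictly more edges.

Topology: growth by preferential attachment from an initial clique on the
seed proteins, with a triad-closure step on each extra link (a new node's
later links copy a neighbour of an earlier target with probability
``triad_closure``) plus post-hoc closure rounds to push the average local
clustering into the observed high-clustering / short-path regime.
Designated "planted hub" nodes enter the growth early and receive a
multiplicative boost of their attachment mass, so they end up in the top
of the degree ranking — the recoverable ground truth for the backbone
parameter-recovery tests.

Scores: true edges draw experimental and database scores from a high Beta
distribution; a fraction ``coexpression_extra_density`` of true edges is
instead supported only by coexpression (high Beta on that channel), which
is what makes the with-coexpression channel setting strictly more
inclusive.  Spurious non-edges receive textmining/coexpression-only
scores from a low Beta, so they never pass a 0.90 threshold on any
analysed channel set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np

from .errors import ConfigError
from .io import ScoredInteraction, write_interactions
from .construct import DEFAULT_PRIOR, combine_scores


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic replicate.

    Defaults target a ~111-protein giant component grown around 13 seed
    proteins, matching the scale of a high-confidence STRING query on a
    gene-biosignature list.
    """

    n_proteins: int = 111
    attachment_m: int = 4
    n_seeds: int = 13
    n_planted_hubs: int = 3
    hub_boost: float = 10.0
    triad_closure: float = 0.9
    closure_rounds: int = 450
    score_params: dict = field(
        default_factory=lambda: {"true": (45.0, 2.0), "spurious": (2.0, 8.0)}
    )
    coexpression_extra_density: float = 0.10
    spurious_fraction: float = 0.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_seeds < 1:
            raise ConfigError("n_seeds must be >= 1")
        if self.attachment_m < 1:
            raise ConfigError("attachment_m must be >= 1")
        if self.n_proteins < self.n_seeds + self.n_planted_hubs:
            raise ConfigError(
                "n_proteins must be >= n_seeds + n_planted_hubs "
                f"({self.n_proteins} < {self.n_seeds} + {self.n_planted_hubs})"
            )
        for name, (a, b) in self.score_params.items():
            if a <= 0 or b <= 0:
                raise ConfigError(f"Beta parameters for {name!r} must be > 0")
        if not 0.0 <= self.coexpression_extra_density <= 1.0:
            raise ConfigError("coexpression_extra_density must be in [0, 1]")

    def node_names(self) -> list[str]:
        seeds = [f"SEED{i:02d}" for i in range(1, self.n_seeds + 1)]
        hubs = [f"HUB{i:02d}" for i in range(1, self.n_planted_hubs + 1)]
        rest = [
            f"P{i:04d}"
            for i in range(1, self.n_proteins - self.n_seeds - self.n_planted_hubs + 1)
        ]
        return seeds + hubs + rest

    @property
    def seed_proteins(self) -> list[str]:
        return self.node_names()[: self.n_seeds]

    @property
    def planted_hubs(self) -> list[str]:
        return self.node_names()[self.n_seeds : self.n_seeds + self.n_planted_hubs]


def generate_topology(config: SynthConfig, rng: np.random.Generator | None = None) -> nx.Graph:
    """Grow the ground-truth interaction graph; deterministic under the seed."""
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    names = config.node_names()
    boosted = set(config.planted_hubs)

    graph = nx.Graph()
    seeds = names[: config.n_seeds]
    graph.add_nodes_from(seeds)
    graph.add_edges_from(
        (seeds[i], seeds[j]) for i in range(len(seeds)) for j in range(i + 1, len(seeds))
    )

    def weight(v: str) -> float:
        # planted hubs carry extra attachment mass: a multiplicative boost on
        # degree plus a floor term, so a hub stays attractive even when it lags
        w = max(graph.degree(v), 1)
        return (w + 10.0) * config.hub_boost if v in boosted else w

    for new in names[config.n_seeds :]:
        if new in boosted:
            # planted hubs enter attached to the whole seed clique, emulating
            # a protein that interacts with the entire query module
            graph.add_node(new)
            graph.add_edges_from((new, s) for s in seeds)
            continue
        existing = list(graph.nodes)
        m = min(config.attachment_m, len(existing))
        weights = np.array([weight(v) for v in existing])
        targets: list[str] = []
        while len(targets) < m:
            if targets and rng.random() < config.triad_closure:
                # triad closure: copy a neighbour of an already-chosen target,
                # picked with the same attachment mass as direct attachment
                anchor = targets[int(rng.integers(len(targets)))]
                candidates = [
                    u for u in graph.neighbors(anchor) if u not in targets and u != new
                ]
                if candidates:
                    w = np.array([weight(v) for v in candidates])
                    targets.append(candidates[int(rng.choice(len(candidates), p=w / w.sum()))])
                    continue
            p = weights / weights.sum()
            pick = existing[int(rng.choice(len(existing), p=p))]
            if pick not in targets:
                targets.append(pick)
        graph.add_node(new)
        graph.add_edges_from((new, t) for t in targets)

    # post-hoc closure: connect random open triads to raise local clustering
    nodes = list(graph.nodes)
    for _ in range(config.closure_rounds):
        v = nodes[int(rng.integers(len(nodes)))]
        nbrs = list(graph.neighbors(v))
        if len(nbrs) < 2:
            continue
        i, j = rng.choice(len(nbrs), size=2, replace=False)
        graph.add_edge(nbrs[int(i)], nbrs[int(j)])

    roles = {v: "protein" for v in graph.nodes}
    roles.update({v: "seed" for v in seeds})
    roles.update({v: "planted_hub" for v in boosted})
    nx.set_node_attributes(graph, roles, "role")
    graph.graph["rng_seed"] = config.rng_seed
    return graph


def generate_scores(
    graph: nx.Graph,
    config: SynthConfig,
    rng: np.random.Generator | None = None,
    prior: float = DEFAULT_PRIOR,
) -> list[ScoredInteraction]:
    """Assign per-channel confidence scores to true edges and spurious pairs."""
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    a_hi, b_hi = config.score_params["true"]
    a_lo, b_lo = config.score_params["spurious"]
    interactions: list[ScoredInteraction] = []

    edges = sorted(tuple(sorted(e)) for e in graph.edges)
    for u, v in edges:
        if rng.random() < config.coexpression_extra_density:
            scores = {"coexpression": float(rng.beta(a_hi, b_hi))}
        else:
            scores = {
                "experimental": float(rng.beta(a_hi, b_hi)),
                "database": float(rng.beta(a_hi, b_hi)),
            }
        interactions.append(_with_combined(u, v, scores, prior))

    n_spurious = int(round(config.spurious_fraction * len(edges)))
    nodes = sorted(graph.nodes)
    edge_set = set(edges)
    spurious: set[tuple[str, str]] = set()
    while len(spurious) < n_spurious:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        pair = tuple(sorted((nodes[int(i)], nodes[int(j)])))
        if pair not in edge_set and pair not in spurious:
            spurious.add(pair)
    for u, v in sorted(spurious):
        scores = {
            "textmining": float(rng.beta(a_lo, b_lo)),
            "coexpression": float(rng.beta(a_lo, b_lo)),
        }
        interactions.append(_with_combined(u, v, scores, prior))
    return interactions


def _with_combined(u: str, v: str, scores: dict[str, float], prior: float) -> ScoredInteraction:
    # quantize to the STRING file resolution so write/read round-trips exactly
    scores = {c: round(s, 3) for c, s in scores.items()}
    it = ScoredInteraction(u, v, channel_scores=scores)
    combined = round(combine_scores(it, scores.keys(), prior=prior), 3)
    return ScoredInteraction(u, v, channel_scores=scores, combined_score=combined)


@dataclass(frozen=True)
class GroundTruth:
    """Machine-readable truth for recovery tests: seeds, hubs, true edges."""

    seed_proteins: tuple[str, ...]
    planted_hubs: tuple[str, ...]
    true_edges: tuple[tuple[str, str], ...]
    rng_seed: int

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps({
            "seed_proteins": list(self.seed_proteins),
            "planted_hubs": list(self.planted_hubs),
            "true_edges": [list(e) for e in self.true_edges],
            "rng_seed": self.rng_seed,
        }, indent=1, sort_keys=True) + "\n")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        data = json.loads(Path(path).read_text())
        return cls(
            seed_proteins=tuple(data["seed_proteins"]),
            planted_hubs=tuple(data["planted_hubs"]),
            true_edges=tuple(tuple(e) for e in data["true_edges"]),
            rng_seed=int(data["rng_seed"]),
        )


def ground_truth(config: SynthConfig, graph: nx.Graph) -> GroundTruth:
    return GroundTruth(
        seed_proteins=tuple(config.seed_proteins),
        planted_hubs=tuple(config.planted_hubs),
        true_edges=tuple(sorted(tuple(sorted(e)) for e in graph.edges)),
        rng_seed=config.rng_seed,
    )


@dataclass(frozen=True)
class SimulationBundle:
    config: SynthConfig
    network: nx.Graph
    interactions: list[ScoredInteraction]
    truth: GroundTruth


def simulate(config: SynthConfig, out_dir: str | Path | None = None) -> SimulationBundle:
    """Run topology + scores on a single RNG stream; optionally write files.

    Writes ``interactions.tsv`` (STRING dialect), ``truth.json`` and
    ``seeds.txt`` when ``out_dir`` is given.
    """
    rng = np.random.default_rng(config.rng_seed)
    graph = generate_topology(config, rng)
    interactions = generate_scores(graph, config, rng)
    truth = ground_truth(config, graph)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_interactions(interactions, out / "interactions.tsv")
        truth.to_json(out / "truth.json")
        (out / "seeds.txt").write_text("\n".join(config.seed_proteins) + "\n")
    return SimulationBundle(config=config, network=graph,
                            interactions=interactions, truth=truth)
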