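"""Signed regulatory network: priors, propagation, pathway ranking.

The network is a directed acyclic graph whose edges carry a sign: ``+`` for
activation, ``-`` for inhibition.  Source nodes (no incoming edges) receive
prior activation probabilities — here, overall structural similarities
clamped to [0, 1].  Probabilities are pushed through the DAG in topological
order under a sign-gated noisy-OR rule: a node activates when at least one
activating parent fires and no inhibiting parent fires, with parents treated
as independent,

    P(v) = prod_{u inhibiting} (1 - P(u)) * (1 - prod_{u activating} (1 - P(u))).

This rule stands in for conditional probability tables, which are never
enumerated for curated signed networks of this kind.  A second, "literal"
mode adds the activator terms and their joint product instead of taking the
union; that sum can exceed one and is clamped (with a logged diagnostic) —
it is provided for comparison only, the union rule is the default.

Candidate pathways are all simple source-to-sink paths; a pathway's
probability is the probability delivered to the sink when only that path's
source is active, which for an all-activating chain is just the source
prior, each inhibiting edge replacing the carried probability by its
complement.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

__all__ = [
    "SignedEdge",
    "RegulatoryNetwork",
    "PathwayScore",
    "NetworkValidationError",
    "build_network",
    "set_priors",
    "propagate",
    "enumerate_paths",
    "path_probability",
    "rank_pathways",
    "posterior_attribution",
    "read_edge_list",
    "read_priors_file",
]

logger = logging.getLogger(__name__)

ACTIVATING = "+"
INHIBITING = "-"


class NetworkValidationError(ValueError):
    """Raised for cycles, unknown endpoints, or missing priors."""


@dataclass(frozen=True)
class SignedEdge:
    source: str
    target: str
    sign: str  # "+" or "-"

    def __post_init__(self) -> None:
        if self.sign not in (ACTIVATING, INHIBITING):
            raise ValueError(f"edge sign must be '+' or '-', got {self.sign!r}")


@dataclass(frozen=True)
class PathwayScore:
    path: tuple[str, ...]
    probability: float


class RegulatoryNetwork:
    """Validated signed DAG with a designated sink and (optional) priors."""

    def __init__(self, graph: nx.DiGraph, sink: str):
        self.graph = graph
        self.sink = sink
        self.priors: dict[str, float] = {}
        self.topological_order: tuple[str, ...] = tuple(
            nx.lexicographical_topological_sort(graph)
        )

    @property
    def sources(self) -> tuple[str, ...]:
        return tuple(sorted(n for n in self.graph.nodes if self.graph.in_degree(n) == 0))

    def parents(self, node: str) -> list[tuple[str, str]]:
        """(parent, sign) pairs, sorted by parent name."""
        return sorted((u, self.graph.edges[u, node]["sign"]) for u in self.graph.predecessors(node))


def build_network(
    nodes: Iterable[str], edges: Iterable[SignedEdge | tuple[str, str, str]], sink: str
) -> RegulatoryNetwork:
    """Validate and assemble the signed DAG.

    Rejects cycles (naming a witness) and edges with endpoints outside the
    node set; warns when the sink is unreachable from every source.
    """
    node_set = set(nodes)
    node_set.add(sink)
    g = nx.DiGraph()
    g.add_nodes_from(sorted(node_set))
    for e in edges:
        if not isinstance(e, SignedEdge):
            e = SignedEdge(*e)
        if e.source not in node_set or e.target not in node_set:
            raise NetworkValidationError(
                f"edge {e.source}->{e.target} references an unknown node"
            )
        g.add_edge(e.source, e.target, sign=e.sign)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        witness = " -> ".join(u for u, _ in cycle) + " -> " + cycle[0][0]
        raise NetworkValidationError(f"network contains a cycle: {witness}")
    net = RegulatoryNetwork(g, sink)
    if not any(nx.has_path(g, s, sink) for s in net.sources if s != sink):
        warnings.warn(f"sink {sink!r} is unreachable from every source", stacklevel=2)
    return net


def set_priors(net: RegulatoryNetwork, scores: Mapping[str, float]) -> RegulatoryNetwork:
    """Assign source priors from similarity scores, clamping to [0, 1].

    Similarity scores can fall outside [0, 1] (the parameter similarities
    are unclamped), so out-of-range scores are clamped and logged.  Every
    source must have a score.
    """
    for s in net.sources:
        if s not in scores:
            raise NetworkValidationError(f"no similarity score for source node {s!r}")
    for s in net.sources:
        raw = float(scores[s])
        clamped = min(1.0, max(0.0, raw))
        if clamped != raw:
            logger.info("prior for %s clamped from %g to %g", s, raw, clamped)
        net.priors[s] = clamped
    return net


def _combine(act: Sequence[float], inh: Sequence[float], mode: str, node: str) -> float:
    gate = 1.0
    for p in inh:
        gate *= 1.0 - p
    if not act:
        return 0.0
    if mode == "union":
        miss = 1.0
        for p in act:
            miss *= 1.0 - p
        return gate * (1.0 - miss)
    # literal: sum the single-activator terms plus the joint term, clamped
    total = sum(act)
    if len(act) >= 2:
        joint = 1.0
        for p in act:
            joint *= p
        total += joint
    total *= gate
    if total > 1.0:
        logger.info("literal-mode probability at %s clamped from %g to 1", node, total)
        total = 1.0
    return total


def propagate(net: RegulatoryNetwork, mode: str = "union") -> dict[str, float]:
    """Node activation probabilities, computed in topological order.

    Sources keep their priors.  ``mode="union"`` is the independent-union
    (noisy-OR) rule with inhibitor gating; ``mode="literal"`` adds the
    activator terms plus their joint product and clamps at 1.
    """
    if mode not in ("union", "literal"):
        raise ValueError(f"mode must be 'union' or 'literal', got {mode!r}")
    sources = set(net.sources)
    missing = sources - set(net.priors)
    if missing:
        raise NetworkValidationError(f"priors not set for sources: {sorted(missing)}")
    prob: dict[str, float] = {}
    for node in net.topological_order:
        if node in sources:
            prob[node] = net.priors[node]
            continue
        act = [prob[u] for u, sign in net.parents(node) if sign == ACTIVATING]
        inh = [prob[u] for u, sign in net.parents(node) if sign == INHIBITING]
        prob[node] = _combine(act, inh, mode, node)
    return prob


def enumerate_paths(net: RegulatoryNetwork) -> list[tuple[str, ...]]:
    """All simple directed source-to-sink paths, lexicographically ordered."""
    paths: list[tuple[str, ...]] = []
    for s in net.sources:
        if s == net.sink:
            continue
        paths.extend(tuple(p) for p in nx.all_simple_paths(net.graph, s, net.sink))
    return sorted(paths)


def path_probability(net: RegulatoryNetwork, path: Sequence[str]) -> float:
    """Probability the path delivers to the sink, in isolation.

    The path's source contributes its prior; each activating edge carries
    the probability forward unchanged (a single firing activator), and each
    inhibiting edge replaces it by the complement.  Always in [0, 1].
    """
    path = tuple(path)
    if len(path) < 1 or path[0] not in net.sources:
        raise NetworkValidationError(f"path must start at a source, got {path}")
    for u, v in itertools.pairwise(path):
        if not net.graph.has_edge(u, v):
            raise NetworkValidationError(f"path uses missing edge {u}->{v}")
    if path[0] not in net.priors:
        raise NetworkValidationError(f"prior not set for source {path[0]!r}")
    p = net.priors[path[0]]
    for u, v in itertools.pairwise(path):
        if net.graph.edges[u, v]["sign"] == INHIBITING:
            p = 1.0 - p
    return p


def rank_pathways(net: RegulatoryNetwork) -> list[PathwayScore]:
    """Score every source-to-sink path and sort descending (ties by path).

    The top entry is the maximum-probability pathway.  Returns an empty list
    (with a warning) when the sink is unreachable.
    """
    paths = enumerate_paths(net)
    if not paths:
        warnings.warn("no source-to-sink paths to rank", stacklevel=2)
        return []
    scored = [PathwayScore(p, path_probability(net, p)) for p in paths]
    return sorted(scored, key=lambda s: (-s.probability, s.path))


def posterior_attribution(net: RegulatoryNetwork, node: str) -> dict[str, float]:
    """Share of a node's activation attributable to each source.

    Bayes-style inversion: each source's contribution is the node's
    activation probability when only that source's prior is kept (all other
    priors zeroed), normalized over sources.  Sums to one whenever any
    source reaches the node; unreachable nodes get an empty distribution.
    """
    if node not in net.graph:
        raise NetworkValidationError(f"unknown node {node!r}")
    contributions: dict[str, float] = {}
    for s in net.sources:
        solo = RegulatoryNetwork(net.graph, net.sink)
        solo.priors = {src: (net.priors[src] if src == s else 0.0) for src in net.sources}
        contributions[s] = propagate(solo)[node]
    total = sum(contributions.values())
    if total == 0.0:
        warnings.warn(f"node {node!r} receives no probability from any source", stacklevel=2)
        return {}
    return {s: c / total for s, c in contributions.items()}


# --- file I/O -------------------------------------------------------------

def read_edge_list(path: str | Path) -> tuple[list[str], list[SignedEdge]]:
    """Read a 3-column TSV edge list: source, target, sign ('+'/'-')."""
    path = Path(path)
    nodes: set[str] = set()
    edges: list[SignedEdge] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise NetworkValidationError(
                f"{path}:{lineno}: expected 'source<TAB>target<TAB>sign', got {line!r}"
            )
        src, dst, sign = (p.strip() for p in parts)
        try:
            edges.append(SignedEdge(src, dst, sign))
        except ValueError as exc:
            raise NetworkValidationError(f"{path}:{lineno}: {exc}") from exc
        nodes.update((src, dst))
    return sorted(nodes), edges


def read_priors_file(path: str | Path) -> dict[str, float]:
    """Read a 2-column TSV of node name and similarity score."""
    path = Path(path)
    scores: dict[str, float] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise NetworkValidationError(
                f"{path}:{lineno}: expected 'node<TAB>score', got {line!r}"
            )
        scores[parts[0].strip()] = float(parts[1])
    return scores
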