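"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is deliberately written as plain loops over Python scalars,
independent of the vectorised implementation under test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from shellsim.bayes_network import RegulatoryNetwork, SignedEdge, build_network, set_priors


def brute_force_mean(coords) -> list[float]:
    n = len(coords)
    out = [0.0, 0.0, 0.0]
    for c in coords:
        for k in range(3):
            out[k] += c[k] / n
    return out


def brute_force_radii(coords, center) -> list[float]:
    return [
        math.sqrt(sum((c[k] - center[k]) ** 2 for k in range(3))) for c in coords
    ]


def brute_force_shell_counts(radii, breakpoints) -> list[int]:
    """Interval membership by explicit comparison, half-open [lo, hi)."""
    edges = [0.0, *breakpoints, math.inf]
    counts = [0] * (len(breakpoints) + 1)
    for r in radii:
        for i in range(len(counts)):
            if edges[i] <= r < edges[i + 1]:
                counts[i] += 1
                break
    return counts


def brute_force_layer_similarity(l1, l2) -> list[float]:
    out = []
    for a, b in zip(l1, l2):
        if a > 0:
            out.append(1.0 - abs(a - b) / a)
        else:
            out.append(1.0 if b == 0 else 0.0)
    return out


def brute_force_layer_weights(l1, l2) -> list[float]:
    n1, n2 = sum(l1), sum(l2)
    return [(a / n1 + b / n2) / 2.0 for a, b in zip(l1, l2)]


def brute_force_density(l1, l2) -> float:
    sims = brute_force_layer_similarity(l1, l2)
    ws = brute_force_layer_weights(l1, l2)
    return sum(w * s for w, s in zip(ws, sims))


def enumerate_activation(net: RegulatoryNetwork) -> dict[str, float]:
    """Exact node activation probabilities by summing over all source states.

    Semantics: a source is active with its prior probability, independently;
    a non-source is active iff at least one activating parent is active and
    no inhibiting parent is active.
    """
    sources = net.sources
    prob = {n: 0.0 for n in net.graph.nodes}
    for states in itertools.product([False, True], repeat=len(sources)):
        p_state = 1.0
        active = {}
        for s, on in zip(sources, states):
            p_state *= net.priors[s] if on else 1.0 - net.priors[s]
            active[s] = on
        for node in net.topological_order:
            if node in active:
                continue
            acts = [active[u] for u, sign in net.parents(node) if sign == "+"]
            inhs = [active[u] for u, sign in net.parents(node) if sign == "-"]
            active[node] = any(acts) and not any(inhs)
        for node, on in active.items():
            if on:
                prob[node] += p_state
    return prob


def brute_force_paths(net: RegulatoryNetwork) -> list[tuple[str, ...]]:
    """All simple source-to-sink paths by recursive DFS."""
    found: list[tuple[str, ...]] = []

    def walk(node, trail):
        if node == net.sink:
            found.append(tuple(trail))
            return
        for nxt in net.graph.successors(node):
            if nxt not in trail:
                walk(nxt, trail + [nxt])

    for s in net.sources:
        if s != net.sink:
            walk(s, [s])
    return sorted(found)


def random_in_tree(rng: np.random.Generator, n_nodes: int = 8):
    """Random signed in-tree directed toward a single sink.

    Every node except the sink gets exactly one outgoing edge toward a
    higher-numbered node, so the underlying undirected graph is a tree and
    any node's parents have disjoint ancestor sets (exact independence).
    Leaves are the sources.
    """
    names = [f"n{i}" for i in range(n_nodes)]
    edges = []
    for i in range(n_nodes - 1):
        j = int(rng.integers(i + 1, n_nodes))
        sign = "-" if rng.random() < 0.3 else "+"
        edges.append(SignedEdge(names[i], names[j], sign))
    net = build_network(names, edges, names[-1])
    priors = {s: float(rng.uniform(0.05, 0.95)) for s in net.sources}
    set_priors(net, priors)
    return net
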