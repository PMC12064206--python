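"""Independent brute-force oracles for the graph metrics and projection.

Everything here is deliberately naive — double loops, breadth-first
search by hand, explicit pair enumeration — so the oracles share no code
path with the package implementations they check.
"""

from __future__ import annotations

import math
from itertools import combinations


def edges_of(graph) -> set[frozenset]:
    return {frozenset((a, b)) for a, b in graph.edges}


def density_oracle(graph) -> float:
    nodes = list(graph.nodes)
    n = len(nodes)
    present = edges_of(graph)
    count = sum(1 for pair in combinations(nodes, 2) if frozenset(pair) in present)
    return count / (n * (n - 1) / 2)


def degrees_oracle(graph) -> dict:
    present = edges_of(graph)
    return {
        v: sum(1 for u in graph.nodes if u != v and frozenset((u, v)) in present)
        for v in graph.nodes
    }


def isolated_oracle(graph) -> list:
    return sorted(str(v) for v, d in degrees_oracle(graph).items() if d == 0)


def inclusiveness_oracle(graph) -> float:
    n = graph.number_of_nodes()
    return (n - len(isolated_oracle(graph))) / n


def bfs_distance(graph, source, target) -> float:
    """Hop distance via hand-rolled BFS; inf when unreachable."""
    if source == target:
        return 0
    present = edges_of(graph)
    frontier, seen, dist = {source}, {source}, 0
    while frontier:
        dist += 1
        frontier = {
            u for v in frontier for u in graph.nodes
            if u not in seen and frozenset((u, v)) in present
        }
        if target in frontier:
            return dist
        seen |= frontier
    return math.inf


def mean_distance_oracle(graph) -> float:
    total, pairs = 0.0, 0
    for a, b in combinations(list(graph.nodes), 2):
        d = bfs_distance(graph, a, b)
        if math.isfinite(d):
            total += d
            pairs += 1
    return total / pairs


def cosine_oracle(columns: dict[str, list[float]]) -> dict[tuple[str, str], float]:
    """Pairwise cosine similarity over named column vectors."""
    out = {}
    for a, b in combinations(sorted(columns), 2):
        xa, xb = columns[a], columns[b]
        dot = sum(p * q for p, q in zip(xa, xb))
        na = math.sqrt(sum(p * p for p in xa))
        nb = math.sqrt(sum(q * q for q in xb))
        out[(a, b)] = dot / (na * nb)
    return out
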