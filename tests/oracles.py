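"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately naive: exact rational arithmetic,
exhaustive enumeration and direct tabulation, kept free of the code paths
they validate.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb


def exact_hypergeom_tail(population: int, successes: int, draws: int, observed: int) -> Fraction:
    """P(X >= observed) by exact rational summation of the pmf."""
    total = comb(population, draws)
    acc = Fraction(0)
    for x in range(observed, min(successes, draws) + 1):
        if draws - x <= population - successes:
            acc += Fraction(comb(successes, x) * comb(population - successes, draws - x), total)
    return acc


def cpm_bruteforce(graph, k: int) -> set[frozenset]:
    """Clique-percolation communities by direct k-subset enumeration.

    Enumerates every k-subset that is a clique, links cliques sharing k-1
    nodes, and floods components with a hand-rolled BFS.
    """
    nodes = sorted(graph.nodes, key=str)
    cliques = [
        frozenset(c)
        for c in itertools.combinations(nodes, k)
        if all(graph.has_edge(a, b) for a, b in itertools.combinations(c, 2))
    ]
    adjacency = {i: [] for i in range(len(cliques))}
    for i, j in itertools.combinations(range(len(cliques)), 2):
        if len(cliques[i] & cliques[j]) >= k - 1:
            adjacency[i].append(j)
            adjacency[j].append(i)
    seen: set[int] = set()
    communities: set[frozenset] = set()
    for start in range(len(cliques)):
        if start in seen:
            continue
        stack, comp = [start], []
        seen.add(start)
        while stack:
            i = stack.pop()
            comp.append(i)
            for j in adjacency[i]:
                if j not in seen:
                    seen.add(j)
                    stack.append(j)
        communities.add(frozenset().union(*(cliques[i] for i in comp)))
    return communities


def logrank_oracle(times_a, events_a, times_b, events_b) -> float:
    """Two-group log-rank chi-square by direct O/E/V tabulation."""
    times_a, events_a = list(times_a), list(events_a)
    times_b, events_b = list(times_b), list(events_b)
    event_times = sorted(
        {t for t, e in zip(times_a + times_b, events_a + events_b) if e == 1}
    )
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        n1 = sum(x >= t for x in times_a)
        n2 = sum(x >= t for x in times_b)
        n = n1 + n2
        d1 = sum(1 for x, e in zip(times_a, events_a) if x == t and e == 1)
        d2 = sum(1 for x, e in zip(times_b, events_b) if x == t and e == 1)
        d = d1 + d2
        if n < 2 or d == 0:
            continue
        o_minus_e += d1 - d * n1 / n
        var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


def betweenness_oracle(graph) -> dict:
    """Normalized betweenness by explicit all-pairs shortest-path enumeration."""
    nodes = sorted(graph.nodes, key=str)
    counts = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = _all_shortest_paths(graph, s, t)
        if not paths:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            counts[v] += through / len(paths)
    n = len(nodes)
    scale = 2.0 / ((n - 1) * (n - 2)) if n > 2 else 1.0
    return {v: c * scale for v, c in counts.items()}


def _all_shortest_paths(graph, s, t) -> list[list]:
    """All shortest s-t paths via hand-rolled BFS levels + DFS back-walk."""
    from collections import deque

    dist = {s: 0}
    preds: dict = {s: []}
    q = deque([s])
    while q:
        u = q.popleft()
        for w in graph.neighbors(u):
            if w not in dist:
                dist[w] = dist[u] + 1
                preds[w] = [u]
                q.append(w)
            elif dist[w] == dist[u] + 1:
                preds[w].append(u)
    if t not in dist:
        return []
    paths: list[list] = []

    def walk(v, acc):
        if v == s:
            paths.append([s] + list(reversed(acc)))
            return
        for p in preds[v]:
            walk(p, acc + [v])

    walk(t, [])
    return paths
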