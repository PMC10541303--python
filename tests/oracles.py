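"""Independent brute-force oracles used by the test suite.

These deliberately avoid networkx/scipy code paths: centralities come from
explicit enumeration of every shortest path, and hypergeometric tail
probabilities from exact rational arithmetic.
"""

from __future__ import annotations

from collections import deque
from fractions import Fraction
from math import comb


def bfs_distances(adj: dict[str, set[str]], source: str) -> dict[str, int]:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def all_shortest_paths(adj: dict[str, set[str]], s: str, t: str) -> list[tuple[str, ...]]:
    """Every shortest s→t path, by exhaustive recursion over the BFS layering."""
    dist = bfs_distances(adj, s)
    if t not in dist:
        return []
    paths: list[tuple[str, ...]] = []

    def walk(node: str, trail: list[str]) -> None:
        if node == s:
            paths.append(tuple(reversed(trail + [s])))
            return
        for prev in adj[node]:
            if dist.get(prev, -1) == dist[node] - 1:
                walk(prev, trail + [node])

    walk(t, [])
    return paths


def brute_centralities(adj: dict[str, set[str]]) -> dict[str, dict[str, float]]:
    """Degree, normalized betweenness and Wasserman–Faust closeness by path
    enumeration. ``adj`` is a symmetric adjacency mapping over all nodes."""
    nodes = sorted(adj)
    n = len(nodes)
    out: dict[str, dict[str, float]] = {}
    pair_paths: dict[tuple[str, str], list[tuple[str, ...]]] = {}
    for i, s in enumerate(nodes):
        for t in nodes[i + 1:]:
            pair_paths[(s, t)] = all_shortest_paths(adj, s, t)
    for v in nodes:
        bc = 0.0
        for (s, t), paths in pair_paths.items():
            if v in (s, t) or not paths:
                continue
            through = sum(1 for p in paths if v in p)
            bc += through / len(paths)
        if n > 2:
            bc /= (n - 1) * (n - 2) / 2
        dist = bfs_distances(adj, v)
        reachable = {u: d for u, d in dist.items() if u != v}
        if reachable and n > 1:
            nc = len(reachable)
            cc = (nc / sum(reachable.values())) * (nc / (n - 1))
        else:
            cc = 0.0
        out[v] = {"degree": len(adj[v]), "betweenness": bc, "closeness": cc}
    return out


def exact_hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> Fraction:
    """P(X >= k) for hypergeometric(N, K, n) in exact rational arithmetic."""
    total = comb(N, n)
    acc = Fraction(0)
    for i in range(k, min(K, n) + 1):
        acc += Fraction(comb(K, i) * comb(N - K, n - i), total)
    return acc


def manual_bh(p_values: list[float]) -> list[float]:
    """Step-up Benjamini–Hochberg computed the long way."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    running = 1.0
    for rank_from_end, idx in enumerate(reversed(order)):
        rank = m - rank_from_end
        running = min(running, p_values[idx] * m / rank)
        q[idx] = running
    return q
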