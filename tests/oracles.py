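"""Independent brute-force oracles used to validate the fast implementations.

These deliberately share no code with dhhkit's algorithms: alignment by
exhaustive path enumeration, motif scanning by all-positions substring test,
UPGMA by a literal re-implementation of the textbook recipe, and tree
distances by path summation.
"""

from __future__ import annotations

import itertools
import math
from typing import Dict, List, Sequence, Tuple


def exhaustive_affine_score(
    a: str,
    b: str,
    score: Dict[Tuple[str, str], float],
    gap_open: float,
    gap_extend: float,
) -> float:
    """Maximum score over every global alignment, enumerated recursively.

    A gap run of length L costs gap_open + (L - 1) * gap_extend.  Feasible for
    lengths <= ~8.
    """
    best = -math.inf

    def recurse(i: int, j: int, state: int, acc: float) -> None:
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, acc)
            return
        if i < len(a) and j < len(b):
            recurse(i + 1, j + 1, 0, acc + score[(a[i], b[j])])
        if i < len(a):
            cost = gap_extend if state == 1 else gap_open
            recurse(i + 1, j, 1, acc - cost)
        if j < len(b):
            cost = gap_extend if state == 2 else gap_open
            recurse(i, j + 1, 2, acc - cost)

    recurse(0, 0, 0, 0.0)
    return best


def brute_force_motif_scan(sequence: str, pattern: str) -> List[int]:
    """1-based start positions of every occurrence, by direct comparison."""
    return [
        i + 1
        for i in range(len(sequence) - len(pattern) + 1)
        if sequence[i : i + len(pattern)] == pattern
    ]


def upgma_merge_trace(
    ids: Sequence[str], dist: Dict[Tuple[str, str], float]
) -> List[Tuple[frozenset, float]]:
    """Textbook UPGMA: returns (merged leaf set, merge height) per step.

    Tie-break: smallest (distance, sorted pair of min-member ids).
    """
    clusters: List[frozenset] = [frozenset([i]) for i in sorted(ids)]
    trace: List[Tuple[frozenset, float]] = []

    def cluster_dist(x: frozenset, y: frozenset) -> float:
        total = sum(dist[(a, b)] if (a, b) in dist else dist[(b, a)]
                    for a in x for b in y)
        return total / (len(x) * len(y))

    while len(clusters) > 1:
        best = None
        for x, y in itertools.combinations(clusters, 2):
            key = (cluster_dist(x, y), tuple(sorted((min(x), min(y)))))
            if best is None or key < best[0]:
                best = (key, x, y)
        (d, _), x, y = best
        merged = x | y
        trace.append((merged, d / 2.0))
        clusters = [c for c in clusters if c not in (x, y)] + [merged]
    return trace


def random_additive_tree(
    n_leaves: int, rng
) -> Tuple[dict, Dict[Tuple[str, str], float]]:
    """Random unrooted binary tree topology with positive branch lengths,
    plus its exact path-sum leaf distance matrix.

    The tree is built by sequential leaf attachment to a random edge; returned
    as {"edges": [(u, v, length)], "leaves": [names]} with internal nodes
    numbered.
    """
    assert n_leaves >= 3
    names = [f"L{i}" for i in range(n_leaves)]
    counter = itertools.count()
    internal = lambda: f"I{next(counter)}"  # noqa: E731

    def blen() -> float:
        return float(rng.uniform(0.1, 2.0))

    hub = internal()
    edges = [(hub, names[0], blen()), (hub, names[1], blen()), (hub, names[2], blen())]
    for leaf in names[3:]:
        idx = int(rng.integers(0, len(edges)))
        u, v, length = edges.pop(idx)
        mid = internal()
        split = float(rng.uniform(0.25, 0.75)) * length
        edges.extend(
            [(u, mid, split), (mid, v, length - split), (mid, leaf, blen())]
        )

    adj: Dict[str, List[Tuple[str, float]]] = {}
    for u, v, w in edges:
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))
    dist: Dict[Tuple[str, str], float] = {}
    for src in names:
        seen = {src: 0.0}
        stack = [src]
        while stack:
            x = stack.pop()
            for y, w in adj[x]:
                if y not in seen:
                    seen[y] = seen[x] + w
                    stack.append(y)
        for dst in names:
            dist[(src, dst)] = seen[dst]
    return {"edges": edges, "leaves": names}, dist


def tree_bipartitions_from_edges(edges, leaves) -> set:
    """Non-trivial splits of an unrooted tree given as an edge list."""
    adj: Dict[str, List[str]] = {}
    for u, v, _ in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    all_leaves = frozenset(leaves)
    anchor = min(all_leaves)
    splits = set()
    for u, v, _ in edges:
        # leaves on v's side of edge (u, v)
        side = set()
        stack = [v]
        seen = {u, v}
        while stack:
            x = stack.pop()
            if x in all_leaves:
                side.add(x)
            for y in adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        side_f = frozenset(side)
        if len(side_f) < 2 or len(all_leaves - side_f) < 2:
            continue
        splits.add(side_f if anchor not in side_f else all_leaves - side_f)
    return splits


def least_squares_line(points) -> Tuple[float, float]:
    """Closed-form normal-equations solution for y = m x + c."""
    n = len(points)
    sx = sum(p[0] for p in points)
    sy = sum(p[1] for p in points)
    sxx = sum(p[0] ** 2 for p in points)
    sxy = sum(p[0] * p[1] for p in points)
    m = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    c = (sy - m * sx) / n
    return m, c
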