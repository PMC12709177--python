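"""Distance matrices, neighbor joining, midpoint rooting, bootstrap, clades.

Neighbor joining on Poisson-corrected distances substitutes for external
maximum-likelihood tree inference; it exactly recovers additive distances and
is the test surface for topology-level behaviour.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .alignment import GAP, Alignment
from .errors import ValidationError
from .tree import Node, PhyloTree, parse_newick, read_newick, write_newick

__all__ = [
    "DistanceMatrix",
    "PhyloConfig",
    "distance_matrix",
    "neighbor_joining",
    "midpoint_root",
    "bootstrap_support",
    "extract_major_clades",
    "parse_newick",
    "read_newick",
    "write_newick",
]

_EPS = 1e-9


@dataclass(frozen=True)
class DistanceMatrix:
    ids: Tuple[str, ...]
    values: np.ndarray
    model: str = "p"

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValidationError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T):
            raise ValidationError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValidationError("distance matrix diagonal must be zero")
        if np.any(v < 0) or not np.all(np.isfinite(v)):
            raise ValidationError("distances must be finite and non-negative")


@dataclass(frozen=True)
class PhyloConfig:
    bootstrap_replicates: int = 1000
    distance_model: str = "poisson"
    clade_min_size: int = 5
    clade_tightness: float = 0.5
    max_distance: float = 10.0

    def __post_init__(self) -> None:
        if self.bootstrap_replicates < 0:
            raise ValidationError("bootstrap_replicates must be >= 0")
        if not 0 < self.clade_tightness < 1:
            raise ValidationError("clade_tightness must be in (0, 1)")


def _pair_arrays(aln: Alignment) -> Tuple[np.ndarray, np.ndarray, List[Tuple[int, int]]]:
    """Per-pair per-column mismatch/comparable boolean matrices."""
    arr = aln.to_array()
    nongap = arr != ord(GAP)
    n = aln.n_rows
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    comp = np.empty((len(pairs), aln.column_count), dtype=bool)
    mism = np.empty_like(comp)
    for k, (i, j) in enumerate(pairs):
        comp[k] = nongap[i] & nongap[j]
        mism[k] = comp[k] & (arr[i] != arr[j])
    return mism, comp, pairs


def _p_to_distance(p: np.ndarray, model: str, max_distance: float) -> np.ndarray:
    if model == "p":
        return p
    if model == "poisson":
        clipped = np.minimum(p, 1.0 - 1e-12)
        return np.minimum(-np.log1p(-clipped), max_distance)
    raise ValidationError(f"unknown distance model {model!r}")


def distance_matrix(
    aln: Alignment, model: str = "poisson", max_distance: float = 10.0
) -> DistanceMatrix:
    """Pairwise-deletion p-distances, optionally Poisson corrected.

    For each pair, p = mismatches / columns where both rows are non-gap.
    ``model="poisson"`` applies d = -ln(1 - p), clamped at ``max_distance``
    when p saturates.  A pair with zero comparable columns is an error.
    """
    if aln.n_rows < 2:
        raise ValidationError("distance matrix requires at least 2 rows")
    mism, comp, pairs = _pair_arrays(aln)
    n_comp = comp.sum(axis=1)
    if np.any(n_comp == 0):
        k = int(np.argmax(n_comp == 0))
        i, j = pairs[k]
        raise ValidationError(
            f"no comparable columns between {aln.row_ids[i]!r} and {aln.row_ids[j]!r}"
        )
    p = mism.sum(axis=1) / n_comp
    d = _p_to_distance(p, model, max_distance)
    n = aln.n_rows
    values = np.zeros((n, n))
    for k, (i, j) in enumerate(pairs):
        values[i, j] = values[j, i] = d[k]
    return DistanceMatrix(tuple(aln.row_ids), values, model)


# -- neighbor joining -------------------------------------------------------


def neighbor_joining(D: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei agglomeration with the Q-criterion.

    Deterministic: at each step the minimal Q entry with the smallest (i, j)
    row-major index is joined.  Negative intermediate branch lengths are
    clamped to zero.  Returns an unrooted tree (trifurcating root).
    """
    n = len(D.ids)
    if n < 3:
        raise ValidationError("neighbor joining requires at least 3 taxa")
    d = D.values.astype(float).copy()
    nodes: List[Node] = [Node(name) for name in D.ids]
    active = list(range(n))

    while len(active) > 3:
        k = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (k - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        iu = np.triu_indices(k, 1)
        Q_masked = np.full_like(Q, np.inf)
        Q_masked[iu] = Q[iu]
        flat = int(np.argmin(Q_masked))
        ai, aj = divmod(flat, k)
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = dij / 2.0 + (r[ai] - r[aj]) / (2.0 * (k - 2))
        lj = dij - li
        li, lj = max(0.0, li), max(0.0, lj)
        parent = Node()
        nodes[i].length = li
        nodes[j].length = lj
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        new = len(nodes)
        nodes.append(parent)
        d = np.pad(d, ((0, 1), (0, 1)))
        for m in active:
            if m in (i, j):
                continue
            dm = max(0.0, (d[i, m] + d[j, m] - dij) / 2.0)
            d[new, m] = d[m, new] = dm
        active = [m for m in active if m not in (i, j)] + [new]

    a, b, c = active
    root = Node()
    la = max(0.0, (d[a, b] + d[a, c] - d[b, c]) / 2.0)
    lb = max(0.0, (d[a, b] + d[b, c] - d[a, c]) / 2.0)
    lc = max(0.0, (d[a, c] + d[b, c] - d[a, b]) / 2.0)
    for idx, length in ((a, la), (b, lb), (c, lc)):
        nodes[idx].length = length
        root.add_child(nodes[idx])
    return PhyloTree(root, rooted=False)


# -- rerooting --------------------------------------------------------------


def _adjacency(tree: PhyloTree):
    """Undirected edge map: node -> [(neighbor, length, support)]."""
    adj: Dict[int, List[Tuple[Node, float, Optional[float]]]] = {}
    nodes = list(tree.preorder())
    for node in nodes:
        adj.setdefault(id(node), [])
    for node in nodes:
        if node.parent is not None:
            adj[id(node.parent)].append((node, node.length, node.support))
            adj[id(node)].append((node.parent, node.length, node.support))
    return adj, nodes


def _rebuild_from(
    start: Node,
    adj,
    *,
    pre_root: Optional[List[Tuple[Node, float, Optional[float], float]]] = None,
) -> Node:
    """Re-orient the tree from ``start`` (or from a fresh node splitting an
    edge when ``pre_root`` is given as [(neighbor, total_len, support, len)])."""
    new_root = Node()
    stack: List[Tuple[Node, Optional[Node], Node]] = []
    if pre_root is None:
        new_root.name = start.name if start.is_leaf else None
        new_root.support = None
        for nbr, length, support in adj[id(start)]:
            stack.append((nbr, start, _attach(new_root, nbr, length, support)))
    else:
        for nbr, _total, support, length in pre_root:
            stack.append((nbr, None, _attach(new_root, nbr, length, support)))
    while stack:
        old, came_from, new = stack.pop()
        for nbr, length, support in adj[id(old)]:
            if nbr is came_from or (came_from is None and _is_pre_root_nbr(nbr, pre_root, old)):
                continue
            stack.append((nbr, old, _attach(new, nbr, length, support)))
    return new_root


def _is_pre_root_nbr(nbr, pre_root, old) -> bool:
    if pre_root is None:
        return False
    partners = {id(p[0]) for p in pre_root}
    return id(nbr) in partners and id(old) in partners


def _attach(parent: Node, old: Node, length: float, support: Optional[float]) -> Node:
    child = Node(old.name if old.is_leaf else None, length, None if old.is_leaf else support)
    parent.add_child(child)
    return child


def midpoint_root(tree: PhyloTree) -> PhyloTree:
    """Root at the midpoint of the longest leaf-to-leaf path.

    Ties between equally long paths are broken by lexicographic leaf-pair
    order.  When the midpoint coincides with an existing internal node the
    tree is rooted there without inserting a zero-length edge.  An all-zero
    branch-length tree roots at the first internal node with a warning.
    """
    leaves = sorted(tree.leaves(), key=lambda n: n.name)
    if len(leaves) < 2:
        raise ValidationError("midpoint rooting requires at least 2 leaves")
    adj, nodes = _adjacency(tree)

    # single DFS per leaf: distances + predecessor chains
    best: Tuple[float, Tuple[str, str]] = (-1.0, ("", ""))
    best_path: List[Node] = []
    by_name = {l.name: l for l in leaves}
    for u in leaves:
        dist: Dict[int, float] = {id(u): 0.0}
        pred: Dict[int, Node] = {}
        stack = [u]
        while stack:
            x = stack.pop()
            for y, w, _s in adj[id(x)]:
                if id(y) not in dist:
                    dist[id(y)] = dist[id(x)] + w
                    pred[id(y)] = x
                    stack.append(y)
        for v in leaves:
            if v.name <= u.name:
                continue
            d = dist[id(v)]
            if d > best[0] + 1e-15:
                path = [v]
                while path[-1] is not u:
                    path.append(pred[id(path[-1])])
                best = (d, (u.name, v.name))
                best_path = list(reversed(path))
    total = best[0]
    if total <= 0:
        warnings.warn("all branch lengths are zero; rooting at first internal node")
        first_internal = next(n for n in tree.preorder() if not n.is_leaf)
        return PhyloTree(_rebuild_from(first_internal, adj), rooted=True)

    half = total / 2.0
    cum = 0.0
    for a, b in zip(best_path, best_path[1:]):
        length = support = None
        for nbr, w, s in adj[id(a)]:
            if nbr is b:
                length, support = w, s
                break
        if abs(cum - half) <= _EPS and not a.is_leaf:
            return PhyloTree(_rebuild_from(a, adj), rooted=True)
        if cum + length >= half - _EPS:
            if abs(cum + length - half) <= _EPS and not b.is_leaf:
                return PhyloTree(_rebuild_from(b, adj), rooted=True)
            offset = half - cum
            pre_root = [
                (a, length, support, offset),
                (b, length, support, length - offset),
            ]
            return PhyloTree(_rebuild_from(a, adj, pre_root=pre_root), rooted=True)
        cum += length
    raise AssertionError("midpoint not found on path")  # pragma: no cover


# -- bootstrap --------------------------------------------------------------


def bootstrap_support(
    aln: Alignment, config: PhyloConfig = PhyloConfig(), seed: int = 0
) -> PhyloTree:
    """NJ tree with bipartition bootstrap supports from column resampling.

    Supports are recovery fractions in [0, 1] attached to internal edges of
    the tree built from the full alignment; seeded and reproducible.  With
    zero replicates the tree is returned without supports.
    """
    if aln.n_rows < 4:
        raise ValidationError("bootstrap requires at least 4 rows")
    D = distance_matrix(aln, config.distance_model, config.max_distance)
    tree = neighbor_joining(D)
    if config.bootstrap_replicates == 0:
        return tree
    mism, comp, pairs = _pair_arrays(aln)
    n = aln.n_rows
    rng = np.random.default_rng(seed)
    counts: Dict[frozenset, int] = {key: 0 for key in tree.bipartitions()}
    for _ in range(config.bootstrap_replicates):
        idx = rng.integers(0, aln.column_count, aln.column_count)
        m = mism[:, idx].sum(axis=1)
        c = comp[:, idx].sum(axis=1)
        with np.errstate(invalid="ignore"):
            p = np.where(c > 0, m / np.maximum(c, 1), 1.0 - 1e-12)
        d = _p_to_distance(p, config.distance_model, config.max_distance)
        values = np.zeros((n, n))
        for k, (i, j) in enumerate(pairs):
            values[i, j] = values[j, i] = d[k]
        rep_tree = neighbor_joining(
            DistanceMatrix(tuple(aln.row_ids), values, config.distance_model)
        )
        rep_splits = set(rep_tree.bipartitions())
        for key in counts:
            if key in rep_splits:
                counts[key] += 1
    for key, node in tree.bipartitions().items():
        node.support = counts[key] / config.bootstrap_replicates
    return tree


# -- major clades -----------------------------------------------------------


def extract_major_clades(
    tree: PhyloTree, config: PhyloConfig = PhyloConfig()
) -> List[Set[str]]:
    """Report maximal tight subtrees as major clades.

    Depth-first from the root, a node is reported when its subtree holds at
    least ``clade_min_size`` leaves and the mean pairwise leaf path length
    within the subtree is at most ``clade_tightness`` times the whole-tree
    mean; descendants of reported nodes are skipped, so reported sets are
    disjoint.
    """
    if not tree.rooted:
        raise ValidationError("major-clade extraction requires a rooted tree")
    names, dist = tree.leaf_distance_matrix()
    if len(names) < 2:
        return []

    def mean_pairwise(members: Sequence[str]) -> float:
        if len(members) < 2:
            return 0.0
        total = 0.0
        count = 0
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                total += dist[(a, b)]
                count += 1
        return total / count

    overall = mean_pairwise(names)
    threshold = config.clade_tightness * overall
    clades: List[Set[str]] = []
    stack = [tree.root]
    while stack:
        node = stack.pop()
        members = sorted(
            leaf.name for leaf in (n for n in _subtree(node) if n.is_leaf)
        )
        if len(members) >= config.clade_min_size and mean_pairwise(members) <= threshold:
            clades.append(set(members))
            continue
        stack.extend(reversed(node.children))
    return clades


def _subtree(node: Node):
    stack = [node]
    while stack:
        n = stack.pop()
        yield n
        stack.extend(n.children)
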