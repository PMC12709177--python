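"""Minimal phylogenetic tree structure with Newick round-trip.

A deliberately small, dependency-free tree: nodes carry parent/children
links, non-negative branch lengths, leaf names and optional support values on
internal edges (stored on the child node).  Determinism of every algorithm
that walks these trees matters more here than feature breadth, which is why
this is hand-rolled rather than delegated to a heavier library.
"""

from __future__ import annotations

from typing import Dict, Iterator, List, Optional, Tuple

from .errors import ParseError, ValidationError


class Node:
    __slots__ = ("name", "length", "support", "children", "parent")

    def __init__(
        self,
        name: Optional[str] = None,
        length: float = 0.0,
        support: Optional[float] = None,
    ) -> None:
        self.name = name
        self.length = length
        self.support = support
        self.children: List["Node"] = []
        self.parent: Optional["Node"] = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover
        return f"Node({self.name!r}, len={self.length}, children={len(self.children)})"


class PhyloTree:
    """A (possibly unrooted) tree.

    An unrooted tree is stored rooted at an arbitrary internal node (a
    trifurcation for trees built by neighbor joining); ``rooted`` records
    whether the root placement is meaningful.
    """

    def __init__(self, root: Node, rooted: bool = False) -> None:
        self.root = root
        self.rooted = rooted
        names = [leaf.name for leaf in self.leaves() if leaf.name is not None]
        if len(names) != len(set(names)):
            raise ValidationError("duplicate leaf labels in tree")

    # -- traversal -----------------------------------------------------

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out: List[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def leaves(self) -> List[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_names(self) -> List[str]:
        return [n.name for n in self.leaves()]

    def internal_edges(self) -> List[Node]:
        """Child nodes of internal (non-trivial) edges."""
        return [
            n
            for n in self.preorder()
            if n.parent is not None and not n.is_leaf
        ]

    # -- leaf-to-leaf path lengths ------------------------------------

    def leaf_distance_matrix(self) -> Tuple[List[str], Dict[Tuple[str, str], float]]:
        """All-pairs leaf path lengths (sum of branch lengths), by leaf name."""
        leaves = sorted(self.leaves(), key=lambda n: n.name)
        names = [l.name for l in leaves]
        # depth of every node from root, plus Euler walk for LCA-free approach:
        # trees here are small, so just do a DFS from each leaf over adjacency.
        adj: Dict[int, List[Tuple[int, float]]] = {}
        nodes = list(self.preorder())
        index = {id(n): i for i, n in enumerate(nodes)}
        for n in nodes:
            adj.setdefault(index[id(n)], [])
        for n in nodes:
            if n.parent is not None:
                i, j = index[id(n.parent)], index[id(n)]
                adj[i].append((j, n.length))
                adj[j].append((i, n.length))
        leaf_idx = {l.name: index[id(l)] for l in leaves}
        dist: Dict[Tuple[str, str], float] = {}
        for name in names:
            start = leaf_idx[name]
            d = {start: 0.0}
            stack = [start]
            while stack:
                u = stack.pop()
                for v, w in adj[u]:
                    if v not in d:
                        d[v] = d[u] + w
                        stack.append(v)
            for other in names:
                dist[(name, other)] = d[leaf_idx[other]]
        return names, dist

    # -- bipartitions --------------------------------------------------

    def bipartitions(self) -> Dict[frozenset, Node]:
        """Canonical non-trivial splits, mapped to the child node of the edge.

        A split is canonicalized as the side *not* containing the
        lexicographically smallest leaf name.
        """
        all_names = frozenset(self.leaf_names())
        anchor = min(all_names)
        splits: Dict[frozenset, Node] = {}
        below: Dict[int, frozenset] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset([node.name])
            else:
                below[id(node)] = frozenset().union(
                    *(below[id(c)] for c in node.children)
                )
        for node in self.internal_edges():
            side = below[id(node)]
            if len(side) < 2 or len(all_names - side) < 2:
                continue
            key = side if anchor not in side else all_names - side
            splits[key] = node
        return splits

    # -- serialization -------------------------------------------------

    def to_newick(self) -> str:
        return _write_node(self.root) + ";"

    def copy(self) -> "PhyloTree":
        return PhyloTree(_copy_node(self.root), rooted=self.rooted)


def _copy_node(node: Node) -> Node:
    new = Node(node.name, node.length, node.support)
    for child in node.children:
        new.add_child(_copy_node(child))
    return new


def _fmt_len(x: float) -> str:
    s = f"{x:.6f}".rstrip("0").rstrip(".")
    return s if s else "0"


def _write_node(node: Node) -> str:
    if node.is_leaf:
        label = node.name or ""
    else:
        inner = ",".join(_write_node(c) for c in node.children)
        if node.support is not None:
            label = f"({inner}){_fmt_len(node.support)}"
        elif node.name:
            label = f"({inner}){node.name}"
        else:
            label = f"({inner})"
    if node.parent is not None:
        label += f":{_fmt_len(node.length)}"
    return label


def parse_newick(text: str, rooted: Optional[bool] = None) -> PhyloTree:
    """Parse a Newick string; raises :class:`ParseError` with character offset.

    Internal-node labels that parse as numbers are interpreted as support
    values.  ``rooted`` defaults to True when the root is bifurcating.
    """
    parser = _NewickParser(text)
    root = parser.parse()
    if rooted is None:
        rooted = len(root.children) == 2
    return PhyloTree(root, rooted=rooted)


class _NewickParser:
    _SPECIAL = set("(),:;")

    def __init__(self, text: str) -> None:
        self.text = text
        self.pos = 0

    def error(self, message: str) -> ParseError:
        return ParseError(f"newick parse error at offset {self.pos}: {message}")

    def peek(self) -> str:
        self._skip_ws()
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def _skip_ws(self) -> None:
        while self.pos < len(self.text) and self.text[self.pos].isspace():
            self.pos += 1

    def parse(self) -> Node:
        node = self._parse_node()
        if self.peek() != ";":
            raise self.error("expected ';'")
        self.pos += 1
        self._skip_ws()
        if self.pos != len(self.text):
            raise self.error("trailing characters after ';'")
        return node

    def _parse_node(self) -> Node:
        node = Node()
        if self.peek() == "(":
            self.pos += 1
            while True:
                node.add_child(self._parse_node())
                ch = self.peek()
                if ch == ",":
                    self.pos += 1
                    continue
                if ch == ")":
                    self.pos += 1
                    break
                raise self.error("expected ',' or ')'")
            label = self._parse_label()
            if label:
                try:
                    node.support = float(label)
                except ValueError:
                    node.name = label
        else:
            label = self._parse_label()
            if not label:
                raise self.error("expected leaf label")
            node.name = label
        if self.peek() == ":":
            self.pos += 1
            node.length = self._parse_number()
        return node

    def _parse_label(self) -> str:
        self._skip_ws()
        start = self.pos
        while (
            self.pos < len(self.text)
            and not self.text[self.pos].isspace()
            and self.text[self.pos] not in self._SPECIAL
        ):
            self.pos += 1
        return self.text[start : self.pos]

    def _parse_number(self) -> float:
        token = self._parse_label()
        try:
            return float(token)
        except ValueError:
            raise self.error(f"invalid branch length {token!r}") from None


def write_newick(tree: PhyloTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


def read_newick(path) -> PhyloTree:
    with open(path) as fh:
        return parse_newick(fh.read().strip())
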