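"""Unrooted phylogenetic trees: Newick I/O, bipartitions, editing, consensus.

Trees are stored with a rooted parent/child structure for traversal but all
identity and comparison semantics are *unrooted*: two trees are the same
topology iff their non-trivial bipartition (split) sets over the shared leaf
set are equal.  Edges carry stable identifiers derived from the split they
induce, so an edge id survives copying and canonical re-serialization.

Edge identifiers
----------------
The id of an edge is the frozenset of leaf labels on the side of the split
that does NOT contain the reference taxon (the lexicographically smallest
leaf label).  A pendant edge to leaf ``X`` therefore has id ``{X}`` unless
``X`` is the reference taxon, in which case the id is the complement set.
"""

from __future__ import annotations

import io
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import dendropy

EdgeId = FrozenSet[str]

__all__ = [
    "PhyloTree",
    "Node",
    "parse_newick",
    "write_newick",
    "bipartitions",
    "attach_leaf",
    "prune_leaf",
    "strict_consensus",
    "tree_from_splits",
    "same_topology",
]


class Node:
    """A tree node; ``label`` is set for leaves, ``length`` is the branch to the parent."""

    __slots__ = ("label", "children", "parent", "length")

    def __init__(self, label: Optional[str] = None, length: Optional[float] = None):
        self.label = label
        self.children: List["Node"] = []
        self.parent: Optional["Node"] = None
        self.length = length

    def add_child(self, node: "Node") -> "Node":
        node.parent = self
        self.children.append(node)
        return node

    @property
    def is_leaf(self) -> bool:
        return not self.children


class PhyloTree:
    """An unrooted phylogenetic tree with unique leaf labels.

    The internal root is a traversal convenience; a root of degree two is
    suppressed whenever the tree is viewed unrooted (edge enumeration,
    bipartitions, canonical Newick, topology identity).
    """

    def __init__(self, root: Node):
        self.root = root
        self._validate()

    # -- construction / validation -------------------------------------------------

    def _validate(self) -> None:
        seen: Set[str] = set()
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                if node.label is None:
                    raise ValueError("leaf without a label")
                if node.label in seen:
                    raise ValueError(f"duplicate leaf label: {node.label!r}")
                seen.add(node.label)
            stack.extend(node.children)
        if not seen:
            raise ValueError("empty tree")

    def copy(self) -> "PhyloTree":
        def rec(node: Node) -> Node:
            clone = Node(node.label, node.length)
            for child in node.children:
                clone.add_child(rec(child))
            return clone

        return PhyloTree(rec(self.root))

    # -- basic queries -------------------------------------------------------------

    def postorder(self) -> Iterable[Node]:
        stack: List[Tuple[Node, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def leaves(self) -> List[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> FrozenSet[str]:
        return frozenset(n.label for n in self.leaves())

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def reference_taxon(self) -> str:
        return min(self.leaf_labels())

    def is_binary_unrooted(self) -> bool:
        """True iff every node has degree 3 when viewed unrooted (leaves degree 1)."""
        if self.n_leaves < 3:
            return True
        for node in self.postorder():
            if node.is_leaf:
                continue
            degree = len(node.children) + (0 if node.parent is None else 1)
            if node.parent is None:
                # a degree-2 root sits on an edge of the unrooted tree
                if degree not in (2, 3):
                    return False
            elif degree != 3:
                return False
        return True

    # -- edges and splits ----------------------------------------------------------

    def _clades(self) -> Dict[int, Tuple[Node, FrozenSet[str]]]:
        """Map id(node) -> (node, leafset below node) for every non-root node."""
        below: Dict[int, FrozenSet[str]] = {}
        out: Dict[int, Tuple[Node, FrozenSet[str]]] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset([node.label])
            else:
                below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))
            if node.parent is not None:
                out[id(node)] = (node, below[id(node)])
        return out

    def canonical_side(self, side: FrozenSet[str]) -> EdgeId:
        """Orient a split side away from the reference taxon."""
        ref = self.reference_taxon()
        if ref in side:
            return self.leaf_labels() - side
        return frozenset(side)

    def edges(self) -> Dict[EdgeId, Node]:
        """All unrooted edges as {edge-id: child node of the rooted edge}.

        When the root has degree two its two child edges are the same unrooted
        edge; the first child is kept as representative.
        """
        labels = self.leaf_labels()
        result: Dict[EdgeId, Node] = {}
        skip: Optional[Node] = None
        if len(self.root.children) == 2:
            skip = self.root.children[1]
        for _nid, (node, below) in self._clades().items():
            if node is skip:
                continue
            if len(below) == len(labels):  # edge above a subtree holding every leaf
                continue
            result[self.canonical_side(below)] = node
        return result

    def bipartitions(self) -> FrozenSet[EdgeId]:
        """Non-trivial splits: both sides of size >= 2."""
        n = self.n_leaves
        return frozenset(
            side for side in self.edges() if 2 <= len(side) <= n - 2
        )

    # -- editing -------------------------------------------------------------------

    def attach_leaf(self, edge: EdgeId, label: str) -> "PhyloTree":
        """Return a new tree with ``label`` attached on ``edge`` via a new degree-3 node."""
        if label in self.leaf_labels():
            raise ValueError(f"label already present: {label!r}")
        tree = self.copy()
        target = tree.edges().get(frozenset(edge))
        if target is None:
            raise KeyError(f"unknown edge: {set(edge)!r}")
        parent = target.parent
        joint = Node()
        parent.children[parent.children.index(target)] = joint
        joint.parent = parent
        joint.add_child(target)
        joint.add_child(Node(label))
        return PhyloTree(tree.root)

    def prune_leaf(self, label: str) -> "PhyloTree":
        if self.n_leaves < 4:
            raise ValueError("tree too small to prune")
        tree = self.copy()
        leaf = next((n for n in tree.postorder() if n.label == label), None)
        if leaf is None:
            raise KeyError(f"unknown leaf: {label!r}")
        parent = leaf.parent
        parent.children.remove(leaf)
        # suppress nodes left with a single child
        node = parent
        while node is not None and not node.is_leaf and len(node.children) == 1:
            child = node.children[0]
            if node.parent is None:
                child.parent = None
                tree.root = child
                node = None
            else:
                grand = node.parent
                grand.children[grand.children.index(node)] = child
                child.parent = grand
                node = grand if len(grand.children) == 1 else None
        # a non-leaf root of degree 0 cannot occur (n >= 4 precondition)
        return PhyloTree(tree.root)


# -- Newick I/O ---------------------------------------------------------------------


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string; branch lengths are kept, polytomies preserved."""
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise ValueError(f"Newick parse error: {exc}") from exc

    def rec(dnode) -> Node:
        label = dnode.taxon.label if dnode.taxon is not None else None
        node = Node(label, dnode.edge.length)
        for child in dnode.child_nodes():
            node.add_child(rec(child))
        return node

    return PhyloTree(rec(dtree.seed_node))


def _quote(label: str) -> str:
    safe = all(c.isalnum() or c in "_.-" for c in label)
    if safe:
        return label
    return "'" + label.replace("'", "''") + "'"


def write_newick(tree: PhyloTree) -> str:
    """Canonical Newick: rooted at the smallest leaf's neighbour, children ordered
    lexicographically by their minimum descendant label, branch lengths omitted.
    Equal unrooted topologies serialize to identical strings."""
    labels = sorted(tree.leaf_labels())
    if len(labels) == 1:
        return f"{_quote(labels[0])};"
    adj = _adjacency(tree)
    if len(labels) == 2:
        return f"({_quote(labels[0])},{_quote(labels[1])});"
    ref = labels[0]
    ref_node = adj.leaf_node[ref]
    base = adj.neighbors[id(ref_node)][0]  # the unique neighbour of a leaf

    def subtree(node: Node, came_from: Node) -> Tuple[str, str]:
        nbrs = [n for n in adj.neighbors[id(node)] if n is not came_from]
        if not nbrs:
            return node.label, _quote(node.label)
        parts = sorted(subtree(n, node) for n in nbrs)
        return parts[0][0], "(" + ",".join(p[1] for p in parts) + ")"

    rendered = sorted(
        subtree(n, base) for n in adj.neighbors[id(base)]
    )
    return "(" + ",".join(p[1] for p in rendered) + ");"


class _Adjacency:
    def __init__(self):
        self.neighbors: Dict[int, List[Node]] = {}
        self.leaf_node: Dict[str, Node] = {}


def _adjacency(tree: PhyloTree) -> _Adjacency:
    """Undirected adjacency with a degree-2 root suppressed."""
    adj = _Adjacency()

    def link(a: Node, b: Node) -> None:
        adj.neighbors.setdefault(id(a), []).append(b)
        adj.neighbors.setdefault(id(b), []).append(a)

    for node in tree.postorder():
        adj.neighbors.setdefault(id(node), [])
        if node.is_leaf:
            adj.leaf_node[node.label] = node
        for child in node.children:
            link(node, child)
    root = tree.root
    if not root.is_leaf and len(root.children) == 2 and tree.n_leaves >= 3:
        a, b = root.children
        adj.neighbors[id(a)].remove(root)
        adj.neighbors[id(b)].remove(root)
        del adj.neighbors[id(root)]
        link(a, b)
    return adj


# -- module-level functional API ----------------------------------------------------


def bipartitions(tree: PhyloTree) -> FrozenSet[EdgeId]:
    return tree.bipartitions()


def attach_leaf(tree: PhyloTree, edge: EdgeId, label: str) -> PhyloTree:
    return tree.attach_leaf(edge, label)


def prune_leaf(tree: PhyloTree, label: str) -> PhyloTree:
    return tree.prune_leaf(label)


def same_topology(a: PhyloTree, b: PhyloTree) -> bool:
    """Unrooted topology identity: same leaves, same non-trivial split sets."""
    return a.leaf_labels() == b.leaf_labels() and a.bipartitions() == b.bipartitions()


def tree_from_splits(leaves: Iterable[str], splits: Iterable[FrozenSet[str]]) -> PhyloTree:
    """Build the (possibly polytomous) unrooted tree whose non-trivial splits are
    exactly ``splits``.  Splits must be pairwise compatible and oriented away
    from the smallest leaf; incompatibility raises ValueError."""
    labels = sorted(set(leaves))
    if len(labels) < 1:
        raise ValueError("no leaves")
    ref = labels[0]
    rest = [l for l in labels if l != ref]
    clades = []
    for s in splits:
        s = frozenset(s)
        if ref in s:
            s = frozenset(labels) - s
        if not (2 <= len(s) <= len(labels) - 2):
            continue
        if not s <= set(rest):
            raise ValueError("split contains unknown leaves")
        clades.append(s)
    clades = sorted(set(clades), key=len, reverse=True)
    root = Node()
    root.add_child(Node(ref))
    if not rest:
        return PhyloTree(root.children[0])
    top = root.add_child(Node())
    holder: Dict[str, Node] = {l: top.add_child(Node(l)) for l in rest}
    # largest-first insertion keeps every clade's leaves direct children of a
    # common parent iff the family is laminar (pairwise compatible splits)
    for clade in clades:
        parents = {id(holder[l].parent): holder[l].parent for l in clade}
        if len(parents) != 1:
            raise ValueError("incompatible splits")
        parent = next(iter(parents.values()))
        group = [c for c in parent.children if _leafset(c) <= clade]
        if sum(len(_leafset(c)) for c in group) != len(clade):
            raise ValueError("incompatible splits")
        new = Node()
        for c in group:
            parent.children.remove(c)
            new.add_child(c)
        parent.add_child(new)
    return PhyloTree(root)


def _leafset(node: Node) -> FrozenSet[str]:
    out = []
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            out.append(n.label)
        stack.extend(n.children)
    return frozenset(out)


def enumerate_topologies(labels: Sequence[str]) -> List[PhyloTree]:
    """Every unrooted binary topology on the given leaves, each exactly once.

    Standard stepwise construction: each topology on n leaves arises from a
    unique (topology on n-1 leaves, edge) pair, so counts follow the
    (2n-5)!! series.  Practical for n <= 9 or so.
    """
    labels = list(labels)
    if len(labels) < 3:
        raise ValueError("need at least 3 leaves")
    root = Node()
    for lab in labels[:3]:
        root.add_child(Node(lab))
    current = [PhyloTree(root)]
    for lab in labels[3:]:
        grown: List[PhyloTree] = []
        for tree in current:
            for edge in sorted(tree.edges(), key=lambda s: (len(s), sorted(s))):
                grown.append(tree.attach_leaf(edge, lab))
        current = grown
    return current


def strict_consensus(trees: Sequence[PhyloTree]) -> PhyloTree:
    """Tree containing exactly the non-trivial splits common to every input."""
    if not trees:
        raise ValueError("need at least one tree")
    labels = trees[0].leaf_labels()
    for t in trees[1:]:
        if t.leaf_labels() != labels:
            raise ValueError("leaf-set mismatch between input trees")
    common = trees[0].bipartitions()
    for t in trees[1:]:
        common &= t.bipartitions()
    return tree_from_splits(labels, common)
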