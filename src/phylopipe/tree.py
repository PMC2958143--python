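"""Phylogenetic tree structure and topology operations.

A :class:`Tree` is a rooted node structure that also serves as the canonical
representation of an *unrooted* tree (``rooted=False``), in which case the
root is a trifurcating internal node and the root edge is meaningless.
Splits (bipartitions of the leaf set) are the unit at which topologies are
compared and node support is recorded; they are keyed canonically by the
lexicographically smaller side so tables from different methods merge.

Newick reading/writing is delegated to dendropy.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Iterator, Optional, Sequence

import dendropy
import numpy as np

__all__ = [
    "Node",
    "Tree",
    "canonical_split",
    "splits_compatible",
    "tree_from_splits",
    "majority_consensus",
    "enumerate_topologies",
    "random_topology",
    "rf_distance",
]


class Node:
    __slots__ = ("label", "length", "children", "parent", "annotations")

    def __init__(self, label: Optional[str] = None, length: Optional[float] = None):
        self.label = label
        self.length = length
        self.children: list["Node"] = []
        self.parent: Optional["Node"] = None
        self.annotations: dict = {}

    def add_child(self, node: "Node") -> "Node":
        node.parent = self
        self.children.append(node)
        return node

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"<Node {self.label or 'internal'}>"


class Tree:
    """Rooted node structure; ``rooted=False`` marks unrooted semantics."""

    def __init__(self, root: Node, rooted: bool = False):
        self.root = root
        self.rooted = rooted

    # ------------------------------------------------------------------
    # construction / io
    # ------------------------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str, rooted: Optional[bool] = None) -> "Tree":
        dt = dendropy.Tree.get(data=newick, schema="newick")
        if rooted is None:
            rooted = bool(dt.is_rooted)

        def convert(dnode) -> Node:
            n = Node(
                label=dnode.taxon.label if dnode.taxon else dnode.label,
                length=dnode.edge.length,
            )
            for c in dnode.child_nodes():
                n.add_child(convert(c))
            return n

        tree = cls(convert(dt.seed_node), rooted=rooted)
        if not rooted:
            tree._ensure_unrooted_shape()
        return tree

    def to_newick(self, include_lengths: bool = True, support_key: Optional[str] = None) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                s = node.label or ""
            else:
                s = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if support_key is not None and support_key in node.annotations:
                    s += f"{node.annotations[support_key]:g}"
            if include_lengths and node.length is not None and node.parent is not None:
                s += f":{node.length:.10g}"
            return s

        return fmt(self.root) + ";"

    def copy(self) -> "Tree":
        def dup(node: Node) -> Node:
            n = Node(node.label, node.length)
            n.annotations = dict(node.annotations)
            for c in node.children:
                n.add_child(dup(c))
            return n

        return Tree(dup(self.root), rooted=self.rooted)

    # ------------------------------------------------------------------
    # traversal
    # ------------------------------------------------------------------
    def postorder(self) -> Iterator[Node]:
        stack = [(self.root, False)]
        while stack:
            node, seen = stack.pop()
            if seen:
                yield node
            else:
                stack.append((node, True))
                for c in reversed(node.children):
                    stack.append((c, False))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    @property
    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def internal_nodes(self, exclude_root: bool = False) -> list[Node]:
        out = [n for n in self.postorder() if not n.is_leaf]
        if exclude_root:
            out = [n for n in out if n is not self.root]
        return out

    def n_leaves(self) -> int:
        return len(self.leaves())

    # ------------------------------------------------------------------
    # shape maintenance
    # ------------------------------------------------------------------
    def _ensure_unrooted_shape(self) -> None:
        """Make the root trifurcating (merge a bifurcating root's edge)."""
        self.suppress_unifurcations()
        root = self.root
        if len(root.children) == 2 and self.n_leaves() >= 3:
            a, b = root.children
            keep, fold = (a, b) if not a.is_leaf else (b, a)
            if keep.is_leaf:  # 2-leaf tree: nothing to do
                return
            # new root = `keep`; attach `fold` under it with merged length
            keep.parent = None
            if fold.length is not None or keep.length is not None:
                fold.length = (fold.length or 0.0) + (keep.length or 0.0)
            keep.length = None
            fold.parent = keep
            keep.children.append(fold)
            self.root = keep

    def suppress_unifurcations(self) -> None:
        for node in list(self.postorder()):
            if node is self.root:
                continue
            if len(node.children) == 1:
                child = node.children[0]
                child.length = (child.length or 0.0) + (node.length or 0.0) \
                    if (child.length is not None or node.length is not None) else None
                parent = node.parent
                idx = parent.children.index(node)
                parent.children[idx] = child
                child.parent = parent
        while len(self.root.children) == 1 and not self.root.children[0].is_leaf:
            self.root = self.root.children[0]
            self.root.parent = None
            self.root.length = None

    # ------------------------------------------------------------------
    # splits
    # ------------------------------------------------------------------
    def splits(self, taxa: Optional[Sequence[str]] = None) -> set[frozenset]:
        """Non-trivial bipartitions, canonically keyed (see canonical_split)."""
        taxa = sorted(taxa) if taxa is not None else sorted(self.leaf_labels)
        all_set = frozenset(taxa)
        out: set[frozenset] = set()
        below: dict[int, frozenset] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset([node.label])
            else:
                side = frozenset().union(*(below[id(c)] for c in node.children))
                below[id(node)] = side
                if node is self.root:
                    continue
                if 2 <= len(side) <= len(all_set) - 2:
                    out.add(canonical_split(side, all_set))
        return out

    def split_nodes(self) -> dict[frozenset, Node]:
        """Map canonical split -> the internal node inducing it."""
        all_set = frozenset(self.leaf_labels)
        out: dict[frozenset, Node] = {}
        below: dict[int, frozenset] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset([node.label])
            else:
                side = frozenset().union(*(below[id(c)] for c in node.children))
                below[id(node)] = side
                if node is not self.root and 2 <= len(side) <= len(all_set) - 2:
                    out[canonical_split(side, all_set)] = node
        return out

    def topology_key(self) -> frozenset:
        """Hashable unrooted-topology identity (leaf set + split set)."""
        return frozenset(self.splits()) | frozenset((lab,) for lab in self.leaf_labels)

    # ------------------------------------------------------------------
    # rooting / clock utilities
    # ------------------------------------------------------------------
    def find_leaf(self, label: str) -> Node:
        for n in self.leaves():
            if n.label == label:
                return n
        raise KeyError(label)

    def root_at_edge_to(self, label: str) -> "Tree":
        """Rooted binary copy with the root placed on the pendant edge of
        `label` (outgroup rooting); the pendant length is split evenly."""
        adj, lengths, leaf_ids = _to_adjacency(self)
        target = leaf_ids[label]
        (nbr,) = adj[target]
        L = lengths[frozenset((target, nbr))]
        new_id = max(max(adj), max(leaf_ids.values())) + 1
        # subdivide edge (target, nbr) with new root node new_id
        adj[target].discard(nbr)
        adj[nbr].discard(target)
        adj[new_id] = {target, nbr}
        adj[target].add(new_id)
        adj[nbr].add(new_id)
        half = None if L is None else L / 2.0
        lengths[frozenset((target, new_id))] = half
        lengths[frozenset((nbr, new_id))] = half
        return _from_adjacency(adj, lengths, {v: k for k, v in leaf_ids.items()},
                               root=new_id, rooted=True)

    def unroot(self) -> "Tree":
        t = self.copy()
        t.rooted = False
        t._ensure_unrooted_shape()
        return t

    def node_heights(self) -> dict[int, float]:
        """Height above the farthest... distance from node down to its leaves.

        Only meaningful for ultrametric trees; returns max leaf distance.
        """
        h: dict[int, float] = {}
        for node in self.postorder():
            if node.is_leaf:
                h[id(node)] = 0.0
            else:
                h[id(node)] = max(h[id(c)] + (c.length or 0.0) for c in node.children)
        return h

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        depths = []
        for node in self.preorder():
            d = 0.0
            n = node
            while n.parent is not None:
                d += n.length or 0.0
                n = n.parent
            if node.is_leaf:
                depths.append(d)
        if not depths:
            return True
        span = max(depths) - min(depths)
        scale = max(max(depths), 1e-12)
        return span / scale <= rel_tol

    def total_length(self) -> float:
        return sum(n.length or 0.0 for n in self.postorder() if n.parent is not None)


# ----------------------------------------------------------------------
# split helpers
# ----------------------------------------------------------------------
def canonical_split(side: Iterable[str], all_taxa: Iterable[str]) -> frozenset:
    """Canonical key of a bipartition: the lexicographically smaller side."""
    side = frozenset(side)
    other = frozenset(all_taxa) - side
    return min(side, other, key=lambda s: tuple(sorted(s)))


def splits_compatible(a: frozenset, b: frozenset, all_taxa: frozenset) -> bool:
    a2, b2 = all_taxa - a, all_taxa - b
    return not (a & b) or not (a & b2) or not (a2 & b) or not (a2 & b2)


def tree_from_splits(splits: Iterable[frozenset], taxa: Sequence[str],
                     weights: Optional[dict] = None,
                     support_key: str = "support") -> Tree:
    """Build the (possibly multifurcating) unrooted tree displaying a
    pairwise-compatible split set."""
    taxa = sorted(taxa)
    all_set = frozenset(taxa)
    ref = taxa[0]
    # clusters: side of each split not containing the reference taxon
    clusters = []
    for s in splits:
        side = s if ref not in s else all_set - s
        clusters.append((frozenset(side), s))
    clusters.sort(key=lambda cs: len(cs[0]))

    root = Node()
    leaf_nodes = {}
    for lab in taxa:
        leaf_nodes[lab] = root.add_child(Node(lab))
    covers: list[tuple[frozenset, Node]] = []  # cluster -> its node, small->large
    for side, orig in clusters:
        members = []
        for c in list(root.children):
            cl = _cluster_of(c, leaf_nodes)
            if cl <= side:
                members.append(c)
        merged = frozenset().union(*(_cluster_of(m, leaf_nodes) for m in members))
        if merged != side:
            # incompatible with already-added structure; skip (greedy mode)
            continue
        new = Node()
        if weights is not None and orig in weights:
            new.annotations[support_key] = weights[orig]
        for m in members:
            root.children.remove(m)
            new.add_child(m)
        root.add_child(new)
        covers.append((side, new))
    return Tree(root, rooted=False)


def _cluster_of(node: Node, leaf_nodes: dict) -> frozenset:
    return frozenset(n.label for n in Tree(node, rooted=True).leaves())


def majority_consensus(trees: Sequence[Tree], min_freq: float = 0.5,
                       extended: bool = False) -> tuple[Tree, dict[frozenset, float]]:
    """Majority-rule consensus; returns (tree, split -> frequency).

    With ``extended=True``, compatible minority splits are greedily added in
    decreasing frequency (majority-rule-extended consensus).
    """
    if not trees:
        raise ValueError("no trees supplied")
    taxa = sorted(trees[0].leaf_labels)
    all_set = frozenset(taxa)
    counts: dict[frozenset, int] = {}
    for t in trees:
        for s in t.splits(taxa):
            counts[s] = counts.get(s, 0) + 1
    n = len(trees)
    freqs = {s: c / n for s, c in counts.items()}
    chosen = [s for s, f in freqs.items() if f > min_freq]
    if extended:
        rest = sorted((s for s in freqs if s not in chosen),
                      key=lambda s: (-freqs[s], tuple(sorted(s))))
        for s in rest:
            if all(splits_compatible(s, c, all_set) for c in chosen):
                chosen.append(s)
    tree = tree_from_splits(chosen, taxa, weights=freqs)
    return tree, freqs


def rf_distance(a: Tree, b: Tree) -> int:
    sa, sb = a.splits(), b.splits()
    return len(sa ^ sb)


# ----------------------------------------------------------------------
# adjacency view (used by rooting and by tree rearrangement code)
# ----------------------------------------------------------------------
def _to_adjacency(tree: Tree):
    """Return (adjacency dict, edge-length dict, leaf label -> id)."""
    adj: dict[int, set[int]] = {}
    lengths: dict[frozenset, Optional[float]] = {}
    leaf_ids: dict[str, int] = {}
    ids: dict[int, int] = {}
    counter = itertools.count()
    for node in tree.postorder():
        ids[id(node)] = next(counter)
    for node in tree.postorder():
        u = ids[id(node)]
        adj.setdefault(u, set())
        if node.is_leaf:
            leaf_ids[node.label] = u
        if node.parent is not None:
            v = ids[id(node.parent)]
            adj.setdefault(v, set())
            adj[u].add(v)
            adj[v].add(u)
            lengths[frozenset((u, v))] = node.length
    return adj, lengths, leaf_ids


def _from_adjacency(adj, lengths, labels, root: int, rooted: bool) -> Tree:
    def build(u: int, parent: Optional[int]) -> Node:
        n = Node(label=labels.get(u))
        if parent is not None:
            n.length = lengths.get(frozenset((u, parent)))
        for v in sorted(adj[u]):
            if v != parent:
                n.add_child(build(v, u))
        return n

    t = Tree(build(root, None), rooted=rooted)
    if not rooted:
        t._ensure_unrooted_shape()
    return t


# ----------------------------------------------------------------------
# topology generation
# ----------------------------------------------------------------------
def enumerate_topologies(taxa: Sequence[str]) -> list[Tree]:
    """All distinct unrooted binary topologies on `taxa` (lengths None).

    (2n-5)!! trees; guarded for n <= 10.
    """
    taxa = list(taxa)
    n = len(taxa)
    if n < 3:
        raise ValueError("need >= 3 taxa")
    if n > 10:
        raise ValueError("enumeration guarded at 10 taxa")
    base = Node()
    for lab in taxa[:3]:
        base.add_child(Node(lab))
    partials = [Tree(base, rooted=False)]
    for lab in taxa[3:]:
        nxt = []
        for t in partials:
            edges = [node for node in t.postorder() if node.parent is not None]
            for i in range(len(edges)):
                t2 = t.copy()
                edges2 = [node for node in t2.postorder() if node.parent is not None]
                child = edges2[i]
                parent = child.parent
                mid = Node()
                idx = parent.children.index(child)
                parent.children[idx] = mid
                mid.parent = parent
                mid.add_child(child)
                mid.add_child(Node(lab))
                nxt.append(t2)
        partials = nxt
    return partials


def random_topology(taxa: Sequence[str], rng: np.random.Generator,
                    branch_lengths=None) -> Tree:
    """Uniform random unrooted binary topology by random sequential addition.

    `branch_lengths`: None, or a callable rng -> float applied to every edge.
    """
    taxa = list(taxa)
    if len(taxa) < 3:
        raise ValueError("need >= 3 taxa")
    order = list(rng.permutation(len(taxa)))
    base = Node()
    for k in order[:3]:
        base.add_child(Node(taxa[k]))
    t = Tree(base, rooted=False)
    for k in order[3:]:
        edges = [node for node in t.postorder() if node.parent is not None]
        child = edges[rng.integers(len(edges))]
        parent = child.parent
        mid = Node()
        idx = parent.children.index(child)
        parent.children[idx] = mid
        mid.parent = parent
        mid.add_child(child)
        mid.add_child(Node(taxa[k]))
    if branch_lengths is not None:
        for node in t.postorder():
            if node.parent is not None:
                node.length = float(branch_lengths(rng))
    return t
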