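"""Maximum-parsimony engine.

Fitch scoring on unrooted binary trees, exact search (exhaustive enumeration
and branch-and-bound by stepwise addition) and TBR/NNI hill-climbing from
random-addition starting trees, nonparametric bootstrap, variable-length
bootstrap curves, and Bremer / partitioned Bremer support via anti-constraint
searches.

Internally trees are adjacency dicts over integer node ids (leaves are
0..n-1 in matrix taxon order); site patterns are compressed with counts, and
cells are 4-bit state sets (missing data and gaps are full wildcards and so
never add changes).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .supermatrix import ConcatenatedMatrix
from .tree import Tree, Node, canonical_split, majority_consensus

__all__ = [
    "SupportTable",
    "fitch_score",
    "mp_search",
    "bootstrap_support",
    "variable_length_bootstrap",
    "bremer_support",
    "partitioned_bremer",
]

# state-set bitmasks per character code (A,C,G,T,-,?,N)
_BITS = np.array([1, 2, 4, 8, 15, 15, 15], dtype=np.uint8)


# ----------------------------------------------------------------------
# encoding and pattern compression
# ----------------------------------------------------------------------
def encode_bitmasks(data: np.ndarray) -> np.ndarray:
    return _BITS[data]


def compress_patterns(bits: np.ndarray,
                      counts: Optional[np.ndarray] = None
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Collapse identical columns; returns (patterns, weights)."""
    pats, inverse = np.unique(bits, axis=1, return_inverse=True)
    if counts is None:
        weights = np.bincount(inverse, minlength=pats.shape[1])
    else:
        weights = np.bincount(inverse, weights=counts,
                              minlength=pats.shape[1]).astype(np.int64)
    keep = weights > 0
    return pats[:, keep], weights[keep].astype(np.int64)


# ----------------------------------------------------------------------
# adjacency utilities
# ----------------------------------------------------------------------
def tree_to_adj(tree: Tree, taxa: Sequence[str]) -> dict[int, set[int]]:
    index = {t: i for i, t in enumerate(taxa)}
    n = len(taxa)
    adj: dict[int, set[int]] = {}
    ids: dict[int, int] = {}
    counter = itertools.count(n)

    for node in tree.postorder():
        if node.is_leaf:
            ids[id(node)] = index[node.label]
        else:
            ids[id(node)] = next(counter)
    for node in tree.postorder():
        u = ids[id(node)]
        adj.setdefault(u, set())
        if node.parent is not None:
            v = ids[id(node.parent)]
            adj.setdefault(v, set())
            adj[u].add(v)
            adj[v].add(u)
    return adj


def adj_to_tree(adj: dict[int, set[int]], taxa: Sequence[str]) -> Tree:
    n = len(taxa)
    start = next(iter(adj[0]))  # internal node adjacent to leaf 0

    def build(u: int, parent: Optional[int]) -> Node:
        node = Node(label=taxa[u] if u < n else None)
        for v in sorted(adj[u]):
            if v != parent:
                node.add_child(build(v, u))
        return node

    t = Tree(build(start, None), rooted=False)
    t._ensure_unrooted_shape()
    return t


def _copy_adj(adj) -> dict[int, set[int]]:
    return {k: set(v) for k, v in adj.items()}


def _edges(adj) -> list[tuple[int, int]]:
    out = []
    for u, nbrs in adj.items():
        for v in nbrs:
            if u < v:
                out.append((u, v))
    return out


def splits_of_adj(adj: dict[int, set[int]], n_leaves: int) -> frozenset:
    """Non-trivial splits as int bitmasks of the side NOT containing leaf 0."""
    masks: dict[int, int] = {}
    out = set()
    root = next(iter(adj[0]))
    stack = [(root, 0, False)]
    while stack:
        node, parent, seen = stack.pop()
        if node < n_leaves:
            masks[node] = 1 << node
            continue
        if seen:
            m = 0
            for v in adj[node]:
                if v != parent:
                    m |= masks[v]
            masks[node] = m
            pc = bin(m).count("1")
            if 2 <= pc <= n_leaves - 2:
                out.add(m)
        else:
            stack.append((node, parent, True))
            for v in adj[node]:
                if v != parent:
                    stack.append((v, node, False))
    return frozenset(out)


def mask_to_split(mask: int, taxa: Sequence[str]) -> frozenset:
    side = frozenset(taxa[i] for i in range(len(taxa)) if mask >> i & 1)
    return canonical_split(side, taxa)


def split_to_mask(split: frozenset, taxa: Sequence[str]) -> int:
    index = {t: i for i, t in enumerate(taxa)}
    mask = 0
    for t in split:
        mask |= 1 << index[t]
    if mask & 1:  # canonical adjacency side excludes leaf 0
        full = (1 << len(taxa)) - 1
        mask = full ^ mask
    return mask


# ----------------------------------------------------------------------
# Fitch scoring
# ----------------------------------------------------------------------
def _fitch_on_adj(adj, pats: np.ndarray, weights: np.ndarray) -> int:
    """Weighted Fitch length of the unrooted tree `adj` (rooted at leaf 0)."""
    n = pats.shape[0]
    leaf0 = min(u for u in adj if u < n)  # partial trees may lack leaf 0
    root = next(iter(adj[leaf0]))
    if root < n:  # 2-leaf tree
        inter = pats[leaf0] & pats[root]
        return int(weights[inter == 0].sum())
    state: dict[int, np.ndarray] = {}
    changes = 0
    stack = [(root, leaf0, False)]
    while stack:
        node, parent, seen = stack.pop()
        if node < n:
            state[node] = pats[node]
            continue
        if not seen:
            stack.append((node, parent, True))
            for v in adj[node]:
                if v != parent:
                    stack.append((v, node, False))
            continue
        children = [v for v in adj[node] if v != parent]
        s = state[children[0]]
        for c in children[1:]:
            inter = s & state[c]
            zero = inter == 0
            if zero.any():
                changes += int(weights[zero].sum())
                s = np.where(zero, s | state[c], inter)
            else:
                s = inter
        state[node] = s
    inter = state[root] & pats[leaf0]
    changes += int(weights[inter == 0].sum())
    return changes


def _prepare(matrix: Union[ConcatenatedMatrix, np.ndarray],
             taxa: Optional[Sequence[str]] = None,
             columns: Optional[np.ndarray] = None):
    if isinstance(matrix, ConcatenatedMatrix):
        data, taxa = matrix.data, matrix.taxa
    else:
        data = np.asarray(matrix)
        if taxa is None:
            taxa = [f"t{i}" for i in range(data.shape[0])]
    if columns is not None:
        data = data[:, np.asarray(columns)]
    bits = encode_bitmasks(data)
    pats, weights = compress_patterns(bits)
    return pats, weights, list(taxa)


def fitch_score(tree: Tree, matrix: Union[ConcatenatedMatrix, np.ndarray],
                taxa: Optional[Sequence[str]] = None) -> int:
    """Minimum number of state changes (equal weights; missing = wildcard)."""
    pats, weights, taxa = _prepare(matrix, taxa)
    if set(tree.leaf_labels) != set(taxa):
        raise ValueError("tree leaves do not match matrix taxa")
    adj = tree_to_adj(tree, taxa)
    return _fitch_on_adj(adj, pats, weights)


# ----------------------------------------------------------------------
# tree construction / rearrangement on adjacencies
# ----------------------------------------------------------------------
def _initial_adj(a: int, b: int, c: int, hub: int) -> dict[int, set[int]]:
    return {a: {hub}, b: {hub}, c: {hub}, hub: {a, b, c}}


def _insert_leaf(adj, leaf: int, edge: tuple[int, int], new_internal: int):
    u, v = edge
    adj[u].discard(v)
    adj[v].discard(u)
    adj[new_internal] = {u, v, leaf}
    adj[u].add(new_internal)
    adj[v].add(new_internal)
    adj[leaf] = {new_internal}


def _greedy_addition_tree(pats, weights, order: Sequence[int],
                          n_leaves: int, rng: np.random.Generator):
    counter = itertools.count(n_leaves)
    hub = next(counter)
    adj = _initial_adj(order[0], order[1], order[2], hub)
    for leaf in order[3:]:
        best_score, best_edges = None, []
        for edge in _edges(adj):
            cand = _copy_adj(adj)
            _insert_leaf(cand, leaf, edge, -1)
            s = _fitch_on_adj(cand, pats, weights)
            if best_score is None or s < best_score:
                best_score, best_edges = s, [edge]
            elif s == best_score:
                best_edges.append(edge)
        edge = best_edges[int(rng.integers(len(best_edges)))]
        _insert_leaf(adj, leaf, edge, next(counter))
        if -1 in adj:
            del adj[-1]
    return adj


def _renumber(adj, n_leaves: int) -> dict[int, set[int]]:
    """Relabel internal ids to a compact 'n_leaves..' range (canonical-ish)."""
    mapping = {}
    counter = itertools.count(n_leaves)
    for u in sorted(adj):
        mapping[u] = u if u < n_leaves else next(counter)
    return {mapping[u]: {mapping[v] for v in nbrs} for u, nbrs in adj.items()}


def nni_neighbors(adj, n_leaves: int):
    """Yield the 2 NNI rearrangements of every internal edge."""
    for (u, v) in _edges(adj):
        if u < n_leaves or v < n_leaves:
            continue
        u_nbrs = [x for x in adj[u] if x != v]
        v_nbrs = [x for x in adj[v] if x != u]
        a = u_nbrs[0]
        for b in v_nbrs:
            cand = _copy_adj(adj)
            cand[u].discard(a); cand[a].discard(u)
            cand[v].discard(b); cand[b].discard(v)
            cand[u].add(b); cand[b].add(u)
            cand[v].add(a); cand[a].add(v)
            yield cand


def _component(adj, start: int, blocked_edge: tuple[int, int]) -> set[int]:
    u, v = blocked_edge
    seen = {start}
    stack = [start]
    while stack:
        x = stack.pop()
        for y in adj[x]:
            if (x, y) in ((u, v), (v, u)):
                continue
            if y not in seen:
                seen.add(y)
                stack.append(y)
    return seen


def tbr_neighbors(adj, n_leaves: int):
    """Yield TBR rearrangements: cut each edge, reconnect every edge pair."""
    fresh = max(adj) + 1
    for (u, v) in _edges(adj):
        comp_u = _component(adj, u, (u, v))
        base = _copy_adj(adj)
        base[u].discard(v)
        base[v].discard(u)
        # suppress degree-2 ends (internal nodes only)
        cut_points = {}
        for end in (u, v):
            if end >= n_leaves and len(base[end]) == 2:
                x, y = sorted(base[end])
                base[x].discard(end); base[y].discard(end)
                base[x].add(y); base[y].add(x)
                del base[end]
                cut_points[end] = (x, y)
        nodes_u = {x for x in base if x in comp_u}
        nodes_v = set(base) - nodes_u
        edges_u = [(a, b) for (a, b) in _edges(base) if a in nodes_u]
        edges_v = [(a, b) for (a, b) in _edges(base) if a in nodes_v]
        att_u = edges_u if edges_u else [None]   # None => single-node side
        att_v = edges_v if edges_v else [None]
        lone_u = next(iter(nodes_u)) if not edges_u else None
        lone_v = next(iter(nodes_v)) if not edges_v else None
        for ea in att_u:
            for eb in att_v:
                cand = _copy_adj(base)
                nid = itertools.count(fresh)
                if ea is None:
                    a_point = lone_u
                else:
                    a_point = next(nid)
                    _subdivide(cand, ea, a_point)
                if eb is None:
                    b_point = lone_v
                else:
                    b_point = next(nid)
                    _subdivide(cand, eb, b_point)
                cand.setdefault(a_point, set()).add(b_point)
                cand.setdefault(b_point, set()).add(a_point)
                yield cand


def _subdivide(adj, edge: tuple[int, int], mid: int):
    a, b = edge
    adj[a].discard(b)
    adj[b].discard(a)
    adj[mid] = {a, b}
    adj[a].add(mid)
    adj[b].add(mid)


# ----------------------------------------------------------------------
# searches
# ----------------------------------------------------------------------
def _hill_climb(adj, pats, weights, n_leaves: int,
                neighbor_fn: Callable, allowed: Optional[Callable] = None,
                max_ties: int = 64) -> tuple[int, list]:
    """Steepest-descent swap until no neighbor improves; returns the set of
    equally-best topologies encountered (signature-deduplicated)."""
    score = _fitch_on_adj(adj, pats, weights)
    pool = {splits_of_adj(adj, n_leaves): adj}
    improved = True
    while improved:
        improved = False
        frontier = list(pool.values())
        for current in frontier:
            for cand in neighbor_fn(current, n_leaves):
                sig = splits_of_adj(cand, n_leaves)
                if allowed is not None and not allowed(sig):
                    continue
                s = _fitch_on_adj(cand, pats, weights)
                if s < score:
                    score = s
                    pool = {sig: _renumber(cand, n_leaves)}
                    improved = True
                    break
                if s == score and sig not in pool and len(pool) < max_ties:
                    pool[sig] = _renumber(cand, n_leaves)
            if improved:
                break
    return score, list(pool.values())


def _enumerate_adjs(n_leaves: int, allowed: Optional[Callable] = None):
    """Yield every unrooted binary topology on leaves 0..n_leaves-1."""
    counter_base = n_leaves

    def rec(adj, next_leaf, next_internal):
        if next_leaf == n_leaves:
            yield adj
            return
        for edge in _edges(adj):
            cand = _copy_adj(adj)
            _insert_leaf(cand, next_leaf, edge, next_internal)
            yield from rec(cand, next_leaf + 1, next_internal + 1)

    start = _initial_adj(0, 1, 2, counter_base)
    yield from rec(start, 3, counter_base + 1)


def _branch_and_bound(pats, weights, n_leaves: int,
                      upper: Optional[int] = None) -> tuple[int, list]:
    best = [upper if upper is not None else np.iinfo(np.int64).max, {}]

    def rec(adj, next_leaf, next_internal):
        s = _fitch_on_adj(adj, pats, weights)
        if s > best[0]:
            return
        if next_leaf == n_leaves:
            sig = splits_of_adj(adj, n_leaves)
            if s < best[0]:
                best[0] = s
                best[1] = {sig: _renumber(adj, n_leaves)}
            elif s == best[0]:
                best[1].setdefault(sig, _renumber(adj, n_leaves))
            return
        for edge in _edges(adj):
            cand = _copy_adj(adj)
            _insert_leaf(cand, next_leaf, edge, next_internal)
            rec(cand, next_leaf + 1, next_internal + 1)

    rec(_initial_adj(0, 1, 2, n_leaves), 3, n_leaves + 1)
    if not best[1]:  # upper bound was too tight; redo unbounded
        return _branch_and_bound(pats, weights, n_leaves, upper=None)
    return best[0], list(best[1].values())


def mp_search(matrix, strategy: str = "auto", n_addition_replicates: int = 10,
              seed: int = 0, taxa: Optional[Sequence[str]] = None,
              allow_large_exhaustive: bool = False,
              neighborhood: str = "tbr",
              allowed: Optional[Callable] = None) -> tuple[list[Tree], int]:
    """Maximum-parsimony search.

    strategy: 'exhaustive' | 'branch_and_bound' | 'tbr_heuristic' | 'auto'
    (auto = branch-and-bound up to 11 taxa, TBR heuristic above). Returns
    (all equally best trees found, best score).
    """
    pats, weights, taxa = _prepare(matrix, taxa)
    n = len(taxa)
    if n < 4:
        raise ValueError("need >= 4 taxa")
    if strategy == "auto":
        strategy = "branch_and_bound" if n <= 11 else "tbr_heuristic"
    rng = np.random.default_rng(seed)

    if strategy == "exhaustive":
        if n > 10 and not allow_large_exhaustive:
            raise ValueError("exhaustive search refused for > 10 taxa "
                             "(pass allow_large_exhaustive=True to override)")
        best_score, best = None, {}
        for adj in _enumerate_adjs(n):
            sig = splits_of_adj(adj, n)
            if allowed is not None and not allowed(sig):
                continue
            s = _fitch_on_adj(adj, pats, weights)
            if best_score is None or s < best_score:
                best_score, best = s, {sig: _renumber(adj, n)}
            elif s == best_score:
                best.setdefault(sig, _renumber(adj, n))
        adjs = list(best.values())
    elif strategy == "branch_and_bound":
        if allowed is not None:
            raise ValueError("constrained search requires exhaustive or TBR")
        order = list(rng.permutation(n))
        upper = _fitch_on_adj(
            _greedy_addition_tree(pats, weights, order, n, rng), pats, weights)
        best_score, adjs = _branch_and_bound(pats, weights, n, upper=upper)
    elif strategy == "tbr_heuristic":
        neighbor_fn = tbr_neighbors if neighborhood == "tbr" else nni_neighbors
        best_score, best = None, {}
        for _ in range(max(1, n_addition_replicates)):
            order = list(rng.permutation(n))
            start = _greedy_addition_tree(pats, weights, order, n, rng)
            if allowed is not None and not allowed(splits_of_adj(start, n)):
                start = _force_allowed(start, n, allowed)
                if start is None:
                    continue
            s, pool = _hill_climb(start, pats, weights, n, neighbor_fn,
                                  allowed=allowed)
            if best_score is None or s < best_score:
                best_score = s
                best = {splits_of_adj(a, n): a for a in pool}
            elif s == best_score:
                for a in pool:
                    best.setdefault(splits_of_adj(a, n), a)
        if best_score is None:
            raise RuntimeError("no admissible starting tree found")
        adjs = list(best.values())
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    trees = [adj_to_tree(a, taxa) for a in adjs]
    return trees, int(best_score)


def _force_allowed(adj, n_leaves, allowed, max_depth: int = 2):
    """Find a nearby topology satisfying `allowed` via NNI/TBR moves."""
    frontier = [adj]
    for _ in range(max_depth):
        nxt = []
        for a in frontier:
            for cand in tbr_neighbors(a, n_leaves):
                if allowed(splits_of_adj(cand, n_leaves)):
                    return _renumber(cand, n_leaves)
                nxt.append(cand)
        frontier = nxt[:50]
    return None


# ----------------------------------------------------------------------
# support table
# ----------------------------------------------------------------------
@dataclass
class SupportTable:
    """Per-split support: bootstrap %, posterior probability, Bremer decay
    and per-partition PBS. Splits are canonical label frozensets."""

    taxa: list[str]
    rows: dict[frozenset, dict] = field(default_factory=dict)

    def set_value(self, split: frozenset, key: str, value) -> None:
        self.rows.setdefault(split, {})[key] = value
        self._check(split)

    def _check(self, split):
        row = self.rows[split]
        b = row.get("bootstrap")
        if b is not None and not (0 <= b <= 100):
            raise ValueError("bootstrap out of [0,100]")
        pp = row.get("posterior")
        if pp is not None and not (0 <= pp <= 1):
            raise ValueError("posterior probability out of [0,1]")
        if "pbs" in row and "decay" in row:
            total = sum(row["pbs"].values())
            if abs(total - row["decay"]) > 1e-9:
                raise ValueError("sum of PBS != Bremer decay")

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for split, row in self.rows.items():
            rec = {"split": "|".join(sorted(split))}
            for k, v in row.items():
                if k == "pbs":
                    for part, val in v.items():
                        rec[f"pbs_{part}"] = val
                else:
                    rec[k] = v
            recs.append(rec)
        return pd.DataFrame(recs)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def merge(self, other: "SupportTable") -> "SupportTable":
        out = SupportTable(self.taxa)
        for src in (self, other):
            for split, row in src.rows.items():
                out.rows.setdefault(split, {}).update(row)
        return out


# ----------------------------------------------------------------------
# bootstrap
# ----------------------------------------------------------------------
def _bootstrap_weights(L: int, size: int, rng) -> np.ndarray:
    """Column resampling with replacement expressed as per-column counts."""
    return rng.multinomial(size, np.full(L, 1.0 / L))


def _search_adjs(pats, weights, n_leaves, rng, strategy, n_addition_replicates,
                 neighborhood):
    """Internal search on prepared patterns, returning adjacency pool."""
    best_score, best = None, {}
    for _ in range(max(1, n_addition_replicates)):
        order = list(rng.permutation(n_leaves))
        start = _greedy_addition_tree(pats, weights, order, n_leaves, rng)
        neighbor_fn = tbr_neighbors if neighborhood == "tbr" else nni_neighbors
        s, pool = _hill_climb(start, pats, weights, n_leaves, neighbor_fn)
        if best_score is None or s < best_score:
            best_score = s
            best = {splits_of_adj(a, n_leaves): a for a in pool}
        elif s == best_score:
            for a in pool:
                best.setdefault(splits_of_adj(a, n_leaves), a)
    return best_score, best


def bootstrap_support(matrix, n_reps: int = 1000, seed: int = 0,
                      reference_tree: Optional[Tree] = None,
                      n_addition_replicates: int = 2,
                      neighborhood: str = "nni",
                      resample_size: Optional[int] = None
                      ) -> tuple[SupportTable, Tree]:
    """Nonparametric bootstrap under MP.

    Columns are resampled with replacement (to `resample_size` columns,
    default the original length); each pseudo-replicate is searched by
    random-addition + branch swapping and contributes fractionally when it
    yields several equally best trees. Returns (SupportTable over all splits
    observed, majority-rule-extended consensus of replicate trees).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    pats0, w0, taxa = _prepare(matrix)
    n = len(taxa)
    L = int(w0.sum())
    size = resample_size if resample_size is not None else L
    rng = np.random.default_rng(seed)
    # expand pattern probabilities for resampling
    probs = w0 / w0.sum()
    counts: dict[int, float] = {}
    rep_best_trees: list = []
    for _ in range(n_reps):
        boot_w = rng.multinomial(size, probs)
        keep = boot_w > 0
        pats, weights = pats0[:, keep], boot_w[keep].astype(np.int64)
        _, best = _search_adjs(pats, weights, n, rng, "tbr_heuristic",
                               n_addition_replicates, neighborhood)
        k = len(best)
        for sig in best:
            for mask in sig:
                counts[mask] = counts.get(mask, 0.0) + 1.0 / k
        rep_best_trees.append(next(iter(best.values())))
    table = SupportTable(taxa)
    for mask, c in counts.items():
        split = mask_to_split(mask, taxa)
        table.set_value(split, "bootstrap", 100.0 * c / n_reps)
    if reference_tree is not None:
        for split in reference_tree.splits(taxa):
            if split not in table.rows:
                table.set_value(split, "bootstrap", 0.0)
    cons_trees = [adj_to_tree(a, taxa) for a in rep_best_trees]
    consensus, _ = majority_consensus(cons_trees, extended=True)
    return table, consensus


def variable_length_bootstrap(matrix, sizes: Sequence[int], n_reps: int = 100,
                              seed: int = 0,
                              reference_tree: Optional[Tree] = None,
                              n_addition_replicates: int = 1,
                              neighborhood: str = "nni") -> pd.DataFrame:
    """Bootstrap support as a function of resampled pseudo-matrix length.

    Sizes may exceed the matrix length (resampling is with replacement).
    Returns a tidy frame (size, split, support) ready for curve plotting.
    """
    sizes = list(sizes)
    if not sizes or any(s < 1 for s in sizes):
        raise ValueError("sizes must be positive and non-empty")
    pats0, w0, taxa = _prepare(matrix)
    if reference_tree is None:
        trees, _ = mp_search(matrix, strategy="tbr_heuristic",
                             n_addition_replicates=max(2, n_addition_replicates),
                             seed=seed)
        reference_tree = trees[0]
    ref_splits = sorted(reference_tree.splits(taxa),
                        key=lambda s: tuple(sorted(s)))
    records = []
    for k, size in enumerate(sizes):
        table, _ = bootstrap_support(
            matrix, n_reps=n_reps, seed=seed + 1000003 * (k + 1),
            reference_tree=reference_tree,
            n_addition_replicates=n_addition_replicates,
            neighborhood=neighborhood, resample_size=int(size))
        for split in ref_splits:
            support = table.rows.get(split, {}).get("bootstrap", 0.0)
            records.append({"size": int(size),
                            "split": "|".join(sorted(split)),
                            "support": support})
    return pd.DataFrame(records)


# ----------------------------------------------------------------------
# Bremer support
# ----------------------------------------------------------------------
def _anti_constraint_best(pats, weights, n_leaves: int, mask: int,
                          best_adj, rng, exact_limit: int = 8,
                          n_addition_replicates: int = 4
                          ) -> tuple[int, list]:
    """Best score and co-optimal topologies among trees NOT containing the
    split `mask` (exact enumeration at small n, constrained TBR otherwise)."""
    forbidden = mask

    def allowed(sig: frozenset) -> bool:
        return forbidden not in sig

    if n_leaves <= exact_limit:
        best_score, best = None, {}
        for adj in _enumerate_adjs(n_leaves):
            sig = splits_of_adj(adj, n_leaves)
            if forbidden in sig:
                continue
            s = _fitch_on_adj(adj, pats, weights)
            if best_score is None or s < best_score:
                best_score, best = s, {sig: _renumber(adj, n_leaves)}
            elif s == best_score:
                best.setdefault(sig, _renumber(adj, n_leaves))
        return best_score, list(best.values())
    # heuristic: start from NNI rearrangements of the best tree that break
    # the split, then constrained TBR
    starts = [cand for cand in nni_neighbors(best_adj, n_leaves)
              if forbidden not in splits_of_adj(cand, n_leaves)]
    if not starts:
        starts = [cand for cand in tbr_neighbors(best_adj, n_leaves)
                  if forbidden not in splits_of_adj(cand, n_leaves)][:4]
    best_score, best = None, {}
    for start in starts[:max(1, n_addition_replicates)]:
        s, pool = _hill_climb(start, pats, weights, n_leaves, tbr_neighbors,
                              allowed=allowed)
        if best_score is None or s < best_score:
            best_score = s
            best = {splits_of_adj(a, n_leaves): a for a in pool}
        elif s == best_score:
            for a in pool:
                best.setdefault(splits_of_adj(a, n_leaves), a)
    return best_score, list(best.values())


def bremer_support(matrix, best_tree: Tree, best_score: Optional[int] = None,
                   seed: int = 0, exact_limit: int = 8,
                   taxa: Optional[Sequence[str]] = None) -> SupportTable:
    """Decay index per internal split of `best_tree`.

    decay(split) = (score of the best tree lacking the split) - best score.
    """
    pats, weights, taxa = _prepare(matrix, taxa)
    n = len(taxa)
    rescored = _fitch_on_adj(tree_to_adj(best_tree, taxa), pats, weights)
    if best_score is not None and rescored != best_score:
        raise ValueError(f"input tree scores {rescored}, not the claimed "
                         f"{best_score}; not an MP tree?")
    best_score = rescored
    best_adj = tree_to_adj(best_tree, taxa)
    rng = np.random.default_rng(seed)
    table = SupportTable(list(taxa))
    for mask in sorted(splits_of_adj(best_adj, n)):
        anti_score, _ = _anti_constraint_best(pats, weights, n, mask,
                                              best_adj, rng,
                                              exact_limit=exact_limit)
        decay = int(anti_score - best_score)
        if decay < 0:
            # the input tree was not optimal after all
            raise ValueError("negative decay: input tree is not an MP tree")
        table.set_value(mask_to_split(mask, taxa), "decay", decay)
    return table


def partitioned_bremer(matrix, scheme: dict[str, np.ndarray], best_tree: Tree,
                       seed: int = 0, exact_limit: int = 8,
                       tie_handling: str = "average") -> SupportTable:
    """Partitioned Bremer support.

    PBS(split, partition) = partition Fitch length on the best tree lacking
    the split minus partition length on the best tree; values can be
    negative; per split they sum exactly to the decay index. Co-optimal
    anti-constraint trees are averaged ('average') or the first is used
    ('first').
    """
    if isinstance(matrix, ConcatenatedMatrix):
        data, taxa = matrix.data, matrix.taxa
    else:
        raise TypeError("partitioned_bremer requires a ConcatenatedMatrix")
    L = data.shape[1]
    covered = np.zeros(L, dtype=bool)
    for idx in scheme.values():
        covered[np.asarray(idx)] = True
    if not covered.all():
        raise ValueError("partition scheme does not cover the matrix")
    pats, weights, taxa = _prepare(matrix)
    n = len(taxa)
    part_data = {name: _prepare(matrix, columns=idx)[:2]
                 for name, idx in scheme.items()}
    best_adj = tree_to_adj(best_tree, taxa)
    best_score = _fitch_on_adj(best_adj, pats, weights)
    best_part_len = {name: _fitch_on_adj(best_adj, p, w)
                     for name, (p, w) in part_data.items()}
    rng = np.random.default_rng(seed)
    table = SupportTable(list(taxa))
    for mask in sorted(splits_of_adj(best_adj, n)):
        anti_score, anti_adjs = _anti_constraint_best(
            pats, weights, n, mask, best_adj, rng, exact_limit=exact_limit)
        if tie_handling == "first":
            anti_adjs = anti_adjs[:1]
        decay = anti_score - best_score
        pbs = {}
        for name, (p, w) in part_data.items():
            lens = [_fitch_on_adj(a, p, w) for a in anti_adjs]
            pbs[name] = float(np.mean(lens)) - best_part_len[name]
        split = mask_to_split(mask, taxa)
        table.rows[split] = {"decay": float(decay), "pbs": pbs}
        table._check(split)
    return table
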