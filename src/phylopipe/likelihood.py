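"""Maximum-likelihood machinery.

Felsenstein-pruning log-likelihood under JC/K80/HKY/GTR with optional
invariant-sites and discrete-gamma rate mixtures; numeric branch-length
optimization; AIC model selection; NNI-based ML tree search (exhaustive scan
at small taxon counts); molecular-clock likelihood-ratio test; RELL-based
KH/SH/WSH topology tests; and a strict-clock fossil scaling that assigns
absolute node ages from a single minimum-age calibration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar
from scipy.special import logsumexp
from scipy.stats import chi2

from .seqmodels import SubstitutionModel
from .supermatrix import ConcatenatedMatrix, MISSING_THRESHOLD
from .tree import Tree, enumerate_topologies

__all__ = [
    "SiteLikelihoods",
    "pruning_lnL",
    "optimize_branch_lengths",
    "fit_model",
    "model_select_aic",
    "ml_tree_search",
    "clock_lrt",
    "topology_tests",
    "date_nodes",
    "mrca",
]

_MIN_BL, _MAX_BL = 1e-9, 20.0


@dataclass
class SiteLikelihoods:
    tree_id: str
    site_lnl: np.ndarray

    def __post_init__(self):
        self.site_lnl = np.asarray(self.site_lnl, dtype=float)
        if not np.all(np.isfinite(self.site_lnl)):
            raise ValueError("non-finite site log-likelihoods")

    @property
    def total(self) -> float:
        return float(self.site_lnl.sum())


# ----------------------------------------------------------------------
# data preparation
# ----------------------------------------------------------------------
def _leaf_partials(data: np.ndarray) -> np.ndarray:
    """(n_taxa, n_cols, 4) indicator partials; missing rows are all-ones."""
    n_taxa, L = data.shape
    out = np.zeros((n_taxa, L, 4))
    for b in range(4):
        out[:, :, b] = data == b
    miss = data >= MISSING_THRESHOLD
    out[miss] = 1.0
    return out


def _compress(data: np.ndarray):
    pats, inverse = np.unique(data, axis=1, return_inverse=True)
    return pats, inverse


def _resolve(matrix, taxa):
    if isinstance(matrix, ConcatenatedMatrix):
        return matrix.data, matrix.taxa
    data = np.asarray(matrix)
    if taxa is None:
        taxa = [f"t{i}" for i in range(data.shape[0])]
    return data, list(taxa)


class _Pruner:
    """Cached pruning engine for one (data, model) pair; topology and branch
    lengths vary between calls."""

    def __init__(self, data: np.ndarray, taxa: Sequence[str],
                 model: SubstitutionModel):
        self.taxa = list(taxa)
        self.model = model
        self.pats, self.inverse = _compress(data)
        self.partials = _leaf_partials(self.pats)
        self.index = {t: i for i, t in enumerate(self.taxa)}
        self.rates, self.rate_weights = model.site_rate_mixture()
        self.counts = None  # lazily built pattern counts

    def set_model(self, model: SubstitutionModel) -> None:
        """Swap the substitution model without re-deriving site patterns."""
        self.model = model
        self.rates, self.rate_weights = model.site_rate_mixture()

    def pattern_lnl(self, tree: Tree) -> np.ndarray:
        P = self.pats.shape[1]
        per_cat = np.empty((self.rates.size, P))
        for k, rate in enumerate(self.rates):
            per_cat[k] = self._lnl_one_rate(tree, rate)
        return logsumexp(per_cat, axis=0, b=self.rate_weights[:, None])

    def _lnl_one_rate(self, tree: Tree, rate: float) -> np.ndarray:
        model = self.model
        P = self.pats.shape[1]
        log_scale = np.zeros(P)
        partial: dict[int, np.ndarray] = {}
        for node in tree.postorder():
            if node.is_leaf:
                partial[id(node)] = self.partials[self.index[node.label]]
                continue
            acc = np.ones((P, 4))
            for c in node.children:
                t = (c.length or 0.0) * rate
                Pm = model.transition_matrix(t)
                acc = acc * (partial[id(c)] @ Pm.T)
            mx = acc.max(axis=1)
            mx[mx == 0] = 1.0  # fully impossible pattern; lnL -> -inf below
            acc /= mx[:, None]
            log_scale += np.log(mx)
            partial[id(node)] = acc
        root_lik = partial[id(tree.root)] @ model.freqs
        with np.errstate(divide="ignore"):
            return np.log(root_lik) + log_scale

    def site_lnl(self, tree: Tree) -> np.ndarray:
        return self.pattern_lnl(tree)[self.inverse]

    def total_lnl(self, tree: Tree) -> float:
        counts = np.bincount(self.inverse, minlength=self.pats.shape[1])
        return float(self.pattern_lnl(tree) @ counts)


def pruning_lnL(tree: Tree, matrix, model: SubstitutionModel,
                taxa: Optional[Sequence[str]] = None,
                tree_id: str = "tree") -> SiteLikelihoods:
    """Per-site log-likelihood by post-order pruning with the +I/+G mixture.

    Missing states integrate over all four bases. Branch lengths are read
    from the tree; `None` lengths count as zero.
    """
    data, taxa = _resolve(matrix, taxa)
    if set(tree.leaf_labels) != set(taxa):
        raise ValueError("tree leaves do not match matrix taxa")
    pruner = _Pruner(data, taxa, model)
    sl = SiteLikelihoods(tree_id, pruner.site_lnl(tree))
    if not np.all(np.isfinite(sl.site_lnl)):  # pragma: no cover - guard
        raise FloatingPointError("non-finite site log-likelihood")
    return sl


# ----------------------------------------------------------------------
# branch-length optimization
# ----------------------------------------------------------------------
def optimize_branch_lengths(topology: Tree, matrix, model: SubstitutionModel,
                            taxa: Optional[Sequence[str]] = None,
                            tol: float = 1e-6, max_sweeps: int = 20,
                            pruner: Optional[_Pruner] = None
                            ) -> tuple[Tree, float]:
    """Coordinate-wise numeric maximization of lnL over branch lengths.

    Sweeps Brent optimization over every branch until the lnL gain of a full
    sweep drops below `tol` (relative); lnL never decreases across sweeps.
    """
    data, taxa = _resolve(matrix, taxa)
    tree = topology.copy()
    for node in tree.postorder():
        if node.parent is not None and (node.length is None or node.length <= 0):
            node.length = 0.05
    if pruner is None:
        pruner = _Pruner(data, taxa, model)
    counts = np.bincount(pruner.inverse, minlength=pruner.pats.shape[1])

    def total(t: Tree) -> float:
        return float(pruner.pattern_lnl(t) @ counts)

    cur = total(tree)
    branches = [n for n in tree.postorder() if n.parent is not None]
    for _ in range(max_sweeps):
        before = cur
        for node in branches:
            original = node.length

            def neg(x):
                node.length = x
                return -total(tree)

            res = minimize_scalar(neg, bounds=(_MIN_BL, _MAX_BL),
                                  method="bounded",
                                  options={"xatol": max(1e-8, tol * 1e-3),
                                           "maxiter": 60})
            if -res.fun >= cur:
                node.length = float(res.x)
                cur = -res.fun
            else:
                node.length = original
        if cur - before <= tol * max(1.0, abs(cur)):
            break
    return tree, cur


# ----------------------------------------------------------------------
# model fitting and AIC selection
# ----------------------------------------------------------------------
def empirical_frequencies(data: np.ndarray) -> np.ndarray:
    counts = np.array([(data == b).sum() for b in range(4)], dtype=float)
    if counts.sum() == 0:
        return np.full(4, 0.25)
    return counts / counts.sum()


def _build_model(family: str, freqs, theta: np.ndarray,
                 plus_i: bool, plus_g: bool) -> SubstitutionModel:
    i = 0
    kwargs = {}
    if family in ("K80", "HKY"):
        kwargs["kappa"] = math.exp(theta[i]); i += 1
    if family == "GTR":
        kwargs["rates"] = np.append(np.exp(theta[i:i + 5]), 1.0); i += 5
    p_inv = 0.0
    if plus_i:
        p_inv = 1.0 / (1.0 + math.exp(-theta[i])) * 0.95; i += 1
    alpha = None
    if plus_g:
        alpha = math.exp(theta[i]); i += 1
    m = SubstitutionModel(family=family,
                          freqs=freqs if family in ("HKY", "GTR") else np.full(4, 0.25),
                          p_inv=p_inv, alpha=alpha, **kwargs)
    m._fit_pinv = plus_i
    return m


def _n_theta(family: str, plus_i: bool, plus_g: bool) -> int:
    base = {"JC": 0, "K80": 1, "HKY": 1, "GTR": 5}[family]
    return base + int(plus_i) + int(plus_g)


def fit_model(matrix, topology: Tree, family: str = "HKY",
              plus_i: bool = False, plus_g: bool = False,
              taxa: Optional[Sequence[str]] = None,
              n_rounds: int = 2) -> tuple[SubstitutionModel, Tree, float]:
    """Fit substitution-model parameters and branch lengths on a fixed
    topology (empirical base frequencies; alternating optimization)."""
    data, taxa = _resolve(matrix, taxa)
    freqs = empirical_frequencies(data)
    n_par = _n_theta(family, plus_i, plus_g)
    theta = np.zeros(n_par)
    if plus_g:
        theta[-1] = 0.0  # alpha = 1
    model = _build_model(family, freqs, theta, plus_i, plus_g)
    pruner = _Pruner(data, taxa, model)
    counts = np.bincount(pruner.inverse, minlength=pruner.pats.shape[1])
    tree, lnl = optimize_branch_lengths(topology, data, model, taxa=taxa,
                                        tol=1e-4, pruner=pruner)
    if n_par == 0:
        tree, lnl = optimize_branch_lengths(tree, data, model, taxa=taxa,
                                            pruner=pruner)
        return model, tree, lnl
    for _ in range(n_rounds):
        def neg(th):
            m = _build_model(family, freqs, th, plus_i, plus_g)
            pruner.set_model(m)
            return -float(pruner.pattern_lnl(tree) @ counts)

        res = minimize(neg, theta, method="Nelder-Mead",
                       options={"xatol": 1e-3, "fatol": 1e-3,
                                "maxiter": 200 * n_par})
        theta = res.x
        model = _build_model(family, freqs, theta, plus_i, plus_g)
        pruner.set_model(model)
        tree, lnl = optimize_branch_lengths(tree, data, model, taxa=taxa,
                                            tol=1e-5, pruner=pruner)
    return model, tree, lnl


_DEFAULT_CANDIDATES = [
    ("JC", False, False), ("JC", True, False), ("JC", False, True), ("JC", True, True),
    ("K80", False, False), ("K80", True, True),
    ("HKY", False, False), ("HKY", True, False), ("HKY", False, True), ("HKY", True, True),
    ("GTR", False, False), ("GTR", True, False), ("GTR", False, True), ("GTR", True, True),
]


def model_select_aic(matrix, topology: Tree,
                     candidates: Optional[Sequence[tuple]] = None,
                     taxa: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """AIC model selection on a fixed reference topology.

    AIC = -2 lnL + 2k with k = free model parameters + branch lengths.
    Returns the full ranked table; lowest AIC first.
    """
    data, taxa = _resolve(matrix, taxa)
    if candidates is None:
        candidates = _DEFAULT_CANDIDATES
    if not candidates:
        raise ValueError("need >= 1 candidate model")
    n_branches = sum(1 for n in topology.postorder() if n.parent is not None)
    rows = []
    for family, plus_i, plus_g in candidates:
        model, tree, lnl = fit_model(matrix, topology, family, plus_i, plus_g,
                                     taxa=taxa)
        k = model.n_free_parameters() + n_branches
        rows.append({"model": model.label(), "lnL": lnl, "k": k,
                     "AIC": -2.0 * lnl + 2.0 * k,
                     "family": family, "plus_i": plus_i, "plus_g": plus_g})
    df = pd.DataFrame(rows).sort_values("AIC").reset_index(drop=True)
    df["dAIC"] = df["AIC"] - df["AIC"].iloc[0]
    df["best"] = df["dAIC"] == 0.0
    return df


# ----------------------------------------------------------------------
# ML tree search
# ----------------------------------------------------------------------
def _nni_trees(tree: Tree) -> list[Tree]:
    """NNI neighbors of an unrooted tree (branch lengths carried over)."""
    from .parsimony import tree_to_adj, adj_to_tree, nni_neighbors
    taxa = sorted(tree.leaf_labels)
    adj = tree_to_adj(tree, taxa)
    out = []
    n = len(taxa)
    for cand in nni_neighbors(adj, n):
        t = adj_to_tree(cand, taxa)
        for node in t.postorder():
            if node.parent is not None and node.length is None:
                node.length = 0.02
        out.append(t)
    return out


def ml_tree_search(matrix, model: SubstitutionModel, seed: int = 0,
                   taxa: Optional[Sequence[str]] = None,
                   start_tree: Optional[Tree] = None,
                   exhaustive_limit: int = 7) -> tuple[Tree, float]:
    """ML topology search: exhaustive scan at <= `exhaustive_limit` taxa,
    NNI hill-climbing with branch re-optimization otherwise."""
    data, taxa = _resolve(matrix, taxa)
    n = len(taxa)
    if n < 4:
        raise ValueError("need >= 4 taxa")
    pruner = _Pruner(data, taxa, model)
    if n <= exhaustive_limit:
        best, best_lnl = None, -math.inf
        for topo in enumerate_topologies(sorted(taxa)):
            t, lnl = optimize_branch_lengths(topo, data, model, taxa=taxa,
                                             tol=1e-5, pruner=pruner)
            if lnl > best_lnl:
                best, best_lnl = t, lnl
        return best, best_lnl
    if start_tree is None:
        from .parsimony import mp_search
        trees, _ = mp_search(ConcatenatedMatrix(
            taxa=list(taxa), data=data,
            site_annotation=np.zeros(data.shape[1], dtype=np.int8),
            gene_spans=[("all", 0, data.shape[1])]),
            strategy="tbr_heuristic", n_addition_replicates=2, seed=seed)
        start_tree = trees[0]
    cur, cur_lnl = optimize_branch_lengths(start_tree, data, model, taxa=taxa,
                                           tol=1e-5, pruner=pruner)
    counts = np.bincount(pruner.inverse, minlength=pruner.pats.shape[1])

    def quick_lnl(t: Tree) -> float:
        """Screen a candidate cheaply: optimize internal branches only,
        one sweep, at loose tolerance."""
        for node in t.postorder():
            if node.parent is not None and (node.length is None or
                                            node.length <= 0):
                node.length = 0.01
        best = float(pruner.pattern_lnl(t) @ counts)
        for node in t.postorder():
            if node.parent is None or node.is_leaf:
                continue
            def neg(x):
                node.length = x
                return -float(pruner.pattern_lnl(t) @ counts)
            res = minimize_scalar(neg, bounds=(_MIN_BL, 1.0), method="bounded",
                                  options={"xatol": 1e-4, "maxiter": 12})
            if -res.fun >= best:
                node.length = float(res.x)
                best = -res.fun
        return best

    improved = True
    while improved:
        improved = False
        scored = sorted(((quick_lnl(c), c) for c in _nni_trees(cur)),
                        key=lambda p: -p[0])
        for q, cand in scored[:3]:
            if q < cur_lnl - 2.0:   # hopeless even after full optimization
                continue
            t, lnl = optimize_branch_lengths(cand, data, model, taxa=taxa,
                                             tol=1e-4, max_sweeps=3,
                                             pruner=pruner)
            if lnl > cur_lnl + 1e-6:
                cur, cur_lnl = t, lnl
                improved = True
                break
    cur, cur_lnl = optimize_branch_lengths(cur, data, model, taxa=taxa,
                                           tol=1e-7, pruner=pruner)
    return cur, cur_lnl


# ----------------------------------------------------------------------
# molecular clock
# ----------------------------------------------------------------------
def _clock_tree_from_params(rooted: Tree, order: list, theta: np.ndarray) -> Tree:
    """Assign branch lengths from (log root height, logit age fractions)."""
    t = rooted
    ages = {}
    root_age = math.exp(theta[0])
    for k, node in enumerate(order):
        if node.parent is None:
            ages[id(node)] = root_age
        else:
            frac = 1.0 / (1.0 + math.exp(-theta[k]))
            ages[id(node)] = ages[id(node.parent)] * frac
    for node in t.preorder():
        if node.is_leaf:
            age = 0.0
        else:
            age = ages[id(node)]
        if node.parent is not None:
            node.length = max(ages[id(node.parent)] - age, 0.0)
    return t


def fit_clock(matrix, rooted_topology: Tree, model: SubstitutionModel,
              taxa: Optional[Sequence[str]] = None) -> tuple[Tree, float]:
    """ML fit of node heights under a strict clock on a rooted topology."""
    data, taxa = _resolve(matrix, taxa)
    tree = rooted_topology.copy()
    internal = [n for n in tree.preorder() if not n.is_leaf]
    pruner = _Pruner(data, taxa, model)
    counts = np.bincount(pruner.inverse, minlength=pruner.pats.shape[1])
    n_par = len(internal)
    x0 = np.full(n_par, 0.0)
    x0[0] = math.log(max(tree.total_length() / 2.0, 1e-3))

    def neg(theta):
        t = _clock_tree_from_params(tree, internal, theta)
        return -float(pruner.pattern_lnl(t) @ counts)

    res = minimize(neg, x0, method="Powell",
                   options={"maxiter": 200 * n_par, "xtol": 1e-6,
                            "ftol": 1e-9})
    res2 = minimize(neg, res.x, method="Nelder-Mead",
                    options={"maxiter": 100 * n_par, "xatol": 1e-6,
                             "fatol": 1e-8})
    if res2.fun < res.fun:
        res = res2
    best = _clock_tree_from_params(tree, internal, res.x)
    return best.copy(), -float(res.fun)


def clock_lrt(matrix, topology: Tree, model: SubstitutionModel, root: str,
              taxa: Optional[Sequence[str]] = None) -> tuple[float, int, float]:
    """Likelihood-ratio test of a global molecular clock.

    statistic = 2 (lnL_free - lnL_clock); df = n_taxa - 2 (2n-3 free branch
    lengths versus n-1 node heights); p from the chi-square upper tail.
    """
    data, taxa = _resolve(matrix, taxa)
    free_tree, lnl_free = optimize_branch_lengths(topology, data, model,
                                                  taxa=taxa, tol=1e-7)
    rooted = free_tree.unroot().root_at_edge_to(root)
    clock_tree, lnl_clock = fit_clock(data, rooted, model, taxa=taxa)
    if lnl_clock > lnl_free + 1e-3:
        raise RuntimeError("clock lnL exceeds unconstrained lnL: optimizer "
                           "failure")
    stat = max(2.0 * (lnl_free - lnl_clock), 0.0)
    df = len(taxa) - 2
    p = float(chi2.sf(stat, df))
    return stat, df, p


# ----------------------------------------------------------------------
# RELL topology tests
# ----------------------------------------------------------------------
def topology_tests(site_lnls: Sequence[SiteLikelihoods], n_rell: int = 10000,
                   seed: int = 0) -> pd.DataFrame:
    """KH, SH and WSH tests by RELL resampling of per-site log-likelihoods.

    KH compares each tree with the observed best via centered RELL
    differences; SH compares against the max over trees (the best tree's SH
    p-value is 1 by construction); WSH standardizes each tree's statistic by
    its RELL standard deviation.
    """
    if len(site_lnls) < 2:
        raise ValueError("need >= 2 candidate trees")
    S = site_lnls[0].site_lnl.size
    if any(sl.site_lnl.size != S for sl in site_lnls):
        raise ValueError("trees with differing site counts")
    M = np.stack([sl.site_lnl for sl in site_lnls])  # (T, S)
    totals = M.sum(axis=1)
    best = int(np.argmax(totals))
    delta = totals[best] - totals          # (T,), >= 0
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, S, size=(n_rell, S))
    R = M[:, idx].sum(axis=2).T            # (n_rell, T) replicate totals
    Rc = R - R.mean(axis=0, keepdims=True)  # centered per tree
    d = Rc[:, [best]] - Rc                 # (n_rell, T) centered pairwise diffs
    sd = d.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    p_kh = (d >= delta[None, :]).mean(axis=0)
    worst = (Rc.max(axis=1, keepdims=True) - Rc)  # (n_rell, T)
    p_sh = (worst >= delta[None, :]).mean(axis=0)
    z = delta / sd
    Mstat = (d / sd[None, :]).max(axis=1, keepdims=True)
    p_wsh = (Mstat >= z[None, :]).mean(axis=0)
    df = pd.DataFrame({
        "tree": [sl.tree_id for sl in site_lnls],
        "lnL": totals,
        "delta": delta,
        "p_KH": p_kh, "p_SH": p_sh, "p_WSH": p_wsh,
        "best": [i == best for i in range(len(site_lnls))],
    })
    return df


# ----------------------------------------------------------------------
# dating
# ----------------------------------------------------------------------
def mrca(tree: Tree, labels: Sequence[str]):
    want = set(labels)
    below: dict[int, set] = {}
    for node in tree.postorder():
        if node.is_leaf:
            below[id(node)] = {node.label}
        else:
            below[id(node)] = set().union(*(below[id(c)] for c in node.children))
        if want <= below[id(node)]:
            return node
    raise ValueError(f"labels {want} not all present")


def date_nodes(clock_tree: Tree, calibration: Sequence[str],
               min_age: float = 1.81) -> tuple[Tree, dict[frozenset, float]]:
    """Strict-clock dating against one fossil minimum age (used as a point
    calibration): all node heights are scaled so the calibrated node's age
    equals `min_age`; ages returned in MY keyed by clade."""
    if not clock_tree.is_ultrametric(rel_tol=1e-4):
        raise ValueError("tree is not ultrametric (clock-constrained)")
    t = clock_tree.copy()
    cal_node = mrca(t, calibration)
    if cal_node.is_leaf:
        raise ValueError("calibration node is a leaf")
    heights = t.node_heights()
    h_cal = heights[id(cal_node)]
    if h_cal <= 0:
        raise ValueError("calibrated node has zero height")
    scale = min_age / h_cal
    ages: dict[frozenset, float] = {}
    below: dict[int, frozenset] = {}
    for node in t.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset([node.label])
        else:
            below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))
            age = heights[id(node)] * scale
            node.annotations["age"] = age
            ages[below[id(node)]] = age
        if node.parent is not None and node.length is not None:
            node.length = node.length * scale
    return t, ages
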