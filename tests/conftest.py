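import itertools

import numpy as np
import pytest

from phylopipe.seqmodels import SubstitutionModel
from phylopipe.simulate import SimulationConfig, simulate_alignments
from phylopipe.supermatrix import concatenate, encode_rows
from phylopipe.tree import Tree, random_topology


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def six_taxon_truth():
    """A fixed 6-taxon tree with clean JC data simulated along it."""
    tree = Tree.from_newick(
        "((A:0.06,B:0.06):0.05,(C:0.06,D:0.06):0.05,(E:0.06,F:0.06):0.05);")
    cfg = SimulationConfig(tree=tree, n_genes=2, length_range=(1500, 1500),
                           exon_fraction=1.0, model=SubstitutionModel("JC"),
                           missing_fraction=0.0, seed=77,
                           gene_rate_multipliers=[1.0, 1.0])
    sim = simulate_alignments(cfg)
    return tree, concatenate(sim.genes)


def brute_force_fitch(tree, rows, taxa):
    """Exhaustive minimization over all internal- and ambiguous-leaf-state
    assignments; the independent oracle for Fitch scoring."""
    from phylopipe.parsimony import tree_to_adj, encode_bitmasks
    adj = tree_to_adj(tree, taxa)
    n = len(taxa)
    internals = [u for u in adj if u >= n]
    edges = [(u, v) for u in adj for v in adj[u] if u < v]
    bits = encode_bitmasks(encode_rows(rows))
    total = 0
    for col in range(bits.shape[1]):
        opts = [[s for s in range(4) if bits[i, col] >> s & 1]
                for i in range(n)]
        best = 10 ** 9
        for assign in itertools.product(range(4), repeat=len(internals)):
            amap = dict(zip(internals, assign))
            for leafassign in itertools.product(*opts):
                full = dict(amap)
                full.update(dict(zip(range(n), leafassign)))
                cost = sum(1 for u, v in edges if full[u] != full[v])
                if cost < best:
                    best = cost
        total += best
    return total


def brute_force_lnl(tree, data, taxa, model):
    """Sum over all internal-node state assignments with exact transition
    probabilities; the independent oracle for pruning likelihoods."""
    import math
    nodes = list(tree.postorder())
    internals = [node for node in nodes if not node.is_leaf]
    rates, wts = model.site_rate_mixture()
    idx = {t: i for i, t in enumerate(taxa)}
    L = data.shape[1]
    out = np.zeros(L)
    for col in range(L):
        lik = 0.0
        for r, w in zip(rates, wts):
            P = {id(n): model.transition_matrix((n.length or 0.0) * r)
                 for n in nodes if n.parent is not None}
            tot = 0.0
            for assign in itertools.product(range(4), repeat=len(internals)):
                amap = {id(n): s for n, s in zip(internals, assign)}
                pr = model.freqs[amap[id(tree.root)]]
                for n in nodes:
                    if n.parent is None:
                        continue
                    if n.is_leaf:
                        obs = data[idx[n.label], col]
                        if obs < 4:
                            pr *= P[id(n)][amap[id(n.parent)], obs]
                    else:
                        pr *= P[id(n)][amap[id(n.parent)], amap[id(n)]]
                tot += pr
            lik += w * tot
        out[col] = math.log(lik)
    return out
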