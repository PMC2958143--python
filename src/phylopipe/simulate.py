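"""Synthetic-data generators: fixture proteomes with planted paralogs,
multi-gene nucleotide alignments simulated along a known tree, and discrete
trait matrices evolved under the Mk model.

Every generator is deterministic given its seed and records machine-readable
truth (labels, generating tree, per-gene models and rates, true internal
states) so downstream inference stages can be tested for recovery.

Default shapes emulate a low-divergence ingroup of ~13 cyprinid-like taxa
with ~100 nuclear loci of a few hundred bp, ~70% exon content, a roughly
2x faster intron rate, a distant outgroup, and sporadic whole-locus missing
data per taxon.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import yaml

from .seqmodels import SubstitutionModel, discrete_gamma_rates, mk_transition_matrix
from .supermatrix import GeneAlignment, _default_annotation, INTRON, DECODE
from .traits import TraitMatrix
from .tree import Tree

__all__ = [
    "GenomeFixture",
    "SimulationConfig",
    "SimulatedAlignments",
    "simulate_genome",
    "simulate_alignments",
    "simulate_traits",
    "default_study_tree",
]

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


# ----------------------------------------------------------------------
# proteome fixture
# ----------------------------------------------------------------------
@dataclass
class GenomeFixture:
    """Fixture proteome with known single-copy genes and planted paralogs."""

    records: list[tuple[str, str]]          # (gene id, amino-acid sequence)
    truth: dict[str, str]                   # id -> single_copy | paralog_member
    paralog_pairs: list[tuple[str, str, float, float]]  # (id, id, sim%, cov%)

    def __post_init__(self):
        ids = [r[0] for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate gene ids")
        members = [i for pair in self.paralog_pairs for i in pair[:2]]
        if len(set(members)) != len(members):
            raise ValueError("a paralog member appears in more than one pair")
        for gid, seq in self.records:
            if not seq or set(seq) - set(AMINO_ACIDS.tolist()):
                raise ValueError(f"invalid amino-acid sequence for {gid}")

    def sequences(self) -> dict[str, str]:
        return dict(self.records)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for gid, seq in self.records:
                fh.write(f">{gid}\n{seq}\n")

    def write_truth(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"truth": self.truth,
                       "paralog_pairs": self.paralog_pairs}, fh, indent=1)


def simulate_genome(n_single: int, n_pairs: int,
                    length_range: tuple[int, int] = (200, 400),
                    similarity_targets: Union[float, Sequence[float]] = 80.0,
                    seed: int = 0,
                    coverage_target: float = 100.0) -> GenomeFixture:
    """Generate a fixture proteome: unrelated single-copy genes plus
    duplicated-then-mutated paralog pairs at given target percent identity."""
    if n_single < 0 or n_pairs < 0:
        raise ValueError("counts must be non-negative")
    if n_single + n_pairs == 0:
        raise ValueError("empty fixture requested")
    lo, hi = length_range
    if lo <= 0 or hi < lo:
        raise ValueError("invalid length range")
    if np.isscalar(similarity_targets):
        similarity_targets = [float(similarity_targets)] * n_pairs
    similarity_targets = [float(s) for s in similarity_targets]
    if len(similarity_targets) != n_pairs:
        raise ValueError("one similarity target per pair required")
    if any(not (0 < s <= 100) for s in similarity_targets):
        raise ValueError("similarity targets must be in (0,100]")
    if not (0 < coverage_target <= 100):
        raise ValueError("coverage target must be in (0,100]")

    rng = np.random.default_rng(seed)
    records: list[tuple[str, str]] = []
    truth: dict[str, str] = {}
    pairs: list[tuple[str, str, float, float]] = []

    def random_seq(length: int) -> str:
        return "".join(rng.choice(AMINO_ACIDS, size=length))

    for i in range(n_single):
        gid = f"sc{i:04d}"
        records.append((gid, random_seq(int(rng.integers(lo, hi + 1)))))
        truth[gid] = "single_copy"

    for i, target in enumerate(similarity_targets):
        length = int(rng.integers(lo, hi + 1))
        a = random_seq(length)
        n_cov = max(1, int(round(length * coverage_target / 100.0)))
        # mutate the duplicated region; draw replacements from the other 19
        # letters so realized identity tracks the target
        region = np.array(list(a[:n_cov]))
        mutate = rng.random(n_cov) < (1.0 - target / 100.0)
        for k in np.flatnonzero(mutate):
            choices = AMINO_ACIDS[AMINO_ACIDS != region[k]]
            region[k] = rng.choice(choices)
        b = "".join(region) + random_seq(length - n_cov)
        ida, idb = f"par{i:04d}a", f"par{i:04d}b"
        records.append((ida, a))
        records.append((idb, b))
        truth[ida] = truth[idb] = "paralog_member"
        pairs.append((ida, idb, target, coverage_target))

    return GenomeFixture(records=records, truth=truth, paralog_pairs=pairs)


# ----------------------------------------------------------------------
# sequence alignments
# ----------------------------------------------------------------------
@dataclass
class SimulationConfig:
    """Shape and model parameters for multi-gene alignment simulation."""

    tree: Tree
    n_genes: int = 100
    length_range: tuple[int, int] = (300, 1500)
    exon_fraction: float = 0.7
    model: Union[SubstitutionModel, dict, None] = None  # or {"exon":m, "intron":m}
    intron_rate_multiplier: float = 2.0
    gene_rate_multipliers: Optional[np.ndarray] = None  # drawn lognormal if None
    gene_rate_sigma: float = 0.4
    missing_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.exon_fraction <= 1.0):
            raise ValueError("exon_fraction must be in [0,1]")
        if not (0.0 <= self.missing_fraction <= 1.0):
            raise ValueError("missing_fraction must be in [0,1]")
        if self.intron_rate_multiplier <= 0:
            raise ValueError("rate multipliers must be positive")
        if self.n_genes < 1:
            raise ValueError("need >= 1 gene")
        if self.tree.n_leaves() < 3:
            raise ValueError("tree needs >= 3 leaves")
        for node in self.tree.postorder():
            if node.parent is not None and (node.length is None or node.length < 0):
                raise ValueError("tree must have non-negative branch lengths")
        if self.model is None:
            self.model = SubstitutionModel("HKY", freqs=np.array([0.26, 0.26, 0.24, 0.24]),
                                           kappa=2.0, alpha=0.8)
        if self.gene_rate_multipliers is not None:
            m = np.asarray(self.gene_rate_multipliers, dtype=float)
            if m.size != self.n_genes or np.any(m <= 0):
                raise ValueError("need one positive multiplier per gene")
            self.gene_rate_multipliers = m

    def model_for(self, klass: str) -> SubstitutionModel:
        if isinstance(self.model, dict):
            return self.model[klass]
        return self.model

    def to_yaml(self, path) -> None:
        d = {
            "n_genes": self.n_genes,
            "length_range": list(self.length_range),
            "exon_fraction": self.exon_fraction,
            "intron_rate_multiplier": self.intron_rate_multiplier,
            "missing_fraction": self.missing_fraction,
            "gene_rate_sigma": self.gene_rate_sigma,
            "seed": self.seed,
            "tree": self.tree.to_newick(),
            "model": {k: m.label() for k, m in self.model.items()}
            if isinstance(self.model, dict) else self.model.label(),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)


@dataclass
class SimulatedAlignments:
    genes: list[GeneAlignment]
    truth: dict                     # gene id -> {model, rate_multiplier, ...}
    tree: Tree
    config: SimulationConfig

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for g in self.genes:
            g.to_fasta(outdir / f"{g.gene_id}.fasta")
            np.savetxt(outdir / f"{g.gene_id}.annotation.tsv",
                       g.site_annotation[None, :], fmt="%d", delimiter="\t")
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1)
        with open(outdir / "true_tree.nwk", "w") as fh:
            fh.write(self.tree.to_newick() + "\n")
        self.config.to_yaml(outdir / "config.yaml")


def _simulate_states_along_tree(tree: Tree, model: SubstitutionModel,
                                site_rates: np.ndarray,
                                rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Simulate base codes (0-3) for every leaf, site-by-site along the tree.

    `site_rates` multiplies every branch length per site; sites sharing a rate
    are propagated together with one transition matrix per branch.
    """
    n_sites = site_rates.size
    uniq, inverse = np.unique(site_rates, return_inverse=True)
    pi = model.freqs
    root_states = rng.choice(4, size=n_sites, p=pi)
    states: dict[int, np.ndarray] = {id(tree.root): root_states}
    leaves: dict[str, np.ndarray] = {}
    for node in tree.preorder():
        if node.parent is None:
            cur = root_states
        else:
            parent_states = states[id(node.parent)]
            cur = np.empty(n_sites, dtype=np.int64)
            t = node.length or 0.0
            for k, r in enumerate(uniq):
                sel = inverse == k
                if not sel.any():
                    continue
                P = model.transition_matrix(t * r)
                cum = P.cumsum(axis=1)
                u = rng.random(int(sel.sum()))
                cur[sel] = (u[:, None] > cum[parent_states[sel]]).sum(axis=1)
            states[id(node)] = cur
        if node.is_leaf:
            leaves[node.label] = cur
    return leaves


def simulate_alignments(config: SimulationConfig) -> SimulatedAlignments:
    """Simulate `config.n_genes` loci along `config.tree`.

    Per gene: length uniform in `length_range`; leading exon block (codon
    positions cycling) and trailing intron; intron sites evolve faster by
    `intron_rate_multiplier`; discrete-gamma site rates drawn per site; whole
    (taxon, gene) cells blanked to '?' with probability `missing_fraction`.
    """
    rng = np.random.default_rng(config.seed)
    tree = config.tree
    taxa = tree.leaf_labels
    if config.gene_rate_multipliers is not None:
        gene_rates = np.asarray(config.gene_rate_multipliers, dtype=float)
    else:
        gene_rates = np.exp(rng.normal(0.0, config.gene_rate_sigma, config.n_genes))
        gene_rates /= gene_rates.mean()
    genes = []
    truth: dict = {"gene_rate_multipliers": {}, "models": {},
                   "tree": tree.to_newick(), "missing_cells": []}
    lo, hi = config.length_range
    for gi in range(config.n_genes):
        gid = f"gene{gi:03d}"
        length = int(rng.integers(lo, hi + 1))
        ann = _default_annotation(length, config.exon_fraction)
        is_intron = ann == INTRON
        site_rates = np.full(length, gene_rates[gi])
        site_rates[is_intron] *= config.intron_rate_multiplier
        model_exon = config.model_for("exon")
        model_intron = config.model_for("intron")
        # gamma heterogeneity: category draw per site from the exon model's
        # shape (shared shape across classes keeps the unit interpretable)
        for klass, model, sel in (("exon", model_exon, ~is_intron),
                                  ("intron", model_intron, is_intron)):
            if model.alpha is not None and sel.any():
                cat_rates = discrete_gamma_rates(model.alpha, model.n_cat)
                site_rates[sel] *= rng.choice(cat_rates, size=int(sel.sum()))
            if model.p_inv > 0 and sel.any():
                inv = rng.random(int(sel.sum())) < model.p_inv
                sub = site_rates[sel]
                sub[inv] = 0.0
                site_rates[sel] = sub
        if isinstance(config.model, dict):
            leaves_exon = _simulate_states_along_tree(
                tree, model_exon, site_rates[~is_intron], rng)
            leaves_intron = _simulate_states_along_tree(
                tree, model_intron, site_rates[is_intron], rng)
            leaf_states = {}
            for t in taxa:
                full = np.empty(length, dtype=np.int64)
                full[~is_intron] = leaves_exon[t]
                full[is_intron] = leaves_intron[t]
                leaf_states[t] = full
        else:
            base = _simulate_states_along_tree(tree, model_exon, site_rates, rng)
            leaf_states = base
        rows = []
        for t in taxa:
            rows.append("".join(DECODE[leaf_states[t]]))
        # whole-locus missing per taxon
        present_taxa, present_rows = [], []
        blanked = rng.random(len(taxa)) < config.missing_fraction
        if (~blanked).sum() < 3:   # keep the gene analyzable
            blanked[:] = False
        for t, row, b in zip(taxa, rows, blanked):
            present_taxa.append(t)
            present_rows.append("?" * length if b else row)
            if b:
                truth["missing_cells"].append([t, gid])
        genes.append(GeneAlignment(gid, present_taxa, present_rows, ann))
        truth["gene_rate_multipliers"][gid] = float(gene_rates[gi])
        truth["models"][gid] = {"exon": model_exon.label(),
                                "intron": model_intron.label()}
    return SimulatedAlignments(genes=genes, truth=truth, tree=tree, config=config)


# ----------------------------------------------------------------------
# discrete traits under Mk
# ----------------------------------------------------------------------
def simulate_traits(tree: Tree, n_chars: int,
                    state_counts: Union[int, Sequence[int]] = 2,
                    rate: float = 0.1, seed: int = 0,
                    names: Optional[Sequence[str]] = None) -> TraitMatrix:
    """Evolve `n_chars` independent characters under symmetric Mk along
    `tree`; true internal-node states are recorded keyed by clade."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    if np.isscalar(state_counts):
        state_counts = [int(state_counts)] * n_chars
    state_counts = [int(k) for k in state_counts]
    if len(state_counts) != n_chars or any(k < 2 for k in state_counts):
        raise ValueError("need >= 2 states per character")
    rng = np.random.default_rng(seed)
    taxa = tree.leaf_labels
    chars = list(names) if names is not None else [f"trait{j+1}" for j in range(n_chars)]
    states = np.zeros((len(taxa), n_chars), dtype=np.int16)
    tindex = {t: i for i, t in enumerate(taxa)}
    true_internal: dict[frozenset, np.ndarray] = {}
    clades: dict[int, frozenset] = {}
    for node in tree.postorder():
        if node.is_leaf:
            clades[id(node)] = frozenset([node.label])
        else:
            clades[id(node)] = frozenset().union(*(clades[id(c)] for c in node.children))
    node_states: dict[int, np.ndarray] = {}
    for j, k in enumerate(state_counts):
        for node in tree.preorder():
            if node.parent is None:
                s = int(rng.integers(k))
            else:
                P = mk_transition_matrix(k, rate, node.length or 0.0)
                parent_s = node_states[id(node.parent)][j]
                s = int(rng.choice(k, p=P[parent_s]))
            node_states.setdefault(id(node), np.zeros(n_chars, dtype=np.int16))[j] = s
    for node in tree.postorder():
        if node.is_leaf:
            states[tindex[node.label]] = node_states[id(node)]
        else:
            true_internal[clades[id(node)]] = node_states[id(node)].copy()
    return TraitMatrix(taxa=taxa, characters=chars, states=states,
                       state_counts=state_counts, true_internal=true_internal,
                       generating_tree=tree)


# ----------------------------------------------------------------------
# default study-shaped tree
# ----------------------------------------------------------------------
def default_study_tree(ingroup_depth: float = 0.004,
                       outgroup_length: float = 0.075,
                       seed: Optional[int] = None) -> Tree:
    """A 13-taxon tree shaped like the study system: a low-divergence,
    fully pectinate-free ingroup of 12 taxa (two clades of 5 and 6 plus a
    basal ingroup taxon) and one distant outgroup.

    `ingroup_depth` sets the typical internal branch length (expected
    substitutions/site). The defaults are calibrated so that, with the
    default simulation model (2x intron rate, lognormal gene rates),
    realized pairwise K2P distances fall near 0.01-0.05 within the ingroup
    and ~0.11 to the outgroup.
    """
    b = ingroup_depth
    nwk = (
        "(((((T01:{b},T02:{b}):{b},(T03:{b},(T04:{b},T05:{b}):{b}):{b}):{b},"
        "T06:{b2}):{b},((T07:{b},T08:{b}):{b},((T09:{b},T10:{b}):{b},"
        "(T11:{b},T12:{b}):{b}):{b}):{b}):{b},OUT:{out});"
    ).format(b=f"{b:.6f}", b2=f"{2*b:.6f}", out=f"{outgroup_length:.6f}")
    return Tree.from_newick(nwk, rooted=False)
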