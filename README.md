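# phylopipe

Supermatrix phylogenomics for recent, rapid radiations — built for the
situation where a clade of closely related species (pairwise K2P distances
of only 0.01–0.05) has defeated single-gene phylogenetics, and the remedy
is many single-copy nuclear loci concatenated into one partitioned matrix.
The package implements the full workflow as a tested, reusable library and
CLI: mining single-copy markers from a proteome, building the supermatrix
and its descriptive statistics, maximum parsimony with rich support
diagnostics, maximum likelihood with model selection and clock testing,
partitioned Bayesian inference with Bayes-factor comparison of partitioning
strategies, and ancestral-state reconstruction of discrete traits — plus
synthetic-data generators with recorded truth so every stage can be
validated end to end.

It is aimed at systematists who want the classic multi-gene workflow in one
scriptable place, and at methods people who want its components (Fitch/TBR
search, partitioned Bremer support, RELL topology tests, harmonic-mean
Bayes factors, Mk reconstruction) as plain Python functions with oracles.

## The statistics at its core

* **Marker mining.** All-vs-all protein alignment; a gene is single-copy
  only if every significant non-self hit has similarity S < 30% *and*
  query coverage C < 30%.
* **Supermatrix statistics.** Variable / parsimony-informative site
  counts, per-taxon base composition with a χ² homogeneity test
  (df = (n−1)·3), pooled Ti/Tv, and Kimura two-parameter distances
  d = −½ ln(1−2P−Q) − ¼ ln(1−2Q) with pairwise deletion.
* **Parsimony.** Fitch length minimized by branch-and-bound (exact, small
  n) or random-addition + TBR; nonparametric and *variable-length*
  bootstrap; Bremer decay b(e) = L(best tree without split e) − L(best);
  partitioned Bremer support with the exact identity Σ_p PBS_p(e) = b(e).
* **Likelihood.** Felsenstein pruning under JC/K80/HKY/GTR (+I, discrete
  Γ₄); AIC = −2 lnL + 2k model selection; clock LRT with 2ΔlnL ~ χ²(n−2);
  KH/SH/WSH topology tests by RELL resampling; strict-clock scaling to a
  fossil minimum age for node dates.
* **Bayesian inference.** MH-MCMC over topology, branch lengths and
  unlinked per-partition model parameters; 50% majority-rule consensus
  with split posterior probabilities; harmonic-mean marginal likelihoods
  and 2 ln BF on the Kass–Raftery scale (2lnBF > 10 decisive); symmetric
  Mk marginal ancestral states by exact message passing.

See `docs/methods.md` for assumptions, priors, numerical choices and
limitations.

## Worked example

Simulate a study-shaped dataset (13 taxa, 100 loci, ~70% exon, distant
outgroup), build the supermatrix, run a parsimony search with bootstrap,
and evaluate a published-scale Bayes-factor comparison:

```python
from phylopipe.simulate import default_study_tree, SimulationConfig, simulate_alignments
from phylopipe.supermatrix import concatenate, site_classes, distance_matrix
from phylopipe.parsimony import mp_search, bootstrap_support
from phylopipe.bayesian import bayes_factor
from phylopipe.tree import rf_distance

tree = default_study_tree()
sim = simulate_alignments(SimulationConfig(tree=tree, n_genes=100,
                                           length_range=(150, 450), seed=1))
matrix = concatenate(sim.genes)
sc = site_classes(matrix.data)
trees, score = mp_search(matrix, strategy="tbr_heuristic",
                         n_addition_replicates=3, seed=2)
table, _ = bootstrap_support(matrix, n_reps=50, seed=3,
                             reference_tree=trees[0])
bf = bayes_factor(-193798.37, -195500.09)
```

This prints (exact numbers for these seeds):

```
supermatrix: 13 taxa x 28746 bp; 4849 variable (16.9%), 1459 parsimony-informative (5.08%)
K2P: ingroup 0.0100-0.0461, mean to outgroup 0.1078
MP: best score 5646, 1 tree(s), RF distance to generating tree = 0
bootstrap: min 100%, median 100% over 10 splits
2lnBF(exon+intron vs single partition) = 3403.44 -> favor_model0
```

Reading it: the simulated matrix has the divergence profile of a recent
radiation (a few percent informative sites, ingroup K2P below 0.05); the
TBR search recovers the generating topology exactly (RF = 0) with every
split at 100% bootstrap; and the Bayes-factor arithmetic on two marginal
log-likelihoods yields 2lnBF = 3403.44, far beyond the decisive threshold
of 10, favoring the exon+intron partitioning (model 0).

The same workflow runs from the shell:

```bash
phylopipe synth --preset cyprinid13 --seed 1 --out data/
phylopipe run --config config.yaml          # full MP + ML + BI + ASR pipeline
phylopipe mine --fasta proteome.fasta --s-max 30 --c-max 30
```

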