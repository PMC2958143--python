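# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `phylopipe`. It is written for a reader who wants to know
exactly what each stage computes and what a passing test suite does and does
not demonstrate about real data.

## Problem setting

The package implements a supermatrix phylogenomic workflow for a
low-divergence clade: ~13 taxa scored at ~100 single-copy nuclear loci
(mixed exon/intron content), with a distant outgroup and sporadic
whole-locus missing data. At these divergences (pairwise K2P roughly
0.015–0.05 within the ingroup, ~0.11 to the outgroup) individual loci carry
little signal, so the workflow concatenates loci, quantifies per-node
support several ways, and cross-checks maximum parsimony, maximum
likelihood and Bayesian inference against each other.

## Synthetic data generators

All downstream stages are validated against data with recorded truth.

**Proteome fixture** (`simulate_genome`). Single-copy genes are i.i.d.
random amino-acid sequences; a paralog pair is a sequence plus a copy
mutated per site with probability `1 - target/100` (replacements drawn from
the 19 alternative residues), so realized identity tracks the target.
Coverage targets below 100% are produced by regenerating the tail of the
copy at random. Truth labels and pair metadata are stored with the records.

**Alignments** (`simulate_alignments`). Each locus draws its length
uniformly from `length_range` (default 300–1500 bp; the desk-scale test
configuration uses 150–450 bp so full MP+ML+Bayesian runs stay fast while
keeping the 13-taxon x 100-locus shape). Sites are annotated as a leading
exon block with cycling codon positions followed by an intron block
(default 70% exon). Evolution is simulated site by site along the
generating tree: the root state is drawn from the model's stationary
frequencies and child states from eigendecomposed transition matrices, so
simulated composition is stationary by construction. Rate heterogeneity
enters at three levels: a lognormal per-gene rate multiplier (sigma 0.4,
mean normalized to 1), a 2x intron multiplier reflecting the higher
variability of non-coding sequence, and optional discrete-gamma site rates.
Missing data is whole-locus: each (taxon, gene) cell is blanked to `?` with
probability `missing_fraction` (a gene always keeps at least three rows so
it remains analyzable). Indels, codon models and heterotachy are not
simulated.

**Traits** (`simulate_traits`). Characters evolve independently under the
symmetric k-state Mk model with a uniform root. The rate is expressed per
unit branch length of the supplied tree; since the generating tree's
branches are in substitutions/site (~0.01), morphologically plausible
change requires rates of order 1–5 — the pipeline default is 3.0, about one
expected change across the tree. True internal states are recorded keyed by
clade (leaf set), which survives any later re-rooting.

What passing recovery tests show: the estimators are correct under their
own model at study-like signal strengths. What they do not show: robustness
to alignment error, paralogy leakage, indel handling, model
misspecification beyond the exon/intron contrasts tested, or real
morphological correlation between characters.

## Marker mining

Six-frame translated database searches are replaced by all-vs-all local
protein alignment (Biopython `PairwiseAligner`, BLOSUM62, gap open −11 /
extend −1). A hit's similarity S is percent identity over the aligned
columns (gap columns included in the denominator); coverage C is the
aligned span as a percent of the *query* length — the literature leaves
both definitions open, so they are stated here and configurable.
Significance is a raw-score cutoff (default 80): Karlin–Altschul statistics
put the best local score between unrelated ~300-residue sequences near
40–50, so 80 corresponds to a stringent e-value while paralogs at ≥40%
identity score in the hundreds. The single-copy rule is strict: a gene is
retained only if *every* non-self significant hit has S < 30 **and**
C < 30; a hit breaching either threshold disqualifies. This reading makes
the filter monotone in both thresholds. The alternative reading (exclude
only when both thresholds are breached) is selectable via the thresholds
themselves. Orthology confirmation (`confirm_single_hit`) requires exactly
one significant non-self subject.

## Supermatrix statistics

Concatenation lays loci end to end in input order, filling absent taxa with
`?`. Five partitioning schemes are materialized: by gene, exon/intron,
codon positions + intron, seven equal-length blocks (balanced to ±1 site),
and a single partition. Conventions:

* `N`, `-` and `?` are all treated as missing in every statistic.
* Variable / parsimony-informative percentages use the total column count
  as denominator. (Published variable-site percentages for this kind of
  data sometimes disagree with their own printed counts; the convention
  here is fixed and stated rather than reverse-engineered.)
* Distances and Ti/Tv use pairwise deletion, since taxa lack whole loci.
* K2P: d = −½ ln(1−2P−Q) − ¼ ln(1−2Q); a non-positive logarithm argument
  marks the pair saturated (reported as infinite, never dropped).
* The chi-square homogeneity test compares each taxon's base counts with
  expectations from the pooled composition; df = (n_taxa − 1) × 3; zero-
  expectation cells contribute nothing.
* Saturation masking is a user-supplied per-gene column mask, not an
  automatic detector.

## Parsimony

Fitch scoring runs on bitmask state sets over compressed site patterns;
gaps and missing data are full wildcards and never add changes. Search
strategies: exhaustive enumeration (guarded above 10 taxa),
branch-and-bound by stepwise addition (exact; the partial-tree score is a
valid lower bound because adding leaves cannot reduce the minimum), and
random-addition greedy starts followed by TBR (or NNI) hill-climbing with
all tied topologies retained (pool capped at 64). Equally best trees found
across addition replicates are pooled by split-set signature.

Bootstrap resampling is implemented as multinomial reweighting of site
patterns (equivalent to resampling columns with replacement and much
faster); a replicate with several equally best trees contributes
fractionally to each split it supports. The variable-length bootstrap runs
the same machinery at a range of pseudo-matrix sizes, which may exceed the
matrix length. Desk-scale defaults swap TBR for NNI inside bootstrap
replicates; the reference search always uses TBR.

Bremer support searches for the best tree *not* containing each split:
exact enumeration at ≤8 taxa, otherwise constrained TBR started from NNI
rearrangements of the best tree that already break the split. Partitioned
Bremer support evaluates each partition's Fitch length on the
anti-constraint tree(s) minus its length on the best tree; with several
co-optimal anti-constraint trees the per-partition lengths are averaged
(switchable to first-found). Because all co-optimal trees share the same
total score, the identity sum(PBS) = decay holds exactly under either
convention, and `SupportTable` asserts it on every computation.

## Likelihood

Reversible models JC/K80/HKY/GTR with optional +I and discrete-gamma (four
equal-probability categories represented by conditional means; +I rescales
gamma rates by 1/(1−p_inv) so the model-wide mean rate stays 1 and branch
lengths remain in substitutions/site). Transition matrices come from the
symmetrized eigendecomposition computed once per model. Pruning uses
per-node rescaling by the pattern maximum, so likelihoods of the order
e^(−10^6) are representable.

Branch lengths are optimized coordinate-wise with bounded Brent sweeps
(bounds 10⁻⁹–20, sweep tolerance 10⁻⁶ relative by default); the sweep
accepts a proposal only if the total lnL does not decrease, so the
objective is monotone across iterations. Model parameters (empirical base
frequencies by default, following common model-selection practice) are fit
by Nelder–Mead on log/logit transforms, alternating with branch-length
sweeps. AIC = −2 lnL + 2k counts free model parameters plus branch
lengths. Note that AIC errs with the chi-square tail probability per
superfluous parameter (~9% for four extra parameters at one comparison),
so recovery of a generating model is expected in most, not all, replicates.

ML topology search scans all topologies at ≤7 taxa; above that it
NNI-climbs from the MP tree, screening candidates by a cheap internal-
branch-only pass and fully optimizing only the top few within 2 lnL of the
incumbent. The final tree is re-optimized at 10⁻⁷.

The clock LRT compares free branch lengths (2n−3 parameters) with a strict
clock on the rooted topology (n−1 node heights): statistic 2ΔlnL, df =
n−2, chi-square upper tail. Node heights are parameterized as a log root
height and logit age fractions, optimized by Powell with a Nelder–Mead
polish. The rooted topology comes from outgroup rooting; the test is only
correctly specified when the outgroup attaches at the true root, which the
default study tree guarantees.

Topology tests use RELL: per-site lnL vectors are resampled (10⁴ draws),
centered per tree, and compared — KH against the observed best tree, SH
against the per-replicate maximum (which makes the best tree's p exactly 1
and guarantees SH ≥ KH pointwise), WSH standardizing each tree's statistic
by its RELL standard deviation. AU and BP are deliberately omitted.

Dating is a declared simplification, not a relaxed-clock method: the
clock-constrained tree is linearly rescaled so the calibrated node (MRCA of
two named taxa) sits exactly at the fossil minimum age (1.81 MY by
default), treating the minimum as a point calibration. No rate
autocorrelation, no uncertainty intervals.

## Bayesian inference

Metropolis–Hastings over topology (uniform prior, NNI proposals with branch
lengths transplanted by matching splits), branch lengths (multiplier
proposals; exponential(rate 10) prior), and per-partition substitution
parameters, unlinked across partitions: Dirichlet(300·current) frequency
proposals, multiplier moves on kappa / GTR exchangeabilities / alpha,
reflected sliding window on p_inv in (0, 0.95). Priors: flat Dirichlet on
frequencies and exchangeabilities, exponential(0.1) on kappa,
exponential(1) on alpha, uniform p_inv. Optional incremental heating
(1/(1+λc), swap moves) is available but off by default at desk scale.
Desk-scale default runs are 10⁴–10⁵ generations; the full-scale
2,000,000-generation setting is a config value, not a code change.

Consensus: 50% majority rule over post-burn-in sampled trees (burn-in
counted in sampled trees), with compatible minority splits added in the
extended mode; split posterior probability is its sample frequency.

Marginal likelihoods use the harmonic-mean estimator in log space
(log-sum-exp of negated lnL values), *because that is the method under
study*; it is known to be unstable and biased upward, so the estimate is
returned with a dominance diagnostic (softmax weight of the most
influential sample — near 1 means the estimate hangs on one draw).
Stepping-stone or path sampling would be superior but are out of scope.
Bayes factors report lnBF, 2lnBF and a Kass–Raftery verdict (2lnBF > 10
decisive for model 0; < 0 favors model 1; the closed band including 0 is
reported inconclusive). Strategy comparisons start every chain from a quick
parsimony tree: the comparison is between marginal likelihoods, which an
unconverged chain underestimates, and a deliberately bad starting tree
would corrupt the harmonic mean rather than the posterior.

Ancestral states under symmetric Mk use exact up/down message passing for
marginal posteriors at every internal node (uniform root frequencies). The
default mode is empirical Bayes with the per-character rate fixed at its
ML value (1-D bounded search on log rate); the `mcmc` mode samples the rate
under an exponential(1) prior and averages the marginals. Characters with a
single observed state are skipped and reported. The reconstruction is
conditioned on a fixed tree (tree uncertainty is not integrated over).

## Pipeline

One YAML config drives all stages. A single global seed fans out to stages
via crc32("seed:stage"), so stages are independently reproducible; the
manifest records the config hash, stage seeds and versions, and two runs of
the same config produce identical manifests and summaries. A stage failure
is logged and isolated; artifacts of earlier stages survive. The 70%
bootstrap display threshold in the agreement table is a rendering rule
only — nothing is filtered by it.

Problem sizes in the default configuration (13 taxa, 100 loci of 150–450
bp, 60 bootstrap replicates with NNI swapping, 12,000-generation MCMC runs)
were chosen as the smallest sizes at which every stage's statistical
behavior is still measurable; all are config values.

## Known limitations

* The harmonic-mean marginal likelihood is noisy; with short desk-scale
  chains, 2lnBF values of order ±10–50 between near-equivalent models are
  not reliable (the decisive contrasts exercised in the tests are hundreds
  of units).
* Heuristic Bremer/PBS values above 8 taxa are upper bounds in principle
  (a missed anti-constraint optimum inflates decay), mitigated by
  multi-start constrained TBR.
* The clock LRT requires the outgroup to attach at the true root; rooting
  elsewhere makes the clock model misspecified and inflates rejection.
* Dating ignores calibration and rate uncertainty entirely, by design.
* AIC model selection fits frequencies empirically rather than by ML.
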