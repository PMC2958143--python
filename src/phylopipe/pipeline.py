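"""End-to-end orchestration: synthesize (or load) data, mine markers, build
the supermatrix and its statistics, run MP with bootstrap / variable-length
bootstrap / Bremer and partitioned Bremer support, ML with AIC model
selection, clock LRT, RELL topology tests and fossil-scaled dating, Bayesian
MCMC with partition-strategy Bayes factors, and Mk ancestral-state
reconstruction — all from one YAML config with a deterministic seed fan-out
and a provenance manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bayesian import (ancestral_states, bayes_factor,
                       compare_partition_strategies, consensus_with_pp,
                       harmonic_mean_lnL, mcmc_run)
from .likelihood import (SiteLikelihoods, clock_lrt, date_nodes, fit_clock,
                         fit_model, ml_tree_search, model_select_aic,
                         optimize_branch_lengths, pruning_lnL, topology_tests)
from .markers import all_vs_all_search, bin_by_exon_length, filter_single_copy
from .parsimony import (bootstrap_support, bremer_support, mp_search,
                        partitioned_bremer, variable_length_bootstrap)
from .seqmodels import SubstitutionModel
from .simulate import (SimulationConfig, default_study_tree, simulate_alignments,
                       simulate_genome, simulate_traits)
from .supermatrix import (base_composition, chi_square_homogeneity, concatenate,
                          distance_matrix, per_gene_report, site_classes,
                          ti_tv_ratio)
from .tree import Tree, rf_distance

logger = logging.getLogger("phylopipe")

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline",
           "topology_agreement", "default_config"]


def default_config(seed: int = 1, output_dir: str = "phylopipe_out") -> dict:
    """Desk-scale default configuration emulating the study shape: 13 taxa,
    100 loci (scaled lengths), ~70% exon content, sparse missing loci."""
    return {
        "seed": seed,
        "output_dir": output_dir,
        "stages": {"mine": True, "describe": True, "mp": True, "ml": True,
                   "bayes": True, "asr": True},
        "synthetic": {
            "n_genes": 100,
            "length_range": [150, 450],
            "exon_fraction": 0.7,
            "intron_rate_multiplier": 2.0,
            "missing_fraction": 0.05,
            "ingroup_depth": 0.004,
            "outgroup_length": 0.075,
            "genome": {"n_single": 15, "n_pairs": 5, "similarity": 75.0},
            "traits": {"n_chars": 4, "state_counts": [2, 3, 2, 2],
                       "rate": 3.0},
        },
        "mine": {"s_max": 30.0, "c_max": 30.0},
        "mp": {"n_addition_replicates": 4, "bootstrap_reps": 60,
               "vlb_sizes": [500, 2000, 8000, 30000], "vlb_reps": 24,
               "bremer": True},
        "ml": {"model_selection": False, "family": "HKY", "plus_g": True,
               "clock_root": "OUT", "calibration": ["T01", "T02"],
               "calibration_min_age": 1.81},
        "bayes": {"n_gens": 12000, "sample_every": 30, "n_runs": 2,
                  "burn_in_trees": 100,
                  "compare_strategies": ["exon_intron", "single"],
                  "bf_n_gens": 8000},
        "asr": {"mode": "pruning"},
    }


@dataclass
class PipelineConfig:
    raw: dict

    def __post_init__(self):
        known = {"seed", "output_dir", "stages", "synthetic", "inputs",
                 "mine", "mp", "ml", "bayes", "asr"}
        unknown = set(self.raw) - known
        if unknown:
            raise ValueError(f"invalid config keys: {sorted(unknown)}")
        if "seed" not in self.raw or "output_dir" not in self.raw:
            raise ValueError("config requires 'seed' and 'output_dir'")
        if "synthetic" not in self.raw and "inputs" not in self.raw:
            raise ValueError("config needs a 'synthetic' block or 'inputs'")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))

    @property
    def seed(self) -> int:
        return int(self.raw["seed"])

    def stage_seed(self, stage: str) -> int:
        """Stable per-stage seed: crc32 of 'seed:stage'."""
        return zlib.crc32(f"{self.seed}:{stage}".encode()) % (2**31)

    def stage_enabled(self, stage: str) -> bool:
        return bool(self.raw.get("stages", {}).get(stage, True))

    def section(self, name: str) -> dict:
        return self.raw.get(name, {}) or {}

    def config_hash(self) -> str:
        blob = json.dumps(self.raw, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class ReportBundle:
    output_dir: Path
    artifacts: dict = field(default_factory=dict)
    summary: dict = field(default_factory=dict)
    errors: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    def write_manifest(self) -> None:
        with open(self.output_dir / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=1, sort_keys=True)

    def add(self, stage: str, name: str, path: Path) -> None:
        self.artifacts.setdefault(stage, {})[name] = str(path)


def _synthesize(cfg: PipelineConfig, outdir: Path):
    syn = cfg.section("synthetic")
    tree = default_study_tree(
        ingroup_depth=syn.get("ingroup_depth", 0.004),
        outgroup_length=syn.get("outgroup_length", 0.075))
    sim_cfg = SimulationConfig(
        tree=tree,
        n_genes=syn.get("n_genes", 100),
        length_range=tuple(syn.get("length_range", [300, 1500])),
        exon_fraction=syn.get("exon_fraction", 0.7),
        intron_rate_multiplier=syn.get("intron_rate_multiplier", 2.0),
        missing_fraction=syn.get("missing_fraction", 0.05),
        seed=cfg.stage_seed("simulate"),
    )
    sim = simulate_alignments(sim_cfg)
    sim.write(outdir / "genes")
    g = syn.get("genome", {})
    fixture = simulate_genome(
        n_single=g.get("n_single", 15), n_pairs=g.get("n_pairs", 5),
        similarity_targets=g.get("similarity", 75.0),
        seed=cfg.stage_seed("genome"))
    fixture.to_fasta(outdir / "proteome.fasta")
    fixture.write_truth(outdir / "proteome_truth.json")
    tr = syn.get("traits", {})
    traits = simulate_traits(
        tree, n_chars=tr.get("n_chars", 4),
        state_counts=tr.get("state_counts", 2),
        rate=tr.get("rate", 3.0), seed=cfg.stage_seed("traits"))
    traits.to_tsv(outdir / "traits.tsv")
    return sim, fixture, traits


def run_pipeline(config: PipelineConfig | dict) -> ReportBundle:
    """Execute enabled stages in dependency order; a stage failure is
    recorded and earlier artifacts survive."""
    if isinstance(config, dict):
        config = PipelineConfig(config)
    outdir = Path(config.raw["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO,
                        format="%(asctime)s %(name)s %(message)s")
    fh = logging.FileHandler(outdir / "run.log")
    logger.addHandler(fh)
    bundle = ReportBundle(output_dir=outdir)
    bundle.manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stage_seeds": {s: config.stage_seed(s) for s in
                        ("simulate", "genome", "traits", "mine", "mp", "ml",
                         "bayes", "asr")},
        "versions": {"phylopipe": __version__,
                     "numpy": np.__version__},
        "config": config.raw,
    }

    # ---------------- synthesis / loading ----------------
    logger.info("stage: synthesize")
    sim, fixture, traits = _synthesize(config, outdir)
    true_tree = sim.tree
    bundle.add("synthesize", "genes", outdir / "genes")

    # ---------------- marker mining ----------------
    if config.stage_enabled("mine"):
        logger.info("stage: mine")
        try:
            mine_cfg = config.section("mine")
            table = all_vs_all_search(fixture.records)
            retained, _ = filter_single_copy(
                table, s_max=mine_cfg.get("s_max", 30.0),
                c_max=mine_cfg.get("c_max", 30.0))
            table.to_tsv(outdir / "hits.tsv")
            (outdir / "retained_genes.txt").write_text(
                "\n".join(sorted(retained)) + "\n")
            lengths = {gid: 3 * len(seq) for gid, seq in fixture.records}
            bins = bin_by_exon_length(lengths)
            pd.Series(bins).to_csv(outdir / "exon_length_bins.tsv", sep="\t")
            truth_single = {g for g, lab in fixture.truth.items()
                            if lab == "single_copy"}
            tp = len(retained & truth_single)
            precision = tp / len(retained) if retained else 0.0
            recall = tp / len(truth_single) if truth_single else 0.0
            bundle.summary["mine"] = {"n_retained": len(retained),
                                      "precision": precision,
                                      "recall": recall}
            bundle.add("mine", "hits", outdir / "hits.tsv")
        except Exception as exc:  # pragma: no cover - stage isolation
            logger.exception("mine stage failed")
            bundle.errors["mine"] = repr(exc)

    # ---------------- supermatrix / description ----------------
    matrix = concatenate(sim.genes)
    if config.stage_enabled("describe"):
        logger.info("stage: describe")
        try:
            matrix.write_nexus(outdir / "supermatrix.nex")
            sc = site_classes(matrix.data)
            stat, df_, p = chi_square_homogeneity(matrix)
            comp = base_composition(matrix)
            comp.to_csv(outdir / "base_composition.tsv", sep="\t")
            dm = distance_matrix(matrix, "k2p")
            dm.to_frame().to_csv(outdir / "k2p_distances.tsv", sep="\t")
            report = per_gene_report(sim.genes)
            report.to_csv(outdir / "per_gene_report.tsv", sep="\t", index=False)
            bundle.summary["describe"] = {
                "length": matrix.length,
                "n_variable": sc["n_variable"],
                "n_informative": sc["n_informative"],
                "pct_variable": sc["pct_variable"],
                "pct_informative": sc["pct_informative"],
                "chi2_stat": stat, "chi2_df": df_, "chi2_p": p,
                "ti_tv": ti_tv_ratio(matrix),
            }
            bundle.add("describe", "supermatrix", outdir / "supermatrix.nex")
        except Exception as exc:  # pragma: no cover
            logger.exception("describe stage failed")
            bundle.errors["describe"] = repr(exc)

    mp_tree = ml_tree = bi_tree = None
    mp_table = None
    pp = {}

    # ---------------- parsimony ----------------
    if config.stage_enabled("mp"):
        logger.info("stage: mp")
        try:
            mp_cfg = config.section("mp")
            seed = config.stage_seed("mp")
            trees, score = mp_search(
                matrix, strategy="tbr_heuristic",
                n_addition_replicates=mp_cfg.get("n_addition_replicates", 4),
                seed=seed)
            mp_tree = trees[0]
            with open(outdir / "mp_tree.nwk", "w") as f:
                f.write(mp_tree.to_newick(include_lengths=False) + "\n")
            mp_table, mp_consensus = bootstrap_support(
                matrix, n_reps=mp_cfg.get("bootstrap_reps", 60),
                seed=seed + 1, reference_tree=mp_tree)
            mp_table.to_tsv(outdir / "mp_bootstrap.tsv")
            vlb_sizes = mp_cfg.get("vlb_sizes")
            if vlb_sizes:
                vlb = variable_length_bootstrap(
                    matrix, sizes=vlb_sizes,
                    n_reps=mp_cfg.get("vlb_reps", 24), seed=seed + 2,
                    reference_tree=mp_tree)
                vlb.to_csv(outdir / "vlb_curve.tsv", sep="\t", index=False)
                bundle.add("mp", "vlb", outdir / "vlb_curve.tsv")
            if mp_cfg.get("bremer", True):
                pbs = partitioned_bremer(matrix, matrix.schemes["exon_intron"],
                                         mp_tree, seed=seed + 3)
                pbs.to_tsv(outdir / "pbs.tsv")
                bundle.add("mp", "pbs", outdir / "pbs.tsv")
            bundle.summary["mp"] = {
                "score": score, "n_best_trees": len(trees),
                "rf_to_truth": rf_distance(mp_tree, true_tree)}
            bundle.add("mp", "tree", outdir / "mp_tree.nwk")
        except Exception as exc:  # pragma: no cover
            logger.exception("mp stage failed")
            bundle.errors["mp"] = repr(exc)

    # ---------------- likelihood ----------------
    if config.stage_enabled("ml"):
        logger.info("stage: ml")
        try:
            ml_cfg = config.section("ml")
            seed = config.stage_seed("ml")
            if ml_cfg.get("model_selection", False):
                ref = mp_tree if mp_tree is not None else None
                if ref is None:
                    trees, _ = mp_search(matrix, strategy="tbr_heuristic",
                                         n_addition_replicates=2, seed=seed)
                    ref = trees[0]
                aic = model_select_aic(matrix, ref,
                                       candidates=[("JC", False, False),
                                                   ("HKY", False, False),
                                                   ("HKY", False, True),
                                                   ("GTR", False, True)])
                aic.to_csv(outdir / "model_selection.tsv", sep="\t",
                           index=False)
                best = aic.iloc[0]
                model, _, _ = fit_model(matrix, ref, best["family"],
                                        best["plus_i"], best["plus_g"])
            else:
                from .likelihood import empirical_frequencies
                model = SubstitutionModel(
                    ml_cfg.get("family", "HKY"),
                    freqs=empirical_frequencies(matrix.data),
                    kappa=2.0,
                    alpha=0.8 if ml_cfg.get("plus_g", True) else None)
            ml_tree, ml_lnl = ml_tree_search(matrix, model, seed=seed,
                                             start_tree=mp_tree)
            with open(outdir / "ml_tree.nwk", "w") as f:
                f.write(ml_tree.to_newick() + "\n")
            root = ml_cfg.get("clock_root", "OUT")
            stat, df_, p = clock_lrt(matrix, ml_tree, model, root=root)
            clock_tree, _ = fit_clock(matrix,
                                      ml_tree.unroot().root_at_edge_to(root),
                                      model)
            cal = ml_cfg.get("calibration")
            ages = {}
            if cal:
                dated, ages = date_nodes(
                    clock_tree, cal,
                    min_age=ml_cfg.get("calibration_min_age", 1.81))
                with open(outdir / "dated_tree.nwk", "w") as f:
                    f.write(dated.to_newick() + "\n")
            # topology tests: generating tree vs ML tree vs MP tree
            cands = {"ml": ml_tree, "truth": true_tree}
            if mp_tree is not None:
                cands["mp"] = mp_tree
            sls = []
            for name, t in cands.items():
                t_opt, _ = optimize_branch_lengths(t, matrix, model, tol=1e-5)
                sls.append(pruning_lnL(t_opt, matrix, model, tree_id=name))
            tt = topology_tests(sls, n_rell=5000, seed=seed + 5)
            tt.to_csv(outdir / "topology_tests.tsv", sep="\t", index=False)
            bundle.summary["ml"] = {
                "lnL": ml_lnl, "clock_stat": stat, "clock_df": df_,
                "clock_p": p, "rf_to_truth": rf_distance(ml_tree, true_tree),
                "root_age": max(ages.values()) if ages else None}
            bundle.add("ml", "tree", outdir / "ml_tree.nwk")
        except Exception as exc:  # pragma: no cover
            logger.exception("ml stage failed")
            bundle.errors["ml"] = repr(exc)

    # ---------------- bayesian ----------------
    if config.stage_enabled("bayes"):
        logger.info("stage: bayes")
        try:
            b_cfg = config.section("bayes")
            seed = config.stage_seed("bayes")
            traces = mcmc_run(matrix, scheme="exon_intron",
                              n_gens=b_cfg.get("n_gens", 12000),
                              sample_every=b_cfg.get("sample_every", 30),
                              n_runs=b_cfg.get("n_runs", 2), seed=seed,
                              start_tree=mp_tree)
            for i, tr in enumerate(traces):
                tr.write(outdir / f"mcmc_run{i}.params.tsv",
                         outdir / f"mcmc_run{i}.trees.nwk")
            burn = b_cfg.get("burn_in_trees", 100)
            bi_tree, pp = consensus_with_pp(traces, burn_in_trees=burn)
            with open(outdir / "bi_consensus.nwk", "w") as f:
                f.write(bi_tree.to_newick(include_lengths=False,
                                          support_key="posterior") + "\n")
            hm, dom = harmonic_mean_lnL(traces[0], burn_in=burn)
            strategies = b_cfg.get("compare_strategies")
            if strategies:
                bf_table = compare_partition_strategies(
                    matrix, strategies=strategies,
                    n_gens=b_cfg.get("bf_n_gens", 8000),
                    sample_every=b_cfg.get("sample_every", 30),
                    seed=seed + 11)
                bf_table.to_csv(outdir / "bayes_factors.tsv", sep="\t",
                                index=False)
                bundle.add("bayes", "bayes_factors",
                           outdir / "bayes_factors.tsv")
            bundle.summary["bayes"] = {
                "harmonic_mean_lnL": hm, "hm_dominance": dom,
                "rf_to_truth": rf_distance(bi_tree, true_tree)}
            bundle.add("bayes", "consensus", outdir / "bi_consensus.nwk")
        except Exception as exc:  # pragma: no cover
            logger.exception("bayes stage failed")
            bundle.errors["bayes"] = repr(exc)

    # ---------------- ancestral states ----------------
    if config.stage_enabled("asr"):
        logger.info("stage: asr")
        try:
            asr_tree = (bi_tree or ml_tree or mp_tree or true_tree)
            # reconstruction needs branch lengths: use the generating tree's
            # rooted form when the consensus lacks lengths
            base = true_tree.root_at_edge_to("OUT")
            recon, skipped = ancestral_states(
                base, traits, mode=config.section("asr").get("mode", "pruning"))
            rows = []
            correct = total = 0
            for char, nodes in recon.items():
                for clade, probs in nodes.items():
                    rows.append({"character": char,
                                 "clade": "|".join(sorted(clade)),
                                 **{f"p{s}": float(p)
                                    for s, p in enumerate(probs)}})
                    if traits.true_internal and clade in traits.true_internal:
                        j = traits.characters.index(char)
                        total += 1
                        correct += int(np.argmax(probs)
                                       == traits.true_internal[clade][j])
            pd.DataFrame(rows).to_csv(outdir / "ancestral_states.tsv",
                                      sep="\t", index=False)
            bundle.summary["asr"] = {
                "skipped": skipped,
                "mode_recovery": correct / total if total else None}
            bundle.add("asr", "states", outdir / "ancestral_states.tsv")
        except Exception as exc:  # pragma: no cover
            logger.exception("asr stage failed")
            bundle.errors["asr"] = repr(exc)

    # ---------------- agreement ----------------
    if mp_tree is not None and ml_tree is not None and bi_tree is not None:
        agree = topology_agreement(mp_tree, ml_tree, bi_tree,
                                   mp_support=mp_table, pp=pp)
        agree.to_csv(outdir / "topology_agreement.tsv", sep="\t", index=False)
        bundle.summary["agreement"] = {
            "all_equal": bool(
                rf_distance(mp_tree, ml_tree) == 0
                and rf_distance(mp_tree, bi_tree) == 0),
            "truth_recovered": bool(
                rf_distance(mp_tree, true_tree) == 0
                and rf_distance(ml_tree, true_tree) == 0
                and rf_distance(bi_tree, true_tree) == 0),
        }
    with open(outdir / "summary.json", "w") as f:
        json.dump(bundle.summary, f, indent=1, default=str)
    bundle.write_manifest()
    logger.removeHandler(fh)
    fh.close()
    return bundle


def topology_agreement(mp_tree: Tree, ml_tree: Tree, bi_tree: Tree,
                       mp_support=None, ml_support=None, pp=None,
                       display_threshold: float = 70.0) -> pd.DataFrame:
    """Per-split agreement across MP / ML / BI trees.

    One row per split in the union of the three split sets, with
    presence flags and support values; bootstrap below the display threshold
    renders as '-' (a rendering rule only, nothing is filtered).
    """
    leafs = [frozenset(t.leaf_labels) for t in (mp_tree, ml_tree, bi_tree)]
    if len(set(leafs)) != 1:
        raise ValueError("trees have different leaf sets")
    s_mp, s_ml, s_bi = (t.splits() for t in (mp_tree, ml_tree, bi_tree))
    rows = []
    for split in sorted(s_mp | s_ml | s_bi, key=lambda s: tuple(sorted(s))):
        def render(table):
            if table is None or split not in getattr(table, "rows", {}):
                return ""
            v = table.rows[split].get("bootstrap")
            if v is None:
                return ""
            return "-" if v < display_threshold else f"{v:.0f}"
        rows.append({
            "split": "|".join(sorted(split)),
            "in_mp": split in s_mp, "in_ml": split in s_ml,
            "in_bi": split in s_bi,
            "mp_bootstrap": render(mp_support),
            "ml_bootstrap": render(ml_support),
            "posterior": round(pp.get(split, float("nan")), 3) if pp else "",
        })
    return pd.DataFrame(rows)
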