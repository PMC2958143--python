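import math

import numpy as np
import pytest

from phylopipe.likelihood import (SiteLikelihoods, clock_lrt, date_nodes,
                                  fit_clock, fit_model, ml_tree_search,
                                  model_select_aic, mrca,
                                  optimize_branch_lengths, pruning_lnL,
                                  topology_tests)
from phylopipe.seqmodels import SubstitutionModel, discrete_gamma_rates
from phylopipe.simulate import SimulationConfig, simulate_alignments
from phylopipe.supermatrix import concatenate, encode_rows
from phylopipe.tree import Tree, enumerate_topologies, random_topology, rf_distance

from conftest import brute_force_lnl


class TestModels:
    def test_q_matrix_rows_sum_to_zero_and_mean_rate_one(self):
        m = SubstitutionModel("GTR", freqs=np.array([0.3, 0.2, 0.2, 0.3]),
                              rates=np.array([1.0, 4.0, 1.0, 1.0, 4.0, 1.0]))
        Q = m.q_matrix()
        assert np.allclose(Q.sum(axis=1), 0)
        assert np.isclose(-np.sum(m.freqs * np.diag(Q)), 1.0)

    def test_transition_matrix_stochastic_and_stationary(self):
        m = SubstitutionModel("HKY", freqs=np.array([0.4, 0.1, 0.2, 0.3]),
                              kappa=3.0)
        P = m.transition_matrix(0.7)
        assert np.allclose(P.sum(axis=1), 1.0)
        assert np.allclose(m.freqs @ P, m.freqs)

    def test_discrete_gamma_categories_have_mean_one(self):
        for alpha in (0.2, 0.8, 2.5):
            r = discrete_gamma_rates(alpha, 4)
            assert np.isclose(r.mean(), 1.0)
            assert np.all(np.diff(r) > 0)

    def test_invalid_model_parameters_rejected(self):
        with pytest.raises(ValueError):
            SubstitutionModel("HKY", freqs=np.array([0.5, 0.5, 0.5, 0.5]))
        with pytest.raises(ValueError):
            SubstitutionModel("JC", alpha=-1.0)


class TestPruning:
    def test_degenerate_star_with_zero_lengths(self):
        t = Tree.from_newick("(A:0,B:0,C:0);")
        data = encode_rows(["G", "G", "G"])
        freqs = np.array([0.1, 0.2, 0.3, 0.4])
        sl = pruning_lnL(t, data, SubstitutionModel("HKY", freqs=freqs),
                         taxa=list("ABC"))
        assert sl.site_lnl[0] == pytest.approx(math.log(0.3))

    def test_missing_data_integrates_to_one_taxon_case(self):
        t = Tree.from_newick("(A:0.3,B:0.2,C:0.1);")
        data = encode_rows(["A", "?", "?"])
        sl = pruning_lnL(t, data, SubstitutionModel("JC"), taxa=list("ABC"))
        assert sl.site_lnl[0] == pytest.approx(math.log(0.25))

    def test_matches_brute_force_enumeration(self, rng):
        """Pruning equals the sum over all internal-state assignments with
        exact transition probabilities, to near machine precision."""
        for _ in range(30):
            n = int(rng.integers(4, 6))
            taxa = [chr(65 + i) for i in range(n)]
            tree = random_topology(taxa, rng,
                                   branch_lengths=lambda r: r.exponential(0.2))
            data = encode_rows(["".join(rng.choice(list("ACGT?"), size=6))
                                for _ in range(n)])
            model = SubstitutionModel("HKY",
                                      freqs=np.array([0.3, 0.2, 0.2, 0.3]),
                                      kappa=2.5, alpha=0.6, p_inv=0.15)
            got = pruning_lnL(tree, data, model, taxa=taxa).site_lnl
            want = brute_force_lnl(tree, data, taxa, model)
            assert np.max(np.abs(got - want) / np.abs(want)) < 1e-10

    def test_invariant_under_rerooting(self, rng):
        taxa = list("ABCDE")
        tree = random_topology(taxa, rng,
                               branch_lengths=lambda r: r.exponential(0.15))
        data = encode_rows(["".join(rng.choice(list("ACGT"), size=40))
                            for _ in range(5)])
        model = SubstitutionModel("GTR", freqs=np.array([0.3, 0.2, 0.2, 0.3]),
                                  rates=np.array([1, 3, 1, 1, 3, 1.0]))
        base = pruning_lnL(tree, data, model, taxa=taxa).total
        for lab in taxa:
            rerooted = tree.root_at_edge_to(lab)
            again = pruning_lnL(rerooted, data, model, taxa=taxa).total
            assert again == pytest.approx(base, abs=1e-8)

    def test_gamma_with_huge_alpha_converges_to_homogeneous(self, rng):
        taxa = list("ABCD")
        tree = random_topology(taxa, rng,
                               branch_lengths=lambda r: r.exponential(0.2))
        data = encode_rows(["".join(rng.choice(list("ACGT"), size=50))
                            for _ in range(4)])
        flat = pruning_lnL(tree, data, SubstitutionModel("JC"),
                           taxa=taxa).total
        near = pruning_lnL(tree, data, SubstitutionModel("JC", alpha=1e4),
                           taxa=taxa).total
        # 4 categories at alpha=1e4 deviate from rate 1 by ~1%, so the
        # totals agree to O(1/alpha) but not machine precision
        assert near == pytest.approx(flat, abs=0.02)

    def test_site_totals_consistent(self):
        sl = SiteLikelihoods("t", np.array([-1.0, -2.0, -3.5]))
        assert sl.total == pytest.approx(-6.5)


class TestBranchOptimization:
    def test_two_taxon_jc_closed_form(self):
        p = 0.08
        L = 5000
        rows = ["A" * L, "A" * int(L * (1 - p)) + "C" * int(L * p)]
        data = encode_rows(rows)
        topo = Tree.from_newick("(A:0.05,B:0.05);", rooted=True)
        t_opt, _ = optimize_branch_lengths(topo, data, SubstitutionModel("JC"),
                                           taxa=["A", "B"])
        expect = -0.75 * math.log(1 - 4 * p / 3)
        assert t_opt.total_length() == pytest.approx(expect, rel=1e-3)

    def test_lnl_never_decreases_and_recovers_truth(self):
        tree = Tree.from_newick("(A:0.05,B:0.05,C:0.1);")
        cfg = SimulationConfig(tree=tree, n_genes=1,
                               length_range=(100_000, 100_000),
                               exon_fraction=1.0, missing_fraction=0.0,
                               model=SubstitutionModel("JC"), seed=2,
                               gene_rate_multipliers=[1.0])
        m = concatenate(simulate_alignments(cfg).genes)
        start = tree.copy()
        for node in start.postorder():
            if node.parent is not None:
                node.length = 0.3
        lnl0 = pruning_lnL(start, m, SubstitutionModel("JC")).total
        t_opt, lnl = optimize_branch_lengths(start, m, SubstitutionModel("JC"))
        assert lnl >= lnl0
        # each branch within 3 binomial SE of its generating value
        truth = {n.label: n.length for n in tree.leaves()}
        for leaf in t_opt.leaves():
            b = truth[leaf.label]
            se = math.sqrt(b / 100_000)  # Poisson-scale error on subst count
            assert abs(leaf.length - b) < 3 * se + 3e-3

    def test_total_length_scales_with_truth(self):
        lens = []
        for scale in (1.0, 2.0):
            tree = Tree.from_newick(
                f"(A:{0.04*scale},B:{0.04*scale},C:{0.04*scale});")
            cfg = SimulationConfig(tree=tree, n_genes=1,
                                   length_range=(20_000, 20_000),
                                   exon_fraction=1.0, missing_fraction=0.0,
                                   model=SubstitutionModel("JC"), seed=4,
                                   gene_rate_multipliers=[1.0])
            m = concatenate(simulate_alignments(cfg).genes)
            t_opt, _ = optimize_branch_lengths(tree, m, SubstitutionModel("JC"))
            lens.append(t_opt.total_length())
        assert lens[1] == pytest.approx(2 * lens[0], rel=0.1)


class TestModelSelection:
    def test_aic_formula_prefers_fewer_parameters_at_equal_lnl(self):
        # direct arithmetic: equal lnL, k differing by one => dAIC = 2
        aic = lambda lnl, k: -2 * lnl + 2 * k
        assert aic(-100.0, 5) - aic(-100.0, 4) == 2.0

    def test_nested_models_never_fit_worse(self, six_taxon_truth):
        tree, m = six_taxon_truth
        table = model_select_aic(m, tree,
                                 candidates=[("JC", False, False),
                                             ("HKY", False, False),
                                             ("HKY", False, True),
                                             ("GTR", False, True)])
        by_model = table.set_index("model")
        assert by_model.loc["GTR+G", "lnL"] >= by_model.loc["HKY+G", "lnL"] - 1e-6
        assert by_model.loc["HKY+G", "lnL"] >= by_model.loc["HKY", "lnL"] - 1e-6

    def test_jc_selected_on_most_jc_replicates(self):
        """AIC recovers the generating model in the large majority of
        replicates (each superfluous-parameter comparison errs with the
        chi-square tail probability, so unanimity is not expected)."""
        taxa = list("ABCD")
        wins = 0
        for rep in range(8):
            true = random_topology(taxa, np.random.default_rng(100 + rep),
                                   branch_lengths=lambda r: 0.08)
            cfg = SimulationConfig(tree=true, n_genes=1,
                                   length_range=(3000, 3000),
                                   exon_fraction=1.0, missing_fraction=0.0,
                                   model=SubstitutionModel("JC"),
                                   seed=200 + rep,
                                   gene_rate_multipliers=[1.0])
            m = concatenate(simulate_alignments(cfg).genes)
            table = model_select_aic(m, true,
                                     candidates=[("JC", False, False),
                                                 ("HKY", False, False)])
            wins += int(table.iloc[0]["model"] == "JC")
        assert wins >= 6


class TestMlSearch:
    def test_four_taxa_equals_argmax_over_topologies(self, rng):
        taxa = list("ABCD")
        true = random_topology(taxa, np.random.default_rng(0),
                               branch_lengths=lambda r: 0.1)
        cfg = SimulationConfig(tree=true, n_genes=1, length_range=(800, 800),
                               exon_fraction=1.0, missing_fraction=0.0,
                               model=SubstitutionModel("JC"), seed=6,
                               gene_rate_multipliers=[1.0])
        m = concatenate(simulate_alignments(cfg).genes)
        model = SubstitutionModel("JC")
        best, lnl = ml_tree_search(m, model, seed=0)
        scores = []
        for topo in enumerate_topologies(taxa):
            _, l = optimize_branch_lengths(topo, m, model)
            scores.append(l)
        assert lnl == pytest.approx(max(scores), abs=1e-4)
        assert pruning_lnL(best, m, model).total == pytest.approx(lnl, abs=1e-6)

    def test_nni_climb_recovers_truth_on_clean_data(self, six_taxon_truth):
        tree, m = six_taxon_truth
        # force the hill-climbing path (not the exhaustive scan)
        best, _ = ml_tree_search(m, SubstitutionModel("JC"), seed=1,
                                 exhaustive_limit=0)
        assert rf_distance(best, tree) == 0


class TestClock:
    def test_df_convention(self, six_taxon_truth):
        tree, m = six_taxon_truth
        _, df, _ = clock_lrt(m, tree, SubstitutionModel("JC"), root="A")
        assert df == 6 - 2

    def test_clock_data_not_rejected_rate_variation_rejected(self):
        # ultrametric generating tree: LRT should not reject
        nwk = ("(((A:0.02,B:0.02):0.02,(C:0.02,D:0.02):0.02):0.06,"
               "E:0.1);")
        clock_tree = Tree.from_newick(nwk, rooted=True).unroot()
        cfg = SimulationConfig(tree=clock_tree, n_genes=1,
                               length_range=(4000, 4000), exon_fraction=1.0,
                               missing_fraction=0.0,
                               model=SubstitutionModel("JC"), seed=9,
                               gene_rate_multipliers=[1.0])
        m = concatenate(simulate_alignments(cfg).genes)
        stat, df, p = clock_lrt(m, clock_tree, SubstitutionModel("JC"),
                                root="E")
        assert p > 0.01
        # now a 8x rate distortion on one pendant branch
        fast = clock_tree.copy()
        fast.find_leaf("A").length = 0.16
        cfg2 = SimulationConfig(tree=fast, n_genes=1,
                                length_range=(4000, 4000), exon_fraction=1.0,
                                missing_fraction=0.0,
                                model=SubstitutionModel("JC"), seed=10,
                                gene_rate_multipliers=[1.0])
        m2 = concatenate(simulate_alignments(cfg2).genes)
        _, _, p2 = clock_lrt(m2, fast, SubstitutionModel("JC"), root="E")
        assert p2 < 0.001


class TestTopologyTests:
    def _site_lnls(self, rng, n_trees=4, S=200):
        base = rng.normal(-3.0, 0.5, size=S)
        out = [SiteLikelihoods("t0", base)]
        for i in range(1, n_trees):
            out.append(SiteLikelihoods(f"t{i}",
                                       base + rng.normal(-0.02, 0.1, size=S)))
        return out

    def test_best_tree_has_p_one_everywhere(self, rng):
        df = topology_tests(self._site_lnls(rng), n_rell=2000, seed=0)
        best = df[df.best].iloc[0]
        assert best.p_KH == 1.0 and best.p_SH == 1.0 and best.p_WSH == 1.0

    def test_sh_at_least_kh_for_non_best(self, rng):
        for trial in range(5):
            df = topology_tests(self._site_lnls(rng), n_rell=1000, seed=trial)
            non_best = df[~df.best]
            assert (non_best.p_SH >= non_best.p_KH - 1e-12).all()

    def test_identical_tree_not_rejected(self, rng):
        sls = self._site_lnls(rng, n_trees=2)
        sls.append(SiteLikelihoods("twin", sls[0].site_lnl.copy()))
        df = topology_tests(sls, n_rell=1000, seed=1).set_index("tree")
        assert df.loc["twin", "p_KH"] == 1.0

    def test_differing_site_counts_rejected(self, rng):
        a = SiteLikelihoods("a", rng.normal(size=10))
        b = SiteLikelihoods("b", rng.normal(size=12))
        with pytest.raises(ValueError):
            topology_tests([a, b])


class TestDating:
    def _clock_tree(self):
        return Tree.from_newick(
            "((A:1,B:1):1,(C:1.5,D:1.5):0.5);", rooted=True)

    def test_linear_scaling_of_ages(self):
        t = self._clock_tree()
        dated, ages = date_nodes(t, ["A", "B"], min_age=1.81)
        assert ages[frozenset("AB")] == pytest.approx(1.81)
        assert ages[frozenset("ABCD")] == pytest.approx(3.62)
        assert ages[frozenset("CD")] == pytest.approx(1.5 / 1.0 * 1.81)

    def test_calibration_at_root(self):
        t = self._clock_tree()
        _, ages = date_nodes(t, ["A", "C"], min_age=1.81)
        assert ages[frozenset("ABCD")] == pytest.approx(1.81)

    def test_ages_decrease_rootward_to_tips(self):
        _, ages = date_nodes(self._clock_tree(), ["A", "B"])
        assert ages[frozenset("ABCD")] > ages[frozenset("AB")] > 0

    def test_non_ultrametric_rejected(self):
        bad = Tree.from_newick("((A:1,B:2):1,(C:1,D:1):1);", rooted=True)
        with pytest.raises(ValueError):
            date_nodes(bad, ["A", "B"])

    def test_leaf_calibration_rejected(self):
        with pytest.raises(ValueError):
            date_nodes(self._clock_tree(), ["A"])

    def test_mrca_lookup(self):
        t = self._clock_tree()
        node = mrca(t, ["A", "B"])
        assert sorted(l.label for l in Tree(node, rooted=True).leaves()) == ["A", "B"]
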