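import numpy as np
import pytest

from phylopipe.parsimony import (SupportTable, bootstrap_support,
                                 bremer_support, fitch_score, mp_search,
                                 partitioned_bremer, variable_length_bootstrap)
from phylopipe.supermatrix import GeneAlignment, concatenate, encode_rows
from phylopipe.supermatrix import _default_annotation
from phylopipe.tree import Tree, enumerate_topologies, random_topology, rf_distance

from conftest import brute_force_fitch


def make_matrix(taxa, rows):
    g = GeneAlignment("g", taxa, rows, _default_annotation(len(rows[0]), 1.0))
    return concatenate([g])


class TestFitch:
    def test_constant_matrix_scores_zero(self):
        t = Tree.from_newick("((A,B),(C,D));")
        m = make_matrix(list("ABCD"), ["ACGT"] * 4)
        assert fitch_score(t, m) == 0

    def test_single_informative_column(self):
        t = Tree.from_newick("((A,B),(C,D));")
        m = make_matrix(list("ABCD"), ["A", "A", "C", "C"])
        assert fitch_score(t, m) == 1

    def test_matches_exhaustive_state_assignment_oracle(self, rng):
        """Fitch equals brute-force minimization over all internal (and
        ambiguous leaf) state assignments on random instances."""
        for _ in range(60):
            n = int(rng.integers(4, 7))
            taxa = [chr(65 + i) for i in range(n)]
            tree = random_topology(taxa, rng)
            rows = ["".join(rng.choice(list("ACGT?-"), size=6))
                    for _ in range(n)]
            got = fitch_score(tree, encode_rows(rows), taxa=taxa)
            assert got == brute_force_fitch(tree, rows, taxa)

    def test_leaf_mismatch_rejected(self):
        t = Tree.from_newick("((A,B),(C,E));")
        m = make_matrix(list("ABCD"), ["A", "A", "C", "C"])
        with pytest.raises(ValueError):
            fitch_score(t, m)


class TestMpSearch:
    def test_four_taxa_beats_both_alternatives(self):
        m = make_matrix(list("ABCD"), ["AAAA", "AAAA", "CCCC", "CCCC"])
        trees, score = mp_search(m, strategy="exhaustive")
        scores = {t.topology_key(): fitch_score(t, m)
                  for t in enumerate_topologies(list("ABCD"))}
        assert score == min(scores.values()) == 4
        assert all(fitch_score(t, m) == score for t in trees)

    def test_branch_and_bound_equals_exhaustive(self, rng):
        for trial in range(5):
            n = int(rng.integers(5, 8))
            taxa = [chr(65 + i) for i in range(n)]
            rows = ["".join(rng.choice(list("ACGT"), size=25))
                    for _ in range(n)]
            m = make_matrix(taxa, rows)
            tb, sb = mp_search(m, strategy="branch_and_bound", seed=trial)
            te, se = mp_search(m, strategy="exhaustive", seed=trial)
            assert sb == se
            assert ({t.topology_key() for t in tb}
                    == {t.topology_key() for t in te})

    def test_tbr_heuristic_matches_exact_score(self, six_taxon_truth):
        tree, m = six_taxon_truth
        _, s_exact = mp_search(m, strategy="branch_and_bound", seed=0)
        trees, s_tbr = mp_search(m, strategy="tbr_heuristic",
                                 n_addition_replicates=3, seed=0)
        assert s_tbr == s_exact
        assert rf_distance(trees[0], tree) == 0

    def test_clean_signal_recovers_generating_topology(self, six_taxon_truth):
        tree, m = six_taxon_truth
        trees, _ = mp_search(m, strategy="branch_and_bound", seed=1)
        assert len(trees) == 1
        assert rf_distance(trees[0], tree) == 0

    def test_exhaustive_guard(self):
        taxa = [f"t{i}" for i in range(11)]
        rows = ["ACGT"] * 11
        m = make_matrix(taxa, rows)
        with pytest.raises(ValueError):
            mp_search(m, strategy="exhaustive")


class TestBootstrap:
    def test_unanimous_split_gets_full_support(self):
        m = make_matrix(list("ABCD"), ["AAAA", "AAAA", "CCCC", "CCCC"])
        ref, _ = mp_search(m, strategy="exhaustive")
        table, cons = bootstrap_support(m, n_reps=20, seed=0,
                                        reference_tree=ref[0])
        split = next(iter(ref[0].splits()))
        assert table.rows[split]["bootstrap"] == 100.0
        assert split in cons.splits()

    def test_supports_bounded_and_reference_splits_reported(self,
                                                            six_taxon_truth):
        tree, m = six_taxon_truth
        table, _ = bootstrap_support(m, n_reps=15, seed=3,
                                     reference_tree=tree)
        for split in tree.splits():
            assert split in table.rows
        for row in table.rows.values():
            assert 0.0 <= row["bootstrap"] <= 100.0

    def test_determinism_under_fixed_seed(self, six_taxon_truth):
        _, m = six_taxon_truth
        a, _ = bootstrap_support(m, n_reps=10, seed=9)
        b, _ = bootstrap_support(m, n_reps=10, seed=9)
        assert a.rows == b.rows


class TestVariableLengthBootstrap:
    def test_size_equal_to_length_matches_plain_bootstrap(self,
                                                          six_taxon_truth):
        tree, m = six_taxon_truth
        plain, _ = bootstrap_support(m, n_reps=10, seed=5,
                                     reference_tree=tree)
        sized, _ = bootstrap_support(m, n_reps=10, seed=5,
                                     reference_tree=tree,
                                     resample_size=m.length)
        assert plain.rows == sized.rows

    def test_curve_shape_and_support_growth(self, six_taxon_truth):
        tree, m = six_taxon_truth
        sizes = [60, 300, 3000]
        df = variable_length_bootstrap(m, sizes=sizes, n_reps=12, seed=2,
                                       reference_tree=tree)
        assert set(df["size"]) == set(sizes)
        n_splits = len(tree.splits())
        assert len(df) == n_splits * len(sizes)
        mean_by_size = df.groupby("size")["support"].mean()
        assert mean_by_size.loc[3000] >= mean_by_size.loc[60]

    def test_empty_sizes_rejected(self, six_taxon_truth):
        _, m = six_taxon_truth
        with pytest.raises(ValueError):
            variable_length_bootstrap(m, sizes=[])


class TestBremer:
    def test_k_uncontradicted_characters_give_decay_k(self):
        k = 4
        rows = ["A" * k, "A" * k, "C" * k, "C" * k, "C" * k]
        m = make_matrix(list("ABCDE"), rows)
        best, score = mp_search(m, strategy="exhaustive")
        table = bremer_support(m, best[0], best_score=score)
        decays = sorted(r["decay"] for r in table.rows.values())
        # the AB|CDE split decays by k; the arbitrary resolution of the
        # C/D/E cherry is unsupported and decays by 0
        assert decays == [0, k]

    def test_zero_support_split_decays_zero(self):
        # star-like data: no column favors any resolution
        rows = ["AAAA", "AAAA", "AAAA", "AAAA"]
        m = make_matrix(list("ABCD"), rows)
        best, score = mp_search(m, strategy="exhaustive")
        table = bremer_support(m, best[0], best_score=score)
        assert all(r["decay"] == 0 for r in table.rows.values())

    def test_decay_bounded_by_variable_columns(self, six_taxon_truth):
        from phylopipe.supermatrix import site_classes
        tree, m = six_taxon_truth
        best, score = mp_search(m, strategy="branch_and_bound", seed=0)
        table = bremer_support(m, best[0], best_score=score)
        bound = site_classes(m.data)["n_variable"]
        assert all(0 <= r["decay"] <= bound for r in table.rows.values())

    def test_non_optimal_tree_detected(self):
        rows = ["AAAA", "AAAA", "CCCC", "CCCC", "CCCC"]
        m = make_matrix(list("ABCDE"), rows)
        best, score = mp_search(m, strategy="exhaustive")
        with pytest.raises(ValueError):
            bremer_support(m, best[0], best_score=score - 1)


class TestPartitionedBremer:
    def _two_gene_matrix(self):
        # gene 1: three columns supporting AB|CD; gene 2: one contradicting
        g1 = GeneAlignment("g1", list("ABCD"), ["AAA", "AAA", "CCC", "CCC"],
                           _default_annotation(3, 1.0))
        g2 = GeneAlignment("g2", list("ABCD"), ["A", "C", "A", "C"],
                           _default_annotation(1, 1.0))
        return concatenate([g1, g2])

    def test_signed_contributions_sum_to_decay(self):
        m = self._two_gene_matrix()
        best, score = mp_search(m, strategy="exhaustive")
        table = partitioned_bremer(m, m.schemes["by_gene"], best[0])
        (row,) = table.rows.values()
        assert row["pbs"]["g1"] == 3.0
        assert row["pbs"]["g2"] == -1.0
        assert row["decay"] == 2.0

    def test_single_partition_pbs_equals_decay(self, six_taxon_truth):
        _, m = six_taxon_truth
        best, score = mp_search(m, strategy="branch_and_bound", seed=0)
        table = partitioned_bremer(m, m.schemes["single"], best[0])
        for row in table.rows.values():
            assert row["pbs"]["all"] == pytest.approx(row["decay"])

    def test_invariant_partition_contributes_zero(self):
        g1 = GeneAlignment("g1", list("ABCDE"),
                           ["AA", "AA", "CC", "CC", "CC"],
                           _default_annotation(2, 1.0))
        g2 = GeneAlignment("g2", list("ABCDE"), ["G"] * 5,
                           _default_annotation(1, 1.0))
        m = concatenate([g1, g2])
        best, _ = mp_search(m, strategy="exhaustive")
        table = partitioned_bremer(m, m.schemes["by_gene"], best[0])
        for row in table.rows.values():
            assert row["pbs"]["g2"] == 0.0

    def test_identity_holds_on_random_matrices(self, rng):
        """Sum over partitions of PBS equals the decay index, always."""
        for trial in range(3):
            taxa = [chr(65 + i) for i in range(6)]
            genes = []
            for gi in range(3):
                rows = ["".join(rng.choice(list("ACGT"), size=8))
                        for _ in range(6)]
                genes.append(GeneAlignment(f"g{gi}", taxa, rows,
                                           _default_annotation(8, 1.0)))
            m = concatenate(genes)
            best, _ = mp_search(m, strategy="branch_and_bound", seed=trial)
            table = partitioned_bremer(m, m.schemes["by_gene"], best[0])
            for row in table.rows.values():
                assert sum(row["pbs"].values()) == pytest.approx(row["decay"])

    def test_incomplete_scheme_rejected(self, six_taxon_truth):
        _, m = six_taxon_truth
        best, _ = mp_search(m, strategy="branch_and_bound", seed=0)
        bad = {"half": np.arange(m.length // 2)}
        with pytest.raises(ValueError):
            partitioned_bremer(m, bad, best[0])


class TestSupportTable:
    def test_bounds_enforced(self):
        t = SupportTable(list("ABCD"))
        with pytest.raises(ValueError):
            t.set_value(frozenset("AB"), "bootstrap", 150.0)
        with pytest.raises(ValueError):
            t.set_value(frozenset("AB"), "posterior", 1.2)

    def test_pbs_decay_consistency_enforced(self):
        t = SupportTable(list("ABCD"))
        t.rows[frozenset("AB")] = {"decay": 2.0, "pbs": {"g1": 3.0, "g2": -1.0}}
        t._check(frozenset("AB"))  # consistent: passes
        t.rows[frozenset("AB")]["pbs"]["g2"] = 0.0
        with pytest.raises(ValueError):
            t._check(frozenset("AB"))

    def test_merge_combines_methods(self):
        a = SupportTable(list("ABCD"))
        a.set_value(frozenset("AB"), "bootstrap", 90.0)
        b = SupportTable(list("ABCD"))
        b.set_value(frozenset("AB"), "posterior", 0.99)
        merged = a.merge(b)
        assert merged.rows[frozenset("AB")] == {"bootstrap": 90.0,
                                                "posterior": 0.99}
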