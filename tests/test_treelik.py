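import numpy as np
import pytest

from plastoscan import Alignment, parse_newick, site_loglik, write_newick
from plastoscan.substmodel import JC69, GTRGIParams
from plastoscan.treelik import (
    LikelihoodEngine,
    bootstrap_columns,
    fit_on_topology,
    empirical_frequencies,
)
from plastoscan.seqsim import simulate_alignment, default_model, backbone_topology

from conftest import random_gtr_params, random_tree_newick
from _oracles import oracle_site_loglik


class TestNewickIO:
    def test_two_leaf_lengths(self):
        t = parse_newick("(A:0.1,B:0.2);")
        assert sorted(t.leaf_labels) == ["A", "B"]
        assert np.allclose(sorted(t.branch_lengths()), [0.1, 0.2])

    def test_missing_lengths_default_zero_and_flagged(self):
        t = parse_newick("((A,B),(C,D));")
        assert not t.lengths_present
        assert np.allclose(t.branch_lengths(), 0.0)
        assert write_newick(t) == "((A,B),(C,D));"

    def test_round_trip_random_trees(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 12))
            text = random_tree_newick(rng, n)
            canonical = write_newick(parse_newick(text))
            assert write_newick(parse_newick(canonical)) == canonical

    @pytest.mark.parametrize("bad", ["((A,B);", "(A,B,,C);", "(A,(B,A));"])
    def test_malformed_newick_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_newick(bad)


class TestSiteLoglik:
    def test_two_taxon_jc_closed_form(self):
        aln = Alignment.from_sequences(["A", "B"], ["A", "A"])
        tree = parse_newick("(A:0.375,B:0.375);")
        prof = site_loglik(aln, tree, JC69)
        expected = np.log(0.25 * (0.25 + 0.75 * np.exp(-1.0)))
        assert abs(prof.site_lnl[0] - expected) < 1e-10
        assert abs(prof.site_lnl[0] + 2.0289) < 1e-4

    def test_all_gap_column_has_zero_loglik(self, quartet_tree, gtr_params):
        aln = Alignment.from_sequences(list("ABCD"), ["-A", "-C", "-G", "-T"])
        prof = site_loglik(aln, quartet_tree, gtr_params)
        assert prof.site_lnl[0] == pytest.approx(0.0, abs=1e-12)
        assert prof.site_lnl[1] < 0.0

    def test_matches_enumeration_on_quartet(self, rng, quartet_tree):
        p = random_gtr_params(rng)
        aln = simulate_alignment(quartet_tree, p, 20, seed=7)
        prof = site_loglik(aln, quartet_tree, p)
        oracle = oracle_site_loglik(aln, quartet_tree, p)
        assert np.allclose(prof.site_lnl, oracle, atol=1e-8)

    def test_total_is_sum_of_sites(self, rng, quartet_tree, gtr_params):
        aln = simulate_alignment(quartet_tree, gtr_params, 100, seed=3)
        prof = site_loglik(aln, quartet_tree, gtr_params)
        assert prof.total == pytest.approx(prof.site_lnl.sum(), abs=1e-6)

    def test_ambiguity_codes_differ_from_gaps(self, quartet_tree, gtr_params):
        ambig = Alignment.from_sequences(list("ABCD"), ["R", "A", "A", "A"])
        gap = Alignment.from_sequences(list("ABCD"), ["-", "A", "A", "A"])
        l_ambig = site_loglik(ambig, quartet_tree, gtr_params).site_lnl[0]
        l_gap = site_loglik(gap, quartet_tree, gtr_params).site_lnl[0]
        assert l_ambig < l_gap  # R restricts to {A, G}; '-' allows all

    def test_missing_taxon_named_in_error(self, quartet_tree, gtr_params):
        aln = Alignment.from_sequences(["A", "B", "C"], ["A", "C", "G"])
        with pytest.raises(ValueError, match="D"):
            site_loglik(aln, quartet_tree, gtr_params)


class TestLikelihoodInvariances:
    def test_rerooting_leaves_likelihood_unchanged(self, rng):
        p = random_gtr_params(rng)
        text = random_tree_newick(rng, 7)
        tree = parse_newick(text)
        aln = simulate_alignment(tree, p, 200, seed=11)
        ref = site_loglik(aln, tree, p).site_lnl
        for node in (1, 3, 5):
            other = site_loglik(aln, tree.rerooted(node), p).site_lnl
            assert np.allclose(ref, other, atol=1e-8)

    def test_leaf_order_permutation_invariance(self, rng, quartet_tree, gtr_params):
        aln = simulate_alignment(quartet_tree, gtr_params, 50, seed=2)
        perm = Alignment(
            list(reversed(aln.taxa)), aln.data[::-1].copy()
        )
        a = site_loglik(aln, quartet_tree, gtr_params).site_lnl
        b = site_loglik(perm, quartet_tree, gtr_params).site_lnl
        assert np.allclose(a, b, atol=1e-12)

    def test_zero_length_branch_is_neutral(self, gtr_params):
        aln = Alignment.from_sequences(list("ABCD"), ["AC", "AC", "GC", "GT"])
        t1 = parse_newick("((A:0.1,B:0.2):0.15,(C:0.3,D:0.1):0.0);")
        t2 = parse_newick("((A:0.1,B:0.2):0.15,C:0.3,D:0.1);")
        a = site_loglik(aln, t1, gtr_params).site_lnl
        b = site_loglik(aln, t2, gtr_params).site_lnl
        assert np.allclose(a, b, atol=1e-10)

    def test_enumeration_agreement_on_small_trees(self, rng):
        # spot-check beyond the quartet: a 5-leaf tree, multiple draws
        text = random_tree_newick(rng, 5)
        tree = parse_newick(text)
        for _ in range(3):
            p = random_gtr_params(rng)
            aln = simulate_alignment(tree, p, 10, seed=int(rng.integers(1e6)))
            mine = site_loglik(aln, tree, p).site_lnl
            oracle = oracle_site_loglik(aln, tree, p)
            assert np.allclose(mine, oracle, atol=1e-8)


class TestFit:
    def test_refit_from_truth_does_not_decrease(self):
        tree = backbone_topology()
        model = default_model()
        aln = simulate_alignment(tree, model, 20000, seed=5)
        truth_lnl = LikelihoodEngine(aln, tree).loglik(model)
        fit = fit_on_topology(aln, tree, model0=model, free=("brlen",))
        assert fit.lnl >= truth_lnl - 1e-6

    def test_two_rootings_fit_to_same_loglik(self):
        tree = backbone_topology()
        model = default_model()
        aln = simulate_alignment(tree, model, 5000, seed=6)
        f1 = fit_on_topology(aln, tree, model0=model, free=("brlen",))
        f2 = fit_on_topology(aln, tree.rerooted(2), model0=model, free=("brlen",))
        assert f1.lnl == pytest.approx(f2.lnl, abs=0.05)

    def test_nonconvergence_warns_and_returns_best(self):
        tree = backbone_topology()
        model = default_model()
        aln = simulate_alignment(tree, model, 5000, seed=8)
        with pytest.warns(RuntimeWarning, match="best-so-far"):
            fit = fit_on_topology(aln, tree, max_cycles=1, tol=1e-12)
        assert not fit.converged
        assert np.isfinite(fit.lnl)

    def test_empirical_frequencies_reflect_composition(self):
        aln = Alignment.from_sequences(["x", "y"], ["AAAT", "AAGT"])
        f = empirical_frequencies(aln, pseudocount=0.0)
        assert f[0] == pytest.approx(5 / 8)


class TestBootstrapColumns:
    def test_reproducible_and_right_shape(self):
        a = bootstrap_columns(100, 5, seed=3)
        b = bootstrap_columns(100, 5, seed=3)
        assert a.shape == (5, 100)
        assert (a == b).all()
        assert a.min() >= 0 and a.max() < 100

    def test_mean_multiplicity_near_one(self):
        reps = bootstrap_columns(200, 1000, seed=9)
        counts = np.array([(reps == j).sum(axis=1) for j in range(5)])
        # each column's expected multiplicity per replicate is 1
        se = 1.0 / np.sqrt(1000)
        assert np.all(np.abs(counts.mean(axis=1) - 1.0) < 3 * se)

    def test_requires_positive_replicates(self):
        with pytest.raises(ValueError):
            bootstrap_columns(10, 0, seed=1)
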