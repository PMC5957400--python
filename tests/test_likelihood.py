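import math

import pytest

import geneshop as gs
from geneshop.likelihood import Alignment, jc, poisson
from geneshop.trees import TreeError

from .oracles import enumeration_log_likelihood


class TestLogLikelihood:
    def test_two_sequence_jc_closed_form(self):
        # lnL = ln( 1/4 * (1/4 + 3/4 exp(-4 t / 3)) ) on the total path t
        tree = gs.parse_newick("(A:0.05,B:0.05);")
        aln = Alignment({"A": "A", "B": "A"}, "nt")
        expected = math.log(0.25 * (0.25 + 0.75 * math.exp(-4 * 0.1 / 3)))
        assert gs.log_likelihood(aln, tree, jc()) == pytest.approx(expected, abs=1e-8)
        diff = Alignment({"A": "A", "B": "C"}, "nt")
        expected_diff = math.log(0.25 * (0.25 - 0.25 * math.exp(-4 * 0.1 / 3)))
        assert gs.log_likelihood(diff, tree, jc()) == pytest.approx(expected_diff, abs=1e-8)

    def test_zero_branches_identical_sequences(self):
        tree = gs.parse_newick("((A:0,B:0):0,C:0);")
        aln = Alignment({t: "ACGTACGT" for t in "ABC"}, "nt")
        assert gs.log_likelihood(aln, tree, jc()) == pytest.approx(8 * math.log(0.25))

    def test_invariant_under_rerooting(self, rng):
        tree = gs.apply_rates(
            gs.simulate_yule(6, 1.0, seed=rng), gs.RateDecoration("ucln"), rng=rng
        )
        aln = gs.simulate_alignment(tree, jc(), 300, seed=rng)
        base = gs.log_likelihood(aln, tree, jc())
        for tip in tree.tip_labels():
            rerooted = gs.root_by_outgroup(tree, {tip})
            assert gs.log_likelihood(aln, rerooted, jc()) == pytest.approx(base, abs=1e-8)

    @pytest.mark.parametrize("alphabet,n_taxa", [("nt", 5), ("aa", 4)])
    def test_matches_exact_state_enumeration(self, rng, alphabet, n_taxa):
        model = jc() if alphabet == "nt" else poisson()
        for _ in range(5):
            tree = gs.apply_rates(
                gs.simulate_yule(n_taxa, 1.0, seed=rng),
                gs.RateDecoration("ucln"),
                rng=rng,
            )
            aln = gs.simulate_alignment(tree, model, 3, seed=rng)
            expected = enumeration_log_likelihood(aln, tree, model)
            assert gs.log_likelihood(aln, tree, model) == pytest.approx(expected, abs=1e-8)

    def test_missing_data_marginalized(self):
        tree = gs.parse_newick("((A:0.1,B:0.2):0.1,C:0.3);")
        aln = Alignment({"A": "AC", "B": "AN", "C": "A-"}, "nt")
        reduced = Alignment({"A": "A", "B": "A", "C": "A"}, "nt")
        col2 = enumeration_log_likelihood(
            Alignment({"A": "C", "B": "N", "C": "-"}, "nt"), tree, jc()
        )
        got = gs.log_likelihood(aln, tree, jc())
        assert got == pytest.approx(gs.log_likelihood(reduced, tree, jc()) + col2, abs=1e-8)

    def test_taxon_mismatch_raises(self, small_tree):
        aln = Alignment({"A": "A", "B": "A", "D": "A"}, "nt")
        with pytest.raises(TreeError, match="mismatch"):
            gs.log_likelihood(aln, small_tree, jc())


class TestOptimizeFree:
    def test_constant_alignment_drives_lengths_to_zero(self):
        tree = gs.parse_newick("((A:0.3,B:0.2):0.1,C:0.4);")
        aln = Alignment({t: "A" * 50 for t in "ABC"}, "nt")
        fitted, lnl = gs.optimize_free(aln, tree, jc())
        for node in fitted.postorder():
            if node.parent is not None:
                assert node.length < 1e-6
        assert lnl == pytest.approx(50 * math.log(0.25))

    def test_ml_dominates_generating_tree(self, rng):
        tree = gs.apply_rates(
            gs.simulate_yule(7, 1.0, seed=rng), gs.RateDecoration("ucln"), rng=rng
        )
        aln = gs.simulate_alignment(tree, jc(), 500, seed=rng)
        _, lnl = gs.optimize_free(aln, tree, jc())
        assert lnl >= gs.log_likelihood(aln, tree, jc()) - 1e-6

    def test_branch_length_recovery_long_alignment(self, rng):
        tree = gs.rescale_height(gs.simulate_yule(5, 1.0, seed=rng), 0.5)
        aln = gs.simulate_alignment(tree, jc(), 100_000, seed=rng)
        fitted, _ = gs.optimize_free(aln, tree, jc())
        truth = {
            frozenset(_tips_below(n)): n.length
            for n in tree.postorder()
            if n.parent is not None and not _is_root_child_pair(n, tree)
        }
        est = {
            frozenset(_tips_below(n)): n.length
            for n in fitted.postorder()
            if n.parent is not None and not _is_root_child_pair(n, fitted)
        }
        for clade, t_true in truth.items():
            if t_true > 0.02:  # short branches drown in sampling noise
                assert est[clade] == pytest.approx(t_true, rel=0.10)


class TestClock:
    def test_clock_fit_is_ultrametric_and_dominated(self, rng):
        tree = gs.apply_rates(
            gs.simulate_yule(7, 1.0, seed=rng),
            gs.RateDecoration("noisy_clock", noise_sd=0.25),
            rng=rng,
        )
        aln = gs.simulate_alignment(tree, jc(), 600, seed=rng)
        ctree, lnl_clock = gs.optimize_clock(aln, tree, jc())
        _, lnl_free = gs.optimize_free(aln, tree, jc())
        assert ctree.is_ultrametric(rel_tol=1e-6)
        assert gs.tree_stats(ctree).rtt_variance == pytest.approx(0.0, abs=1e-12)
        assert lnl_clock <= lnl_free + 1e-6

    @pytest.mark.parametrize("n_taxa,df", [(3, 1), (11, 9)])
    def test_degrees_of_freedom(self, rng, n_taxa, df):
        tree = gs.rescale_height(gs.simulate_yule(n_taxa, 1.0, seed=rng), 0.4)
        aln = gs.simulate_alignment(tree, jc(), 200, seed=rng)
        res = gs.clock_lrt(aln, tree, jc())
        assert res.df == df
        assert res.statistic >= 0.0
        assert 0.0 <= res.p_value <= 1.0

    def test_relaxed_clock_data_rejected(self, rng):
        # strongly non-clock data should fail the test decisively
        tree = gs.apply_rates(
            gs.rescale_height(gs.simulate_yule(10, 1.0, seed=rng), 0.75),
            gs.RateDecoration("ucln", mean_log=-0.5, stdev_log=1.0),
            rng=rng,
        )
        aln = gs.simulate_alignment(tree, jc(), 1500, seed=rng)
        res = gs.clock_lrt(aln, tree, jc())
        assert res.rejected
        assert res.p_value < 1e-4


class TestAlignment:
    def test_length_mismatch_rejected(self):
        with pytest.raises(Exception, match="length"):
            Alignment({"A": "ACGT", "B": "ACG"}, "nt")

    def test_fasta_roundtrip(self, tmp_path, rng):
        tree = gs.simulate_yule(5, 1.0, seed=rng)
        aln = gs.simulate_alignment(tree, poisson(), 40, seed=rng)
        path = tmp_path / "aln.fasta"
        aln.to_fasta(path)
        back = Alignment.from_fasta(path, "aa")
        assert back.sequences == aln.sequences

    def test_concatenate_partitions_tile(self, rng):
        tree = gs.simulate_yule(4, 1.0, seed=rng)
        alns = [gs.simulate_alignment(tree, jc(), n, seed=rng) for n in (7, 11, 5)]
        concat, parts = gs.concatenate(alns)
        assert parts == [(1, 7), (8, 18), (19, 23)]
        assert concat.length == 23


def _tips_below(node):
    if not node.children:
        return [node.label]
    out = []
    for c in node.children:
        out.extend(_tips_below(c))
    return out


def _is_root_child_pair(node, tree):
    # with a bifurcating root only the sum of the two root edges is
    # identifiable; skip them in per-branch comparisons
    return node.parent is tree.root and len(tree.root.children) == 2
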