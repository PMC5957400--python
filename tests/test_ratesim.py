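import math

import numpy as np
import pytest

import geneshop as gs
from geneshop.likelihood import jc
from geneshop.ratesim import RateDecoration
from geneshop.trees import TreeError


class TestYule:
    def test_two_taxon_tree_is_a_cherry(self):
        t = gs.simulate_yule(2, 1.0, seed=0)
        assert t.n_tips == 2
        assert len(t.root.children) == 2
        assert t.is_ultrametric()

    def test_seed_determinism(self):
        a = gs.simulate_yule(12, 1.0, seed=42)
        b = gs.simulate_yule(12, 1.0, seed=42)
        assert a.newick() == b.newick()
        assert a.newick() != gs.simulate_yule(12, 1.0, seed=43).newick()

    def test_output_is_ultrametric_binary(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 20))
            t = gs.simulate_yule(n, 1.0, seed=rng)
            assert t.n_tips == n
            assert t.is_ultrametric()
            assert all(len(x.children) in (0, 2) for x in t.postorder())

    def test_speciation_rate_scales_height(self, rng):
        # doubling lambda halves expected waiting times
        heights1 = [gs.simulate_yule(8, 1.0, seed=rng).height() for _ in range(300)]
        heights2 = [gs.simulate_yule(8, 2.0, seed=rng).height() for _ in range(300)]
        assert np.mean(heights1) > 1.5 * np.mean(heights2)


class TestRescale:
    def test_exact_target_height(self, rng):
        t = gs.simulate_yule(9, 1.0, seed=rng)
        for h in (0.25, 0.5, 0.75):
            r = gs.rescale_height(t, h)
            assert r.height() == pytest.approx(h)
            assert r.is_ultrametric()

    def test_rescaling_twice_equals_once(self, rng):
        t = gs.simulate_yule(6, 1.0, seed=rng)
        twice = gs.rescale_height(gs.rescale_height(t, 0.25), 0.6)
        once = gs.rescale_height(t, 0.6)
        paths_twice, paths_once = twice.root_to_tip(), once.root_to_tip()
        for tip in paths_once:
            assert paths_twice[tip] == pytest.approx(paths_once[tip], rel=1e-12)

    def test_zero_height_rejected(self):
        flat = gs.parse_newick("((A:0,B:0):0,C:0);")
        with pytest.raises(TreeError):
            gs.rescale_height(flat, 1.0)


class TestApplyRates:
    def test_strict_rate_one_is_identity(self, yule12):
        phy = gs.apply_rates(yule12, RateDecoration("strict", global_rate=1.0, seed=1))
        assert phy.newick() == yule12.newick()

    def test_strict_scales_all_branches(self, yule12):
        phy = gs.apply_rates(yule12, RateDecoration("strict", global_rate=2.5, seed=1))
        assert phy.tree_length() == pytest.approx(2.5 * yule12.tree_length())
        assert phy.is_ultrametric()

    def test_zero_noise_equals_strict(self, yule12):
        noisy = gs.apply_rates(yule12, RateDecoration("noisy_clock", noise_sd=0.0, seed=3))
        assert noisy.newick() == yule12.newick()

    def test_decoration_seed_determinism(self, yule12):
        deco = RateDecoration("ucln", mean_log=-0.5, stdev_log=1.0, seed=11)
        assert gs.apply_rates(yule12, deco).newick() == gs.apply_rates(yule12, deco).newick()

    def test_noisy_rates_positive(self, yule12, rng):
        deco = RateDecoration("noisy_clock", global_rate=1.0, noise_sd=0.75)
        rates = [deco.draw_rate(rng) for _ in range(5000)]
        assert min(rates) > 0

    def test_ucln_mean_rate_matches_lognormal_moment(self, rng):
        # E[rate] = exp(mean_log + stdev_log^2 / 2)
        deco = RateDecoration("ucln", mean_log=-0.5, stdev_log=0.5)
        draws = np.array([deco.draw_rate(rng) for _ in range(100_000)])
        expected = math.exp(-0.5 + 0.5**2 / 2)
        se = draws.std() / math.sqrt(draws.size)
        assert abs(draws.mean() - expected) < 3 * se

    def test_variance_increases_with_dispersion(self, rng):
        chrono = gs.rescale_height(gs.simulate_yule(12, 1.0, seed=rng), 0.5)
        def mean_var(deco, reps=60):
            return np.mean(
                [gs.tree_stats(gs.apply_rates(chrono, deco, rng=rng)).rtt_variance
                 for _ in range(reps)]
            )
        noisy = [mean_var(RateDecoration("noisy_clock", noise_sd=s)) for s in (0.0, 0.25, 0.75)]
        assert noisy[0] < noisy[1] < noisy[2]
        ucln = [mean_var(RateDecoration("ucln", stdev_log=s)) for s in (0.5, 1.0)]
        assert ucln[0] < ucln[1]

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            RateDecoration("brownian")
        with pytest.raises(ValueError):
            RateDecoration("strict", global_rate=0.0)


class TestSimulateAlignment:
    def test_zero_length_branches_copy_sequences(self):
        t = gs.parse_newick("((A:0,B:0):0,C:0);")
        aln = gs.simulate_alignment(t, jc(), 100, seed=5)
        assert aln.sequences["A"] == aln.sequences["B"] == aln.sequences["C"]

    def test_seed_determinism(self, yule12):
        a = gs.simulate_alignment(yule12, jc(), 50, seed=9)
        b = gs.simulate_alignment(yule12, jc(), 50, seed=9)
        assert a.sequences == b.sequences

    def test_jc_pairwise_distance_matches_expectation(self):
        # P(diff) = 3/4 (1 - exp(-4 t / 3)) at total path t
        t = gs.parse_newick("(A:0.1,B:0.1);")
        aln = gs.simulate_alignment(t, jc(), 100_000, seed=13)
        p_obs = np.mean(
            [a != b for a, b in zip(aln.sequences["A"], aln.sequences["B"])]
        )
        p_exp = 0.75 * (1 - math.exp(-4 * 0.2 / 3))
        se = math.sqrt(p_exp * (1 - p_exp) / 100_000)
        assert abs(p_obs - p_exp) < 3.5 * se

    def test_inference_roundtrip_recovers_total_depth(self, rng):
        chrono = gs.rescale_height(gs.simulate_yule(6, 1.0, seed=rng), 0.4)
        aln = gs.simulate_alignment(chrono, jc(), 20_000, seed=rng)
        fitted, _ = gs.optimize_free(aln, chrono, jc())
        assert fitted.tree_length() == pytest.approx(chrono.tree_length(), rel=0.1)


class TestGenePool:
    def test_pool_is_deterministic_and_per_gene_independent(self, yule12):
        decos = {f"g{i}": RateDecoration("ucln", stdev_log=1.0) for i in range(4)}
        pool_a = gs.simulate_gene_pool(yule12, decos, jc(), 60, seed=21)
        pool_b = gs.simulate_gene_pool(yule12, decos, jc(), 60, seed=21)
        news_a = [t.newick() for t in pool_a.phylograms.values()]
        news_b = [t.newick() for t in pool_b.phylograms.values()]
        assert news_a == news_b
        assert len(set(news_a)) == 4  # fresh rate draws per gene
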