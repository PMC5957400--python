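import numpy as np
import pandas as pd
import pytest

import geneshop as gs
from geneshop.shop import RankingPolicy, compute_gene_stats, rank_genes, select_genes


def _records(rows):
    return pd.DataFrame(
        [
            {"gene_id": g, "concordance": c, "rtt_variance": v, "tree_length": l, "flag": ""}
            for g, c, v, l in rows
        ]
    )


class TestRanking:
    def test_lexicographic_order(self):
        df = _records(
            [("g1", 1.0, 0.01, 2.0), ("g2", 0.8, 0.001, 5.0), ("g3", 1.0, 0.002, 1.0)]
        )
        ranked = rank_genes(df)
        assert list(ranked["gene_id"]) == ["g3", "g1", "g2"]

    def test_ties_break_by_gene_id(self):
        df = _records([("b", 1.0, 0.1, 1.0), ("a", 1.0, 0.1, 1.0), ("c", 1.0, 0.1, 1.0)])
        assert list(rank_genes(df)["gene_id"]) == ["a", "b", "c"]

    def test_invariant_to_input_row_order(self, rng):
        rows = [
            (f"g{i}", float(rng.choice([0.6, 0.8, 1.0])), float(rng.random()),
             float(rng.random() * 5))
            for i in range(20)
        ]
        df = _records(rows)
        shuffled = df.sample(frac=1.0, random_state=3).reset_index(drop=True)
        assert list(rank_genes(df)["gene_id"]) == list(rank_genes(shuffled)["gene_id"])

    def test_threshold_excludes_genes(self):
        df = _records(
            [("g1", 1.0, 0.01, 2.0), ("g2", 0.8, 0.001, 5.0), ("g3", 1.0, 0.002, 1.0)]
        )
        ranked = rank_genes(df, RankingPolicy(thresholds={"concordance": 0.9}))
        assert list(ranked["gene_id"]) == ["g3", "g1"]

    def test_all_excluded_warns_and_returns_empty(self, caplog):
        df = _records([("g1", 0.5, 0.1, 1.0)])
        with caplog.at_level("WARNING"):
            out = rank_genes(df, RankingPolicy(thresholds={"concordance": 0.9}))
        assert len(out) == 0
        assert "excluded" in caplog.text

    def test_custom_criterion_order(self):
        df = _records([("g1", 0.5, 0.001, 9.0), ("g2", 1.0, 0.5, 1.0)])
        by_var = rank_genes(df, RankingPolicy(order=("rtt_variance", "concordance", "tree_length")))
        assert list(by_var["gene_id"]) == ["g1", "g2"]

    def test_invalid_policy_rejected(self):
        with pytest.raises(ValueError):
            RankingPolicy(order=("concordance", "concordance", "tree_length"))
        with pytest.raises(ValueError):
            RankingPolicy(thresholds={"length": 1.0})


class TestComputeGeneStats:
    def test_clock_genes_on_species_topology(self, rng):
        from geneshop.fixtures import attach_outgroup

        ingroup = gs.rescale_height(gs.simulate_yule(8, 1.0, seed=rng), 0.5)
        species = attach_outgroup(ingroup)
        genes = {
            f"g{i}": gs.apply_rates(species, gs.RateDecoration("strict"), rng=rng)
            for i in range(3)
        }
        df = compute_gene_stats(genes, species, outgroup={"OUT"})
        assert list(df["gene_id"]) == ["g0", "g1", "g2"]
        assert (df["concordance"] == 1.0).all()
        assert (df["rtt_variance"] < 1e-18).all()
        # tree length excludes the outgroup subtree and the rooting stem
        assert df.loc[0, "tree_length"] == pytest.approx(ingroup.tree_length())

    def test_gene_missing_taxa_is_flagged_and_consistent(self, rng):
        from geneshop.fixtures import attach_outgroup

        species = attach_outgroup(gs.rescale_height(gs.simulate_yule(8, 1.0, seed=rng), 0.5))
        full = gs.apply_rates(species, gs.RateDecoration("ucln"), rng=rng)
        ingroup_tips = [t for t in full.tip_labels() if t != "OUT"]
        reduced = gs.prune_taxa(full, {ingroup_tips[0]})
        df = compute_gene_stats({"g": reduced}, species, outgroup={"OUT"})
        assert df.loc[0, "flag"] == "reduced_taxa"
        oracle = gs.tree_stats(
            gs.drop_root_stem(gs.prune_taxa(gs.root_by_outgroup(reduced, {"OUT"}), {"OUT"}))
        )
        assert df.loc[0, "rtt_variance"] == pytest.approx(oracle.rtt_variance)
        assert df.loc[0, "tree_length"] == pytest.approx(oracle.tree_length)

    def test_gene_without_outgroup_taxon_skipped(self, rng, caplog):
        species = gs.simulate_yule(6, 1.0, seed=rng)
        outgroup_tip = species.tip_labels()[0]
        genes = {
            "good": gs.apply_rates(species, gs.RateDecoration("strict"), rng=rng),
            "bad": gs.prune_taxa(species, {outgroup_tip}),
        }
        with caplog.at_level("WARNING"):
            df = compute_gene_stats(genes, species, outgroup={outgroup_tip})
        assert list(df["gene_id"]) == ["good"]
        assert "bad" in caplog.text

    def test_empty_input_gives_empty_table(self):
        df = compute_gene_stats({}, gs.parse_newick("((A:1,B:1):1,C:1);"))
        assert len(df) == 0
        assert list(df.columns) == ["gene_id", "concordance", "rtt_variance", "tree_length", "flag"]


class TestSelect:
    def test_top_n_and_manifest_tiling(self):
        df = _records([(f"g{i}", 1.0, i / 100, 1.0) for i in range(10)])
        ranked = rank_genes(df)
        lengths = {f"g{i}": 100 + i for i in range(10)}
        top, manifest = select_genes(ranked, 3, alignment_lengths=lengths)
        assert len(top) == 3
        pos = 1
        for entry in manifest:
            assert entry["start"] == pos
            assert entry["end"] == entry["start"] + lengths[entry["gene_id"]] - 1
            pos = entry["end"] + 1

    def test_requesting_more_than_available_warns(self, caplog):
        df = _records([("g1", 1.0, 0.1, 1.0), ("g2", 1.0, 0.2, 1.0)])
        with caplog.at_level("WARNING"):
            top, _ = select_genes(rank_genes(df), 3)
        assert len(top) == 2
        assert "only 2" in caplog.text


class TestSelectionProperty:
    def test_shopped_genes_have_lower_mean_variance_than_random(self, rng):
        """Selection by the winnowing criteria picks more clock-like genes
        than uniform sampling, in expectation over many simulated pools."""
        diffs = []
        for _ in range(100):
            chrono = gs.rescale_height(gs.simulate_yule(10, 1.0, seed=rng), 0.5)
            genes = {}
            for i in range(20):
                noise = float(rng.choice([0.0, 0.25, 0.75]))
                genes[f"g{i:02d}"] = gs.apply_rates(
                    chrono, gs.RateDecoration("noisy_clock", noise_sd=noise), rng=rng
                )
            df = compute_gene_stats(genes, chrono)
            ranked = rank_genes(df)
            shopped = ranked["rtt_variance"].head(3).mean()
            random_ids = rng.choice(df["gene_id"], size=3, replace=False)
            random_mean = df.set_index("gene_id").loc[random_ids, "rtt_variance"].mean()
            diffs.append(shopped - random_mean)
        assert np.mean(diffs) < 0
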