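"""Deterministic simulated datasets packaging the study's scenarios.

Each profile writes a self-contained directory: a species chronogram with an
outgroup, per-gene true phylograms, simulated alignments, a truth table, and
the expected shopping table computed from the true gene trees — the whole
thing reproducible byte-for-byte from (profile, seed).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .likelihood import model_for
from .ratesim import (
    RateDecoration,
    apply_rates,
    rescale_height,
    simulate_alignment,
    simulate_yule,
)
from .shop import RankingPolicy, compute_gene_stats, rank_genes
from .trees import Node, RootedTree, tree_stats

OUTGROUP_LABEL = "OUT"

_PROFILE_DECOS = {
    "clock": [RateDecoration("strict", global_rate=1.0)],
    "noisy25": [RateDecoration("noisy_clock", global_rate=1.0, noise_sd=0.25)],
    "noisy75": [RateDecoration("noisy_clock", global_rate=1.0, noise_sd=0.75)],
    "ucln05": [RateDecoration("ucln", mean_log=-0.5, stdev_log=0.5)],
    "ucln10": [RateDecoration("ucln", mean_log=-0.5, stdev_log=1.0)],
}
_PROFILE_DECOS["mixed_pool"] = [d for v in _PROFILE_DECOS.values() for d in v]

PROFILES = tuple(_PROFILE_DECOS)


def attach_outgroup(
    chronogram: RootedTree, label: str = OUTGROUP_LABEL, stem_fraction: float = 0.2
) -> RootedTree:
    """Add an outgroup tip below a new root, keeping the tree ultrametric."""
    height = chronogram.height()
    stem = stem_fraction * height
    new_root = Node()
    old = chronogram.copy().root
    old.length = stem
    new_root.add_child(old)
    new_root.add_child(Node(label=label, length=height + stem))
    return RootedTree(new_root)


def make_fixtures(
    profile: str,
    seed: int,
    outdir,
    n_taxa: int = 12,
    n_genes: int = 10,
    alignment_length: int = 500,
    alphabet: str = "nt",
    tree_height: float = 0.5,
) -> Path:
    """Write a fixture directory for a named simulation profile.

    Profiles: clock, noisy25, noisy75, ucln05, ucln10 (one rate model for
    every gene) and mixed_pool (genes cycle through all five conditions).
    """
    if profile not in _PROFILE_DECOS:
        raise ValueError(
            f"unknown profile {profile!r}; valid profiles: {', '.join(PROFILES)}"
        )
    outdir = Path(outdir)
    (outdir / "gene_trees").mkdir(parents=True, exist_ok=True)
    (outdir / "alignments").mkdir(exist_ok=True)

    rng = np.random.default_rng(seed)
    ingroup = rescale_height(simulate_yule(n_taxa, 1.0, seed=rng), tree_height)
    species = attach_outgroup(ingroup)
    (outdir / "species.tre").write_text(species.newick() + "\n")

    model = model_for(alphabet)
    decos = _PROFILE_DECOS[profile]
    gene_trees = {}
    truth_rows = []
    for g in range(n_genes):
        gene_id = f"g{g:03d}"
        deco = decos[g % len(decos)]
        phy = apply_rates(species, deco, rng=rng)
        gene_trees[gene_id] = phy
        (outdir / "gene_trees" / f"{gene_id}.tre").write_text(phy.newick() + "\n")
        aln = simulate_alignment(phy, model, alignment_length, seed=rng)
        aln.to_fasta(outdir / "alignments" / f"{gene_id}.fasta")
        stats = tree_stats(phy)
        truth_rows.append(
            {
                "gene_id": gene_id,
                "rate_model": deco.kind,
                "global_rate": deco.global_rate,
                "noise_sd": deco.noise_sd,
                "mean_log": deco.mean_log,
                "stdev_log": deco.stdev_log,
                "true_tree_length": stats.tree_length,
                "true_rtt_variance": stats.rtt_variance,
            }
        )
    pd.DataFrame(truth_rows).to_csv(outdir / "truth.tsv", sep="\t", index=False)

    stats = compute_gene_stats(gene_trees, species, outgroup={OUTGROUP_LABEL})
    ranked = rank_genes(stats, RankingPolicy(n_select=3))
    ranked.to_csv(outdir / "expected_shop.tsv", sep="\t", index=False)

    meta = {
        "profile": profile,
        "seed": seed,
        "n_taxa": n_taxa,
        "n_genes": n_genes,
        "alignment_length": alignment_length,
        "alphabet": alphabet,
        "tree_height": tree_height,
        "outgroup": OUTGROUP_LABEL,
    }
    (outdir / "profile.json").write_text(json.dumps(meta, indent=2) + "\n")
    return outdir
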