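"""The gene-shopping core: per-gene statistics, ranking and selection.

For every rooted gene tree the pipeline records three winnowing criteria:

* concordance — fraction of the gene tree's splits shared with the focal
  species tree (computed before outgroup removal);
* root-to-tip variance — clock-likeness, computed on the ingroup phylogram
  after the outgroup is pruned;
* tree length — information content, also on the ingroup tree.

Genes are then ranked lexicographically, by default most concordant first,
then lowest variance, then greatest tree length, and the top n are selected
for divergence-time estimation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .bipartitions import concordance_proportion
from .trees import (
    RootedTree,
    TreeError,
    drop_root_stem,
    prune_taxa,
    root_by_outgroup,
    tree_stats,
)

log = logging.getLogger(__name__)

COLUMNS = ["gene_id", "concordance", "rtt_variance", "tree_length", "flag"]

_DIRECTIONS = {
    "concordance": False,  # descending: more agreement with the species tree
    "rtt_variance": True,  # ascending: more clock-like
    "tree_length": False,  # descending: more information
}


@dataclass(frozen=True)
class GeneRecord:
    """One gene's winnowing statistics."""

    gene_id: str
    concordance: float
    rtt_variance: float
    tree_length: float
    clock_p_value: float | None = None
    flag: str = ""


@dataclass(frozen=True)
class RankingPolicy:
    """Criterion order, optional hard thresholds, and how many genes to keep.

    ``order`` is a permutation of ("concordance", "rtt_variance",
    "tree_length"); each criterion sorts in its natural direction
    (concordance and tree length descending, variance ascending).
    ``thresholds`` maps a criterion to a cutoff applied before sorting:
    minimum for concordance and tree length, maximum for variance.
    """

    order: tuple[str, ...] = ("concordance", "rtt_variance", "tree_length")
    thresholds: dict = field(default_factory=dict)
    n_select: int = 3

    def __post_init__(self):
        if sorted(self.order) != sorted(_DIRECTIONS):
            raise ValueError(
                f"order must be a permutation of {tuple(_DIRECTIONS)}, got {self.order}"
            )
        if self.n_select < 1:
            raise ValueError("n_select must be >= 1")
        unknown = set(self.thresholds) - set(_DIRECTIONS)
        if unknown:
            raise ValueError(f"unknown threshold criteria: {sorted(unknown)}")


def compute_gene_stats(
    gene_trees: dict[str, RootedTree],
    species_tree: RootedTree,
    outgroup: set[str] | None = None,
) -> pd.DataFrame:
    """Winnowing statistics for a collection of gene trees.

    Per gene: root by the outgroup (if given), score concordance against the
    species tree on the full rooted tree, prune the outgroup, then measure
    root-to-tip variance and tree length on the ingroup.  Genes that cannot
    be processed (unrootable outgroup, too few shared taxa) are skipped with
    a logged reason rather than aborting the run.  Rows are ordered by
    gene_id; genes missing ingroup taxa are flagged ``reduced_taxa``.
    """
    outgroup = set(outgroup or ())
    sp_ingroup = set(species_tree.tip_labels()) - outgroup
    rows = []
    for gene_id in sorted(gene_trees):
        tree = gene_trees[gene_id]
        try:
            if outgroup:
                og_here = outgroup & set(tree.tip_labels())
                if not og_here:
                    raise TreeError("no outgroup taxon present")
                rooted = root_by_outgroup(tree, og_here)
            else:
                og_here = set()
                rooted = tree
            conc = concordance_proportion(rooted, species_tree).concordance
            ingroup = rooted if not og_here else drop_root_stem(prune_taxa(rooted, og_here))
            stats = tree_stats(ingroup)
            flag = ""
            if set(ingroup.tip_labels()) != sp_ingroup:
                flag = "reduced_taxa"
            rows.append(
                {
                    "gene_id": gene_id,
                    "concordance": conc,
                    "rtt_variance": stats.rtt_variance,
                    "tree_length": stats.tree_length,
                    "flag": flag,
                }
            )
        except TreeError as exc:
            log.warning("skipping gene %s: %s", gene_id, exc)
    return pd.DataFrame(rows, columns=COLUMNS)


def rank_genes(records: pd.DataFrame, policy: RankingPolicy | None = None) -> pd.DataFrame:
    """Lexicographic ranking by the policy's criteria.

    Thresholded genes are dropped before sorting; the sort is stable, with a
    final gene_id tie-break so output is bit-reproducible regardless of the
    input row order.
    """
    policy = policy or RankingPolicy()
    df = records.copy()
    for crit, cut in policy.thresholds.items():
        if _DIRECTIONS[crit]:  # ascending criterion: threshold is a maximum
            df = df[df[crit] <= cut]
        else:
            df = df[df[crit] >= cut]
    if len(df) == 0 and len(records) > 0:
        log.warning("all %d genes excluded by thresholds", len(records))
        return df.reset_index(drop=True)
    by = list(policy.order) + ["gene_id"]
    ascending = [_DIRECTIONS[c] for c in policy.order] + [True]
    return df.sort_values(by=by, ascending=ascending, kind="stable").reset_index(
        drop=True
    )


def select_genes(
    ranked: pd.DataFrame,
    n: int,
    alignment_lengths: dict[str, int] | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Top-n genes plus a concatenation manifest.

    The manifest lists, per selected gene, 1-based [start, end] columns of
    its partition in the concatenated supermatrix (contiguous, no gaps or
    overlap), when alignment lengths are provided.
    """
    if n > len(ranked):
        log.warning("requested %d genes but only %d available", n, len(ranked))
    top = ranked.head(n).reset_index(drop=True)
    manifest = []
    pos = 0
    for gene_id in top["gene_id"]:
        entry = {"gene_id": gene_id}
        if alignment_lengths is not None:
            length = alignment_lengths[gene_id]
            entry["start"] = pos + 1
            entry["end"] = pos + length
            pos += length
        manifest.append(entry)
    return top, manifest
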