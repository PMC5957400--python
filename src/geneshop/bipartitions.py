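"""Bipartitions (taxon splits) and gene-tree/species-tree concordance.

Removing an internal edge of an unrooted tree partitions the taxa in two;
these splits are the rooting-free description of a topology.  A gene tree's
concordance with the species tree is the fraction of its nontrivial splits
that are also present in the species tree after both trees are restricted to
their shared taxa — 1.0 means complete topological agreement.
"""

from __future__ import annotations

from dataclasses import dataclass

from .trees import RootedTree, TreeError, prune_taxa


@dataclass(frozen=True)
class Bipartition:
    """A nontrivial taxon split, canonicalized so a split equals its complement.

    ``side`` stores the smaller half (ties broken by sorted-tuple order) and
    ``universe`` the full taxon set the split was computed on.
    """

    side: frozenset[str]
    universe: frozenset[str]

    @staticmethod
    def of(side, universe) -> "Bipartition":
        side = frozenset(side)
        universe = frozenset(universe)
        other = universe - side
        if len(other) < len(side) or (
            len(other) == len(side) and tuple(sorted(other)) < tuple(sorted(side))
        ):
            side = other
        return Bipartition(side, universe)

    @property
    def complement(self) -> frozenset[str]:
        return self.universe - self.side


@dataclass(frozen=True)
class ConcordanceResult:
    shared_count: int
    gene_biparts: int
    concordance: float
    shared_taxa: frozenset[str]


def extract_bipartitions(
    tree: RootedTree, universe: frozenset[str] | None = None
) -> set[Bipartition]:
    """All nontrivial splits of the tree's unrooted topology.

    Each internal edge yields one split; trivial splits (one side a single
    taxon) are excluded, and the two edges incident to a bifurcating root
    collapse to the same unrooted split.  Trees with fewer than 4 taxa have
    no nontrivial splits and yield an empty set.
    """
    tips = frozenset(tree.tip_labels())
    if universe is None:
        universe = tips
    elif not tips <= frozenset(universe):
        raise TreeError("tree tips are not a subset of the universe")
    if len(tips) < 4:
        return set()

    out: set[Bipartition] = set()
    below: dict[int, frozenset[str]] = {}
    for node in tree.postorder():
        if node.is_tip:
            below[id(node)] = frozenset([node.label])
            continue
        s = frozenset().union(*(below[id(c)] for c in node.children))
        below[id(node)] = s
        if node is tree.root:
            continue
        if len(s) >= 2 and len(tips - s) >= 2:
            out.add(Bipartition.of(s, tips))
    return out


def concordance_proportion(
    gene_tree: RootedTree,
    species_tree: RootedTree,
    denominator: str = "gene",
) -> ConcordanceResult:
    """Fraction of the gene tree's splits that agree with the species tree.

    Both trees are first restricted to their shared taxa; splits are then
    compared on that set.  With ``denominator="gene"`` (the default) the
    proportion is over the gene tree's nontrivial splits, which stays
    well-defined when the gene is missing taxa; ``denominator="species"``
    divides by the restricted species tree's split count instead.

    A gene tree with no nontrivial splits on the shared set (a star) has
    nothing to disagree with and scores 1.0.
    """
    if denominator not in ("gene", "species"):
        raise ValueError("denominator must be 'gene' or 'species'")
    gene_taxa = set(gene_tree.tip_labels())
    sp_taxa = set(species_tree.tip_labels())
    shared = frozenset(gene_taxa & sp_taxa)
    if len(shared) < 4:
        raise TreeError(
            f"insufficient taxon overlap: {len(shared)} shared taxa (need >= 4)"
        )
    g = gene_tree if gene_taxa == shared else prune_taxa(gene_tree, gene_taxa - shared)
    s = (
        species_tree
        if sp_taxa == shared
        else prune_taxa(species_tree, sp_taxa - shared)
    )
    gene_splits = extract_bipartitions(g)
    sp_splits = extract_bipartitions(s)
    shared_count = len(gene_splits & sp_splits)
    denom = len(gene_splits) if denominator == "gene" else len(sp_splits)
    concordance = shared_count / denom if denom else 1.0
    return ConcordanceResult(
        shared_count=shared_count,
        gene_biparts=len(gene_splits),
        concordance=concordance,
        shared_taxa=shared,
    )
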