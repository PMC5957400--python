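"""Independent reference implementations used to cross-check the package.

These deliberately avoid the package's own algorithms: bipartitions come
from dendropy's tree model, and likelihoods from exhaustive enumeration of
internal-state assignments with explicit transition matrices.
"""

from __future__ import annotations

import itertools
import math

import dendropy
import numpy as np


def dendropy_splits(newick: str) -> tuple[set[frozenset], frozenset]:
    """Nontrivial splits of the unrooted topology, as canonical frozensets."""
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = False
    taxa = frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())
    splits: set[frozenset] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        other = taxa - side
        if len(side) < 2 or len(other) < 2:
            continue
        canonical = min(
            (len(side), tuple(sorted(side))), (len(other), tuple(sorted(other)))
        )
        splits.add(frozenset(canonical[1]))
    return splits, taxa


def bruteforce_concordance(gene_newick: str, species_newick: str) -> float:
    """|gene splits shared with species tree| / |gene splits|, via dendropy."""
    g, gt = dendropy_splits(gene_newick)
    s, st = dendropy_splits(species_newick)
    assert gt == st, "oracle expects identical taxon sets"
    if not g:
        return 1.0
    return len(g & s) / len(g)


def enumeration_log_likelihood(alignment, tree, model) -> float:
    """Exact likelihood by summing over every internal-state assignment."""
    taxa = alignment.taxa
    enc = alignment.encode(taxa)
    row = {t: i for i, t in enumerate(taxa)}
    nodes = list(tree.postorder())
    internals = [n for n in nodes if n.children]
    P = {id(n): model.transition_matrix(n.length or 0.0) for n in nodes}
    k = model.k
    total = 0.0
    for j in range(alignment.length):
        site = 0.0
        for assign in itertools.product(range(k), repeat=len(internals)):
            state = {id(n): s for n, s in zip(internals, assign)}
            p = model.frequencies[state[id(tree.root)]]
            for n in nodes:
                if n is tree.root:
                    continue
                parent_state = state[id(n.parent)]
                if n.is_tip:
                    obs = enc[row[n.label], j]
                    factor = 1.0 if obs < 0 else P[id(n)][parent_state, obs]
                else:
                    factor = P[id(n)][parent_state, state[id(n)]]
                p *= factor
                if p == 0.0:
                    break
            site += p
        total += math.log(site)
    return total


def nni_neighbor(tree, rng: np.random.Generator):
    """One nearest-neighbor-interchange move on a copy of a binary tree.

    Swaps a child of an internal node v with v's sibling, which replaces
    exactly one nontrivial split of the unrooted topology.
    """
    t = tree.copy()
    candidates = [
        n
        for n in t.postorder()
        if n.children and n.parent is not None and n.parent.parent is not None
    ]
    v = candidates[int(rng.integers(len(candidates)))]
    p = v.parent
    sibling = next(c for c in p.children if c is not v)
    child = v.children[int(rng.integers(len(v.children)))]
    v.children[v.children.index(child)] = sibling
    p.children[p.children.index(sibling)] = child
    sibling.parent = v
    child.parent = p
    return type(tree)(t.root)
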