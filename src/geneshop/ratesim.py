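"""Simulators for the validation experiments.

Covers the full generative pipeline used to study the winnowing procedure:

1. a Yule (pure-birth) chronogram for the species history;
2. a branch-rate decoration turning the chronogram into a phylogram —
   strict clock (one global rate), *noisy clock* (global rate plus a
   zero-mean Gaussian perturbation per branch, redrawn until positive) or
   *UCLN* (independent lognormal rate per branch, parameterized by the mean
   and standard deviation of the log rate);
3. substitution-only sequence evolution along the phylogram (JC for
   nucleotides, Poisson for amino acids).

Everything is seed-deterministic: the same parameters and seed give
byte-identical trees and alignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .likelihood import Alignment, SubstitutionModel
from .trees import Node, RootedTree, TreeError


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


@dataclass(frozen=True)
class RateDecoration:
    """Branch-rate model mapping a chronogram to a phylogram.

    kind="strict"       rate = global_rate on every branch
    kind="noisy_clock"  rate = global_rate + Normal(0, noise_sd), redrawn
                        until positive
    kind="ucln"         rate = LogNormal(mean_log, stdev_log), i.i.d. per
                        branch (parameters on the natural-log scale)
    """

    kind: Literal["strict", "noisy_clock", "ucln"]
    global_rate: float = 1.0
    noise_sd: float = 0.0
    mean_log: float = -0.5
    stdev_log: float = 0.5
    seed: int | None = None

    def __post_init__(self):
        if self.kind not in ("strict", "noisy_clock", "ucln"):
            raise ValueError(f"unknown rate model {self.kind!r}")
        if self.global_rate <= 0:
            raise ValueError("global_rate must be positive")
        if self.noise_sd < 0 or self.stdev_log < 0:
            raise ValueError("dispersion parameters must be non-negative")

    def draw_rate(self, rng: np.random.Generator) -> float:
        if self.kind == "strict":
            return self.global_rate
        if self.kind == "noisy_clock":
            while True:
                r = self.global_rate + rng.normal(0.0, self.noise_sd)
                if r > 0:
                    return r
        return float(rng.lognormal(self.mean_log, self.stdev_log))


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a multi-gene simulation experiment."""

    n_taxa: int = 12
    speciation_rate: float = 1.0
    root_height_rescale: float | None = None
    alignment_length: int = 1500
    alphabet: str = "nt"
    n_genes: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 3:
            raise ValueError("n_taxa must be >= 3")
        if self.alignment_length < 1:
            raise ValueError("alignment_length must be positive")


def simulate_yule(n_taxa: int, speciation_rate: float = 1.0, seed=None) -> RootedTree:
    """Pure-birth chronogram with ``n_taxa`` tips.

    The process starts from two lineages at the root; with k extant lineages
    the waiting time to the next speciation is Exp(k * lambda) and the
    splitting lineage is uniform.  It stops at the n-th birth, so the root
    height is a sum of exponentials with means 1/(k*lambda), k = 2..n-1
    (for n=12, lambda=1 the expectation is sum_{k=2}^{11} 1/k ~ 2.0199).
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    if speciation_rate <= 0:
        raise ValueError("speciation rate must be positive")
    rng = _rng(seed)
    root = Node()
    active = [root.add_child(Node(length=0.0)), root.add_child(Node(length=0.0))]
    while len(active) < n_taxa:
        dt = rng.exponential(1.0 / (len(active) * speciation_rate))
        for node in active:
            node.length += dt
        idx = rng.integers(len(active))
        parent = active.pop(int(idx))
        active.append(parent.add_child(Node(length=0.0)))
        active.append(parent.add_child(Node(length=0.0)))
    for i, node in enumerate(active):
        node.label = f"t{i + 1}"
    return RootedTree(root)


def rescale_height(tree: RootedTree, target_height: float) -> RootedTree:
    """Multiply all branch lengths so the tree height equals ``target_height``."""
    height = tree.height()
    if height <= 0:
        raise TreeError("cannot rescale a zero-height tree")
    if target_height <= 0:
        raise ValueError("target height must be positive")
    factor = target_height / height
    out = tree.copy()
    for node in out.postorder():
        if node.length is not None:
            node.length *= factor
    return out


def apply_rates(
    chronogram: RootedTree,
    decoration: RateDecoration,
    rng=None,
    return_rates: bool = False,
):
    """Decorate a chronogram with branch rates, returning the phylogram.

    Branches are visited in a deterministic preorder, so the same decoration
    seed always yields the same phylogram.  With ``return_rates=True`` a
    parallel preorder list of the drawn rates is returned too.
    """
    if rng is None:
        rng = _rng(decoration.seed)
    else:
        rng = _rng(rng)
    out = chronogram.copy()
    rates = []
    for node in out.preorder():
        if node is out.root:
            continue
        r = decoration.draw_rate(rng)
        rates.append(r)
        node.length = (node.length or 0.0) * r
    tree = RootedTree(out.root)
    return (tree, rates) if return_rates else tree


def simulate_alignment(
    phylogram: RootedTree, model: SubstitutionModel, length: int, seed=None
) -> Alignment:
    """Evolve sequences down the phylogram under the substitution model.

    The root sequence is drawn from the stationary frequencies; each branch
    applies the closed-form transition probabilities of the equal-rates
    model (a site either keeps its state or moves uniformly to one of the
    other k-1 states).  Output is gap-free.
    """
    if length < 1:
        raise ValueError("alignment length must be >= 1")
    rng = _rng(seed)
    k = model.k
    states = model.states
    seqs: dict[str, str] = {}
    root_states = rng.integers(k, size=length)
    stack = [(phylogram.root, root_states)]
    while stack:
        node, parent_states = stack.pop()
        if node is phylogram.root:
            node_states = parent_states
        else:
            t = node.length or 0.0
            p_same = model.p_same(t)
            change = rng.random(length) >= p_same
            node_states = parent_states.copy()
            n_changed = int(change.sum())
            if n_changed:
                # jump uniformly to one of the other k-1 states
                shift = rng.integers(1, k, size=n_changed)
                node_states[change] = (node_states[change] + shift) % k
        if node.is_tip:
            seqs[node.label] = "".join(states[s] for s in node_states)
        else:
            for child in reversed(node.children):
                stack.append((child, node_states))
    alphabet = "nt" if len(states) == 4 else "aa"
    return Alignment(seqs, alphabet)


@dataclass
class GenePool:
    """A simulated multi-gene dataset on one shared chronogram."""

    chronogram: RootedTree
    phylograms: dict[str, RootedTree] = field(default_factory=dict)
    alignments: dict[str, Alignment] = field(default_factory=dict)
    decorations: dict[str, RateDecoration] = field(default_factory=dict)


def simulate_gene_pool(
    chronogram: RootedTree,
    decorations: dict[str, RateDecoration],
    model: SubstitutionModel,
    length: int,
    seed=None,
) -> GenePool:
    """Simulate many genes on one chronogram, fresh rate draws per gene."""
    rng = _rng(seed)
    pool = GenePool(chronogram=chronogram)
    for gene_id, deco in decorations.items():
        phy = apply_rates(chronogram, deco, rng=rng)
        pool.phylograms[gene_id] = phy
        pool.alignments[gene_id] = simulate_alignment(phy, model, length, seed=rng)
        pool.decorations[gene_id] = deco
    return pool
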