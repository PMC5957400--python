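"""Pruning-algorithm likelihood, ML optimization and the strict-clock test.

The engine computes exact log-likelihoods on a fixed rooted topology under
equal-exchangeability substitution models (Jukes–Cantor for nucleotides and
its 20-state Poisson analog for amino acids), optimizes either free branch
lengths or clock-constrained node heights by monotone coordinate ascent, and
runs the standard molecular-clock likelihood-ratio test:

    2 (lnL_free - lnL_clock)  ~  chi^2 with n - 2 degrees of freedom,

from the parameter counts 2n-3 (free branch lengths of the unrooted tree)
versus n-1 (node heights under the clock) for n taxa.

For a k-state model with uniform frequencies and exchangeabilities, scaled
to mean rate 1, the transition probabilities are

    P_ij(t) = 1/k + (delta_ij - 1/k) * exp(-beta t),   beta = k / (k - 1),

so propagating a conditional-likelihood matrix across a branch costs
O(patterns x states) — no matrix exponentials are needed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

from .trees import Node, RootedTree, TreeError

_MIN_BL = 1e-8
_MAX_BL = 20.0
_MIN_DT = 1e-9

NT_STATES = "ACGT"
AA_STATES = "ARNDCQEGHILKMFPSTWYV"


class AlignmentError(ValueError):
    pass


@dataclass
class Alignment:
    """A taxon-indexed character matrix (nucleotide or amino acid).

    Characters outside the alphabet (gaps, ambiguity codes, ``N``/``X``/``?``)
    are treated as missing data: their conditional likelihood is 1 for every
    state.
    """

    sequences: dict[str, str]
    alphabet: str  # "nt" or "aa"

    def __post_init__(self):
        if self.alphabet not in ("nt", "aa"):
            raise AlignmentError(f"unknown alphabet {self.alphabet!r}")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise AlignmentError(f"sequences differ in length: {sorted(lengths)}")
        if not self.sequences:
            raise AlignmentError("empty alignment")

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def taxa(self) -> list[str]:
        return list(self.sequences)

    @property
    def states(self) -> str:
        return NT_STATES if self.alphabet == "nt" else AA_STATES

    @classmethod
    def from_fasta(cls, path, alphabet: str) -> "Alignment":
        from Bio import SeqIO

        seqs = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in seqs:
                raise AlignmentError(f"duplicate taxon {rec.id!r} in {path}")
            seqs[rec.id] = str(rec.seq).upper()
        return cls(seqs, alphabet)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for taxon, seq in self.sequences.items():
                fh.write(f">{taxon}\n{seq}\n")

    def subset(self, taxa) -> "Alignment":
        return Alignment({t: self.sequences[t] for t in taxa}, self.alphabet)

    def encode(self, taxa_order: list[str]) -> np.ndarray:
        """Integer matrix (n_taxa, n_sites); missing characters are -1."""
        states = self.states
        lut = np.full(128, -1, dtype=np.int8)
        for i, c in enumerate(states):
            lut[ord(c)] = i
            lut[ord(c.lower())] = i
        if self.alphabet == "nt":
            lut[ord("U")] = lut[ord("u")] = states.index("T")
        rows = []
        for t in taxa_order:
            raw = np.frombuffer(self.sequences[t].encode("ascii"), dtype=np.uint8)
            rows.append(lut[raw])
        return np.vstack(rows)


def concatenate(alignments: list[Alignment]) -> tuple[Alignment, list[tuple[int, int]]]:
    """Concatenate same-taxon alignments; returns 1-based [start, end] partitions."""
    taxa = alignments[0].taxa
    for a in alignments[1:]:
        if set(a.taxa) != set(taxa):
            raise AlignmentError("alignments do not share a taxon set")
    parts, pos = [], 0
    seqs = {t: [] for t in taxa}
    for a in alignments:
        parts.append((pos + 1, pos + a.length))
        pos += a.length
        for t in taxa:
            seqs[t].append(a.sequences[t])
    return Alignment({t: "".join(v) for t, v in seqs.items()}, alignments[0].alphabet), parts


@dataclass(frozen=True)
class SubstitutionModel:
    """Equal-rates reversible model with uniform stationary frequencies."""

    name: str
    states: str

    @property
    def k(self) -> int:
        return len(self.states)

    @property
    def beta(self) -> float:
        # normalizes the rate matrix to one expected substitution per unit time
        k = self.k
        return k / (k - 1.0)

    @property
    def frequencies(self) -> np.ndarray:
        return np.full(self.k, 1.0 / self.k)

    def transition_matrix(self, t: float) -> np.ndarray:
        e = np.exp(-self.beta * t)
        k = self.k
        return np.full((k, k), (1.0 - e) / k) + e * np.eye(k)

    def p_same(self, t: float) -> float:
        """Probability that a site is in the same state after time t."""
        e = np.exp(-self.beta * t)
        return e + (1.0 - e) / self.k


def jc() -> SubstitutionModel:
    """Jukes–Cantor nucleotide model."""
    return SubstitutionModel("JC", NT_STATES)


def poisson() -> SubstitutionModel:
    """20-state amino-acid analog of Jukes–Cantor (uniform exchangeabilities)."""
    return SubstitutionModel("Poisson", AA_STATES)


def model_for(alphabet: str) -> SubstitutionModel:
    return jc() if alphabet == "nt" else poisson()


@dataclass(frozen=True)
class ClockTestResult:
    """Outcome of the strict-clock likelihood-ratio test for one gene."""

    lnL_free: float
    lnL_clock: float
    statistic: float
    df: int
    p_value: float
    alpha: float
    rejected: bool


# ---------------------------------------------------------------------------
# engine internals
# ---------------------------------------------------------------------------


def _compress_patterns(data: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Site-pattern compression, merging patterns equal up to state relabeling.

    The engine's models are fully state-symmetric (uniform frequencies and
    exchangeabilities), so a site's likelihood depends only on which taxa
    share states, not on the states themselves.  Each column is relabeled by
    order of first appearance (missing stays -1) before deduplication.
    """
    n, L = data.shape
    eq = data[None, :, :] == np.arange(k, dtype=data.dtype)[:, None, None]  # (k,n,L)
    has = eq.any(axis=1)
    first = np.where(has, eq.argmax(axis=1), n)  # row of first occurrence
    order = np.argsort(first, axis=0, kind="stable")
    rank = np.argsort(order, axis=0).astype(data.dtype)
    canon = np.where(data >= 0, rank[data.clip(min=0), np.arange(L)], -1)
    return np.unique(canon, axis=1, return_counts=True)


class _Engine:
    """Pruning likelihood on an indexed copy of a rooted topology.

    Nodes are indexed in postorder (root last).  ``lengths[i]`` is the branch
    above node i.  Site patterns are compressed with multiplicity weights.
    """

    def __init__(self, alignment: Alignment, tree: RootedTree, model: SubstitutionModel):
        tree_taxa = set(tree.tip_labels())
        aln_taxa = set(alignment.sequences)
        if tree_taxa != aln_taxa:
            diff = sorted(tree_taxa ^ aln_taxa)
            raise TreeError(f"alignment/tree taxon mismatch: {diff}")
        self.model = model
        self.tree = tree.copy()
        self.nodes: list[Node] = list(self.tree.postorder())
        self.index = {id(n): i for i, n in enumerate(self.nodes)}
        self.parent = np.array(
            [self.index[id(n.parent)] if n.parent is not None else -1 for n in self.nodes]
        )
        self.children: list[list[int]] = [
            [self.index[id(c)] for c in n.children] for n in self.nodes
        ]
        self.root = len(self.nodes) - 1
        self.lengths = np.array(
            [n.length if n.length is not None else 0.0 for n in self.nodes]
        )
        self.tip_idx = [i for i, n in enumerate(self.nodes) if n.is_tip]
        taxa_order = [self.nodes[i].label for i in self.tip_idx]

        data = alignment.encode(taxa_order)
        patterns, counts = _compress_patterns(data, model.k)
        self.counts = counts.astype(float)
        self.n_pat = patterns.shape[1]
        k = model.k
        self.k = k
        self.pi = model.frequencies

        # tip conditional likelihoods: one-hot, missing = all ones
        self.tip_partial: dict[int, np.ndarray] = {}
        for row, i in enumerate(self.tip_idx):
            P = np.zeros((self.n_pat, k))
            obs = patterns[row]
            ok = obs >= 0
            P[np.arange(self.n_pat)[ok], obs[ok]] = 1.0
            P[~ok, :] = 1.0
            self.tip_partial[i] = P

    # -- primitives --------------------------------------------------------

    def _trans(self, partial: np.ndarray, t: float) -> np.ndarray:
        """Propagate conditionals across a branch: partial @ P(t) (P symmetric)."""
        e = np.exp(-self.model.beta * max(t, 0.0))
        return e * partial + ((1.0 - e) / self.k) * partial.sum(axis=1, keepdims=True)

    def _down_pass(self, lengths: np.ndarray) -> list[np.ndarray]:
        down: list[np.ndarray] = [None] * len(self.nodes)
        for i, kids in enumerate(self.children):
            if not kids:
                down[i] = self.tip_partial[i]
                continue
            acc = self._trans(down[kids[0]], lengths[kids[0]])
            for c in kids[1:]:
                acc = acc * self._trans(down[c], lengths[c])
            down[i] = acc
        return down

    def _up_pass(self, lengths: np.ndarray, down: list[np.ndarray]) -> list[np.ndarray]:
        """up[i]: conditionals of everything outside i's subtree, seen at i's
        parent, including the stationary frequencies."""
        up: list[np.ndarray] = [None] * len(self.nodes)
        up[self.root] = np.broadcast_to(self.pi, (self.n_pat, self.k))
        for i in range(len(self.nodes) - 1, -1, -1):
            kids = self.children[i]
            if not kids:
                continue
            # outside partial evaluated at node i itself: propagate across
            # the edge above i (absent for the root)
            base = up[i] if i == self.root else self._trans(up[i], lengths[i])
            trans_kids = {c: self._trans(down[c], lengths[c]) for c in kids}
            for c in kids:
                acc = base
                for s in kids:
                    if s != c:
                        acc = acc * trans_kids[s]
                up[c] = acc
        return up

    def _lnl_from_root(self, down_root: np.ndarray) -> float:
        site = down_root @ self.pi
        if np.any(site <= 0):
            return -np.inf
        return float(self.counts @ np.log(site))

    def lnl(self, lengths: np.ndarray | None = None) -> float:
        lengths = self.lengths if lengths is None else lengths
        down = self._down_pass(lengths)
        return self._lnl_from_root(down[self.root])

    # -- free branch lengths ----------------------------------------------

    def _edge_objective(self, d: np.ndarray, u: np.ndarray):
        def neg(t):
            site = np.einsum("ij,ij->i", u, self._trans(d, t))
            if np.any(site <= 0):
                return np.inf
            return -float(self.counts @ np.log(site))

        return neg

    def _optimize_edge(self, d: np.ndarray, u: np.ndarray, t_init: float) -> tuple[float, float]:
        """Exact single-edge ML length given fixed inside/outside partials.

        With x = exp(-beta t) the per-pattern site likelihood is the affine
        function C + x (A - C), where A = sum_s u_s d_s and C = (sum u)(sum
        d)/k, so the edge log-likelihood is concave in x and the optimum is
        found by safeguarded Newton on its derivative.  Returns (t, lnL).
        """
        A = np.einsum("ij,ij->i", u, d)
        C = u.sum(axis=1) * d.sum(axis=1) / self.k
        D = A - C
        beta = self.model.beta
        c = self.counts

        def grad(x):
            return float(c @ (D / (C + x * D)))

        xlo = np.exp(-beta * _MAX_BL)
        xhi = np.exp(-beta * _MIN_BL)
        if grad(xhi) >= 0.0:
            x = xhi
        elif grad(xlo) <= 0.0:
            x = xlo
        else:
            lo, hi = xlo, xhi
            x = min(max(np.exp(-beta * max(t_init, _MIN_BL)), lo), hi)
            for _ in range(60):
                denom = C + x * D
                ratio = D / denom
                gx = float(c @ ratio)
                if gx > 0.0:
                    lo = x
                else:
                    hi = x
                if abs(gx) < 1e-9 or hi - lo < 1e-14:
                    break
                gpx = -float(c @ ratio**2)
                step = x - gx / gpx
                x = step if lo < step < hi else 0.5 * (lo + hi)
        t = float(-np.log(x) / beta)
        lnl = float(c @ np.log(C + x * D))
        return t, lnl

    def optimize_free(self, tol: float = 1e-6, max_sweeps: int = 60) -> float:
        """Monotone coordinate ascent over branch lengths.

        Each sweep is a depth-first Gauss–Seidel pass: every edge is solved
        exactly (see :meth:`_optimize_edge`) against inside/outside partials
        kept consistent with the current lengths, so the likelihood never
        decreases.  Stops when a sweep improves it by less than ``tol``.
        """
        lengths = np.maximum(self.lengths, _MIN_BL)
        lengths[self.root] = 0.0
        down = self._down_pass(lengths)
        best = self._lnl_from_root(down[self.root])
        converged = False
        for _ in range(max_sweeps):
            prev_lengths = lengths.copy()
            self._free_sweep(lengths, down)
            new = self._lnl_from_root(down[self.root])
            # accelerate the geometric tail of coordinate ascent by
            # extrapolating along the sweep displacement while it helps
            step = lengths - prev_lengths
            alpha = 1.0
            while alpha <= 32.0:
                trial = np.clip(lengths + alpha * step, _MIN_BL, _MAX_BL)
                trial[self.root] = 0.0
                trial_lnl = self.lnl(trial)
                if trial_lnl <= new:
                    break
                lengths[:] = trial
                new = trial_lnl
                alpha *= 2.0
            if alpha > 1.0:
                down = self._down_pass(lengths)
            if new - best < tol:
                best = max(best, new)
                converged = True
                break
            best = new
        if not converged:
            warnings.warn("branch-length optimization did not converge", stacklevel=2)
        self.lengths = lengths
        return best

    def _free_sweep(self, lengths: np.ndarray, down: list[np.ndarray]) -> None:
        """One DFS pass updating every edge and the down partials in place."""
        pi_arr = np.broadcast_to(self.pi, (self.n_pat, self.k))

        def visit(i: int, outside: np.ndarray | None) -> None:
            if outside is not None:
                lengths[i], _ = self._optimize_edge(down[i], outside, lengths[i])
            kids = self.children[i]
            if not kids:
                return
            base = pi_arr if outside is None else self._trans(outside, lengths[i])
            trans_kids = {c: self._trans(down[c], lengths[c]) for c in kids}
            for c in kids:
                o = base
                for s in kids:
                    if s != c:
                        o = o * trans_kids[s]
                visit(c, o)
                trans_kids[c] = self._trans(down[c], lengths[c])
            acc = trans_kids[kids[0]]
            for c in kids[1:]:
                acc = acc * trans_kids[c]
            down[i] = acc

        visit(self.root, None)

    def tree_with_lengths(self) -> RootedTree:
        out = self.tree.copy()
        for node, src in zip(out.postorder(), self.nodes):
            node.length = None if src.parent is None else float(
                self.lengths[self.index[id(src)]]
            )
        return RootedTree(out.root)


class _ClockEngine(_Engine):
    """Clock-constrained optimization over internal node heights.

    Tips sit at height 0; each internal node's height is bounded below by its
    highest child and above by its parent, so branch lengths h(parent) -
    h(child) are never negative.
    """

    def init_heights(self) -> np.ndarray:
        h = np.zeros(len(self.nodes))
        for i, kids in enumerate(self.children):
            if kids:
                h[i] = max(h[c] + max(self.lengths[c], _MIN_DT) for c in kids)
        return h

    def heights_to_lengths(self, h: np.ndarray) -> np.ndarray:
        lengths = np.zeros_like(h)
        for i in range(len(self.nodes)):
            p = self.parent[i]
            if p >= 0:
                lengths[i] = h[p] - h[i]
        return lengths

    def optimize_clock(
        self, tol: float = 1e-6, max_sweeps: int = 50
    ) -> tuple[np.ndarray, float]:
        """Monotone coordinate ascent over node heights (3 sweeps minimum).

        The root height is capped at 5x its initial value: on saturated
        data the ML root height diverges (deep branches are effectively
        unbounded once sequences approach stationarity), and an
        unregularized fit would report arbitrarily old relative ages.
        """
        h = self.init_heights()
        internal = [i for i, kids in enumerate(self.children) if kids]
        root_cap = max(5.0 * h[self.root], h[self.root] + 1.0)
        best = self.lnl(self.heights_to_lengths(h))
        converged = False
        for sweep in range(max_sweeps):
            prev = best
            prev_h = h.copy()
            for i in internal:
                lengths = self.heights_to_lengths(h)
                down = self._down_pass(lengths)
                up = self._up_pass(lengths, down)
                kids = self.children[i]
                kid_down = [down[c] for c in kids]
                kid_h = [h[c] for c in kids]
                lo = max(kid_h) + _MIN_DT
                p = self.parent[i]
                if p >= 0:
                    hi = h[p] - _MIN_DT
                    outside = up[i]
                else:
                    hi = max(root_cap, lo + _MIN_DT)
                    outside = np.broadcast_to(self.pi, (self.n_pat, self.k))
                if hi <= lo:
                    continue

                def neg(hv, kid_down=kid_down, kid_h=kid_h, p=p, outside=outside):
                    acc = self._trans(kid_down[0], hv - kid_h[0])
                    for d, hc in zip(kid_down[1:], kid_h[1:]):
                        acc = acc * self._trans(d, hv - hc)
                    if p >= 0:
                        acc = self._trans(acc, h[p] - hv)
                    site = np.einsum("ij,ij->i", outside, acc)
                    if np.any(site <= 0):
                        return np.inf
                    return -float(self.counts @ np.log(site))

                current = neg(h[i])
                res = minimize_scalar(
                    neg, bounds=(lo, hi), method="bounded", options={"xatol": 1e-7}
                )
                if res.fun < current:
                    h[i] = res.x
                    best = max(best, -res.fun)
            new = self.lnl(self.heights_to_lengths(h))
            # extrapolate along the sweep displacement (see optimize_free)
            step = h - prev_h
            alpha = 1.0
            while alpha <= 32.0 and np.any(step != 0):
                trial = h + alpha * step
                lengths = self.heights_to_lengths(trial)
                if (
                    np.any(lengths[:-1] < 0)
                    or trial[self.root] > root_cap
                    or np.any(trial[self.tip_idx] != 0)
                ):
                    break
                trial_lnl = self.lnl(lengths)
                if trial_lnl <= new:
                    break
                h[:] = trial
                new = trial_lnl
                alpha *= 2.0
            best = max(best, new)
            if best - prev < tol and sweep >= 2:  # at least 3 full sweeps
                converged = True
                break
        if not converged:
            warnings.warn("clock optimization did not converge", stacklevel=2)
        return h, best

    def ultrametric_tree(self, h: np.ndarray) -> RootedTree:
        lengths = self.heights_to_lengths(h)
        out = self.tree.copy()
        for node, i in zip(out.postorder(), range(len(self.nodes))):
            node.length = None if i == self.root else float(lengths[i])
        return RootedTree(out.root)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def log_likelihood(
    alignment: Alignment, tree: RootedTree, model: SubstitutionModel | None = None
) -> float:
    """Exact pruning-algorithm log-likelihood of the alignment on the tree."""
    model = model or model_for(alignment.alphabet)
    return _Engine(alignment, tree, model).lnl()


def optimize_free(
    alignment: Alignment,
    topology: RootedTree,
    model: SubstitutionModel | None = None,
    tol: float = 1e-6,
    max_sweeps: int = 60,
) -> tuple[RootedTree, float]:
    """ML branch lengths on a fixed topology (coordinate ascent per branch).

    Branch lengths on ``topology`` seed the optimization when present.
    Returns the tree with ML lengths and the maximized log-likelihood.
    """
    if topology.n_tips < 3:
        raise TreeError("free optimization needs at least 3 taxa")
    model = model or model_for(alignment.alphabet)
    eng = _Engine(alignment, topology, model)
    if not np.any(eng.lengths > 0):
        eng.lengths = np.full_like(eng.lengths, 0.1)
    lnl = eng.optimize_free(tol=tol, max_sweeps=max_sweeps)
    return eng.tree_with_lengths(), lnl


def optimize_clock(
    alignment: Alignment,
    topology: RootedTree,
    model: SubstitutionModel | None = None,
    tol: float = 1e-6,
    max_sweeps: int = 50,
) -> tuple[RootedTree, float]:
    """ML under a strict clock: node heights on the rooted topology.

    Returns an ultrametric tree (branch lengths in expected substitutions
    per site) and the maximized log-likelihood.
    """
    if topology.n_tips < 3:
        raise TreeError("clock optimization needs at least 3 taxa")
    model = model or model_for(alignment.alphabet)
    eng = _ClockEngine(alignment, topology, model)
    h, lnl = eng.optimize_clock(tol=tol, max_sweeps=max_sweeps)
    return eng.ultrametric_tree(h), lnl


def clock_lrt(
    alignment: Alignment,
    rooted_topology: RootedTree,
    model: SubstitutionModel | None = None,
    alpha: float = 0.05,
    tol: float = 1e-6,
) -> ClockTestResult:
    """Strict-clock likelihood-ratio test on a rooted topology.

    Compares the ML score with free branch lengths (2n-3 parameters) against
    the clock-constrained ML score (n-1 node heights); the doubled difference
    is referred to a chi-square distribution with n-2 degrees of freedom.
    Outgroups should already have been pruned.
    """
    model = model or model_for(alignment.alphabet)
    n = rooted_topology.n_tips
    _, lnl_free = optimize_free(alignment, rooted_topology, model, tol=tol)
    _, lnl_clock = optimize_clock(alignment, rooted_topology, model, tol=tol)
    stat = 2.0 * (lnl_free - lnl_clock)
    if stat < 0:
        if stat < -0.1:
            warnings.warn(
                f"clock lnL exceeded free lnL by {-stat / 2:.4f}; statistic clamped to 0",
                stacklevel=2,
            )
        stat = 0.0
    df = n - 2
    p = float(chi2.sf(stat, df))
    return ClockTestResult(
        lnL_free=lnl_free,
        lnL_clock=lnl_clock,
        statistic=stat,
        df=df,
        p_value=p,
        alpha=alpha,
        rejected=p < alpha,
    )
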