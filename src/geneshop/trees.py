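"""Rooted trees, Newick I/O and the per-tree clock statistics.

The central object is :class:`RootedTree`, a lightweight mutable tree of
:class:`Node` objects.  Branch lengths are expected substitutions per site on
phylograms, or time units on chronograms; a missing length is stored as
``None`` and treated as 0 in path arithmetic.

Statistics relevant to gene shopping live in :func:`tree_stats`:

* ``tree_length`` — the sum of all branch lengths, a proxy for the amount of
  discernible molecular evolution (information content) in a gene;
* ``rtt_variance`` — the variance of root-to-tip path lengths, a proxy for
  clock-likeness: a perfectly clock-like phylogram is ultrametric and has
  zero root-to-tip variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator


class NewickError(ValueError):
    """Malformed Newick input; carries the character offset of the problem."""

    def __init__(self, message: str, offset: int | None = None):
        if offset is not None:
            message = f"{message} (at character {offset})"
        super().__init__(message)
        self.offset = offset


class TreeError(ValueError):
    """Invalid tree operation (bad outgroup, pruning to nothing, ...)."""


class Node:
    """A node of a rooted tree."""

    __slots__ = ("label", "length", "children", "parent")

    def __init__(self, label: str | None = None, length: float | None = None):
        self.label = label
        self.length = length
        self.children: list[Node] = []
        self.parent: Node | None = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_tip(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "tip" if self.is_tip else f"internal({len(self.children)})"
        return f"<Node {self.label!r} {kind} length={self.length}>"


class RootedTree:
    """A rooted phylogenetic tree with branch lengths.

    Invariants: exactly one root, unique non-empty tip labels, branch
    lengths non-negative when present.
    """

    def __init__(self, root: Node):
        self.root = root
        self._validate()

    # -- construction / validation -------------------------------------------------

    def _validate(self) -> None:
        seen: set[str] = set()
        for node in self.postorder():
            if node.is_tip:
                if not node.label:
                    raise TreeError("tip with empty label")
                if node.label in seen:
                    raise TreeError(f"duplicate tip label {node.label!r}")
                seen.add(node.label)
            if node.length is not None and node.length < 0:
                raise TreeError(
                    f"negative branch length {node.length} at {node.label!r}"
                )

    # -- traversal -----------------------------------------------------------------

    def postorder(self) -> Iterator[Node]:
        stack = [(self.root, False)]
        while stack:
            node, visited = stack.pop()
            if visited:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            for child in reversed(node.children):
                stack.append(child)

    def tips(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_tip]

    def tip_labels(self) -> list[str]:
        return [n.label for n in self.tips()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tips())

    def copy(self) -> "RootedTree":
        def clone(node: Node) -> Node:
            new = Node(node.label, node.length)
            for child in node.children:
                new.add_child(clone(child))
            return new

        return RootedTree(clone(self.root))

    # -- path arithmetic -----------------------------------------------------------

    def root_to_tip(self) -> dict[str, float]:
        """Path length from the root to every tip."""
        depth: dict[int, float] = {id(self.root): 0.0}
        out: dict[str, float] = {}
        for node in self.preorder():
            if node is not self.root:
                depth[id(node)] = depth[id(node.parent)] + (node.length or 0.0)
            if node.is_tip:
                out[node.label] = depth[id(node)]
        return out

    def tree_length(self) -> float:
        return sum(n.length or 0.0 for n in self.postorder() if n is not self.root)

    def height(self) -> float:
        paths = self.root_to_tip()
        return max(paths.values()) if paths else 0.0

    def is_ultrametric(self, rel_tol: float = 1e-9) -> bool:
        paths = list(self.root_to_tip().values())
        hi, lo = max(paths), min(paths)
        return (hi - lo) <= rel_tol * max(hi, 1e-300)

    # -- Newick --------------------------------------------------------------------

    def newick(self) -> str:
        return write_newick(self)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<RootedTree {self.n_tips} tips>"


@dataclass(frozen=True)
class TreeStats:
    """Per-tree clock statistics consumed by the winnowing procedure."""

    tree_length: float
    root_to_tip: dict[str, float] = field(repr=False)
    rtt_variance: float = 0.0
    rtt_deviations: dict[str, float] = field(default_factory=dict, repr=False)


def tree_stats(tree: RootedTree) -> TreeStats:
    """Tree length, root-to-tip paths, their variance and per-tip deviations.

    The variance is the sample variance (n-1 denominator) of the root-to-tip
    path lengths; it is 0 exactly when the tree is ultrametric.  Deviations
    are ``path - mean(path)`` per tip and sum to 0.
    """
    paths = tree.root_to_tip()
    if len(paths) < 2:
        raise TreeError("tree statistics need at least 2 tips")
    values = list(paths.values())
    mean = sum(values) / len(values)
    var = sum((v - mean) ** 2 for v in values) / (len(values) - 1)
    dev = {t: v - mean for t, v in paths.items()}
    return TreeStats(
        tree_length=tree.tree_length(),
        root_to_tip=paths,
        rtt_variance=var,
        rtt_deviations=dev,
    )


# -- Newick parsing ---------------------------------------------------------------


def _format_length(x: float) -> str:
    # repr gives the shortest decimal string that round-trips the float
    return repr(float(x))


def write_newick(tree: RootedTree) -> str:
    def fmt(node: Node) -> str:
        if node.is_tip:
            s = _quote_if_needed(node.label)
        else:
            s = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.label:
                s += _quote_if_needed(node.label)
        if node.length is not None and node is not tree.root:
            s += ":" + _format_length(node.length)
        return s

    return fmt(tree.root) + ";"


_UNQUOTED_FORBIDDEN = set("()[]{}:;,='\" \t\n")


def _quote_if_needed(label: str) -> str:
    if label and not (_UNQUOTED_FORBIDDEN & set(label)):
        return label
    return "'" + label.replace("'", "''") + "'"


class _NewickScanner:
    """Recursive-descent Newick reader.

    Supports branch lengths, internal labels (commonly support values),
    single-quoted labels with doubled-quote escapes, and square-bracket
    comments (skipped).  Reports the character offset of any syntax error.
    """

    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def error(self, msg: str) -> NewickError:
        return NewickError(msg, self.pos)

    def skip_space(self) -> None:
        text, n = self.text, len(self.text)
        while self.pos < n:
            c = text[self.pos]
            if c in " \t\r\n":
                self.pos += 1
            elif c == "[":
                end = text.find("]", self.pos)
                if end < 0:
                    raise self.error("unterminated comment")
                self.pos = end + 1
            else:
                return

    def peek(self) -> str:
        self.skip_space()
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def parse(self) -> Node:
        node = self.parse_clade()
        if self.peek() != ";":
            raise self.error("expected ';' at end of tree")
        self.pos += 1
        self.skip_space()
        if self.pos != len(self.text):
            raise self.error("trailing characters after ';'")
        return node

    def parse_clade(self) -> Node:
        node = Node()
        if self.peek() == "(":
            self.pos += 1
            node.add_child(self.parse_clade())
            while self.peek() == ",":
                self.pos += 1
                node.add_child(self.parse_clade())
            if self.peek() != ")":
                raise self.error("expected ')' or ','")
            self.pos += 1
            node.label = self.parse_label(required=False)
        else:
            label = self.parse_label(required=True)
            node.label = label
        if self.peek() == ":":
            self.pos += 1
            node.length = self.parse_number()
        return node

    def parse_label(self, required: bool) -> str | None:
        c = self.peek()
        if c == "'":
            return self.parse_quoted()
        start = self.pos
        text, n = self.text, len(self.text)
        while self.pos < n and text[self.pos] not in "()[]:;,":
            self.pos += 1
        label = text[start : self.pos].strip()
        if not label:
            if required:
                raise self.error("expected a taxon label")
            return None
        return label

    def parse_quoted(self) -> str:
        assert self.text[self.pos] == "'"
        self.pos += 1
        out = []
        text, n = self.text, len(self.text)
        while self.pos < n:
            c = text[self.pos]
            if c == "'":
                if self.pos + 1 < n and text[self.pos + 1] == "'":
                    out.append("'")
                    self.pos += 2
                else:
                    self.pos += 1
                    return "".join(out)
            else:
                out.append(c)
                self.pos += 1
        raise self.error("unterminated quoted label")

    def parse_number(self) -> float:
        self.skip_space()
        start = self.pos
        text, n = self.text, len(self.text)
        while self.pos < n and (text[self.pos] in "+-.eE" or text[self.pos].isdigit()):
            self.pos += 1
        token = text[start : self.pos]
        try:
            return float(token)
        except ValueError:
            self.pos = start
            raise self.error(f"invalid branch length {token!r}") from None


def parse_newick(text: str) -> RootedTree:
    """Parse a Newick string into a :class:`RootedTree`.

    Raises :class:`NewickError` (with a character offset) on malformed
    input and :class:`TreeError` on duplicate or empty tip labels.
    """
    root = _NewickScanner(text).parse()
    if root.is_tip:
        raise NewickError("tree must have at least one internal node", 0)
    return RootedTree(root)


def read_newick_file(path) -> list[RootedTree]:
    """Read one tree per non-blank line from a Newick file."""
    trees = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                trees.append(parse_newick(line))
    return trees


# -- rooting ---------------------------------------------------------------------


def root_by_outgroup(tree: RootedTree, outgroup: Iterable[str]) -> RootedTree:
    """Re-root a tree on the edge separating the outgroup from the ingroup.

    The outgroup must form one side of a single edge of the *unrooted*
    topology.  The root is placed at the midpoint of that edge, so the total
    tree length is conserved.
    """
    outgroup = set(outgroup)
    tips = set(tree.tip_labels())
    missing = outgroup - tips
    if missing:
        raise TreeError(f"outgroup taxa not in tree: {sorted(missing)}")
    if not outgroup or outgroup == tips:
        raise TreeError("outgroup must be a proper nonempty subset of the tips")

    work = tree.copy()
    # Collapse a bifurcating root so the search is over the unrooted topology:
    # the two root edges are a single unrooted edge.
    root = work.root
    if len(root.children) == 2:
        a, b = root.children
        keep, fold = (a, b) if not a.is_tip else (b, a)
        if keep.is_tip:  # two-tip tree: no internal edge to root on
            raise TreeError("tree too small to re-root")
        root.children = list(keep.children)
        for c in root.children:
            c.parent = root
        root.label = keep.label
        fold.length = (fold.length or 0.0) + (keep.length or 0.0)
        root.add_child(fold)

    # Find the node whose descendant tip set is the outgroup (or its complement).
    below: dict[int, set[str]] = {}
    target: Node | None = None
    for node in work.postorder():
        s = {node.label} if node.is_tip else set().union(*(below[id(c)] for c in node.children))
        below[id(node)] = s
        if node is work.root:
            continue
        if s == outgroup or (tips - s) == outgroup:
            target = node
            break
    if target is None:
        raise TreeError(
            f"outgroup {sorted(outgroup)} is not separable by a single edge"
        )

    # Place the new root at the midpoint of the edge above `target`.
    half = (target.length or 0.0) / 2.0
    old_parent = target.parent
    old_parent.children.remove(target)
    new_root = Node()
    target.parent = None
    target.length = half
    new_root.add_child(target)

    # Reverse the parent chain from old_parent up to the old root.
    prev = new_root
    carry = half
    node = old_parent
    while node is not None:
        nxt = node.parent
        if nxt is not None:
            nxt.children.remove(node)
        node.parent = None
        next_carry = node.length
        node.length = carry
        prev.add_child(node)
        prev = node
        carry = next_carry
        node = nxt

    # The old root now dangles with its remaining children; if it is left
    # with a single child it is a degree-2 node and gets suppressed.
    def suppress_unifurcations(n: Node) -> None:
        for child in list(n.children):
            suppress_unifurcations(child)
        if len(n.children) == 1 and n.parent is not None:
            child = n.children[0]
            child.length = (child.length or 0.0) + (n.length or 0.0)
            idx = n.parent.children.index(n)
            child.parent = n.parent
            n.parent.children[idx] = child

    suppress_unifurcations(new_root.children[-1])
    return RootedTree(new_root)


# -- pruning ---------------------------------------------------------------------


def prune_taxa(tree: RootedTree, drop: Iterable[str]) -> RootedTree:
    """Remove tips and suppress the resulting degree-2 nodes.

    Branch lengths of suppressed nodes are summed, so every surviving tip
    keeps its original root-to-tip path length; if the root is left with a
    single child, the stem edge is kept (the root stays where it was).
    """
    drop = set(drop)
    tips = set(tree.tip_labels())
    missing = drop - tips
    if missing:
        raise TreeError(f"taxa not in tree: {sorted(missing)}")
    if len(tips - drop) < 3:
        raise TreeError("pruning would leave fewer than 3 tips")

    work = tree.copy()

    def prune(node: Node) -> Node | None:
        if node.is_tip:
            return None if node.label in drop else node
        kept = []
        for child in node.children:
            res = prune(child)
            if res is not None:
                kept.append(res)
        if not kept:
            return None
        if len(kept) == 1 and node.parent is not None:
            child = kept[0]
            child.length = (child.length or 0.0) + (node.length or 0.0)
            child.parent = node.parent
            return child
        node.children = kept
        for c in kept:
            c.parent = node
        return node

    new_root = prune(work.root)
    assert new_root is not None
    new_root.parent = None
    return RootedTree(new_root)


def drop_root_stem(tree: RootedTree) -> RootedTree:
    """Collapse a degree-1 root into its child, discarding the stem edge.

    After outgroup pruning the root may retain a stem whose length depends
    on where the root was placed along the rooting edge; statistics that
    should not see that arbitrary choice (tree length) use this first.
    Root-to-tip variance is unaffected either way (the stem shifts every
    path by the same constant).
    """
    work = tree.copy()
    while len(work.root.children) == 1:
        child = work.root.children[0]
        child.parent = None
        child.length = None
        work = RootedTree(child)
    return work
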