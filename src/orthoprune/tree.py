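"""Rooted-storage phylogenetic trees with newick I/O.

Every tree is stored rooted (a single root node), with an explicit
``rooted`` flag: a newick whose outermost grouping has exactly two
children is treated as genuinely rooted, one with three or more as an
unrooted tree written in rooted form.  Branch lengths are optional;
a missing length is ``None`` and is never silently conflated with 0 —
cutoff comparisons that need a number use :func:`edge_length`, which
warns once per call site and substitutes 0.
"""

from __future__ import annotations

import logging
from typing import Callable, Iterator, Optional

logger = logging.getLogger(__name__)

__all__ = [
    "Node",
    "Tree",
    "NewickError",
    "TreeError",
    "read_newick",
    "write_newick",
    "edge_length",
]


class NewickError(ValueError):
    """Malformed newick text; carries the character offset of the fault."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at character {offset})")
        self.offset = offset


class TreeError(ValueError):
    """A tree violated a structural contract (e.g. duplicate tip labels)."""


class Node:
    """One node of a tree.

    ``length`` is the length of the edge *above* this node (to its
    parent); ``None`` means the newick carried no length for that edge.
    """

    __slots__ = ("label", "length", "children", "parent")

    def __init__(self, label: str = "", length: Optional[float] = None):
        self.label = label
        self.length = length
        self.children: list[Node] = []
        self.parent: Optional[Node] = None

    @property
    def is_tip(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def remove_child(self, child: "Node") -> "Node":
        self.children.remove(child)
        child.parent = None
        return child

    def iter_preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def iter_postorder(self) -> Iterator["Node"]:
        out = list(self.iter_preorder())
        return iter(reversed(out))

    def iter_tips(self) -> Iterator["Node"]:
        for node in self.iter_preorder():
            if node.is_tip:
                yield node

    def tip_labels(self) -> list[str]:
        return [t.label for t in self.iter_tips()]

    def copy(self) -> "Node":
        """Deep copy of the subtree rooted at this node."""
        new = Node(self.label, self.length)
        for child in self.children:
            new.add_child(child.copy())
        return new

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Node {self.label or '(internal)'} len={self.length}>"


class Tree:
    """A phylogeny: a root :class:`Node` plus a rooted-flag."""

    def __init__(self, root: Node, rooted: Optional[bool] = None):
        self.root = root
        if rooted is None:
            rooted = len(root.children) == 2
        self.rooted = rooted

    # -- basic queries ------------------------------------------------

    def iter_tips(self) -> Iterator[Node]:
        return self.root.iter_tips()

    def tip_labels(self) -> list[str]:
        return self.root.tip_labels()

    def num_tips(self) -> int:
        return sum(1 for _ in self.iter_tips())

    def taxa(self, taxon_of: Callable[[str], str]) -> set[str]:
        return {taxon_of(t) for t in self.tip_labels()}

    def copy(self) -> "Tree":
        return Tree(self.root.copy(), rooted=self.rooted)

    def validate(self) -> None:
        labels = self.tip_labels()
        dupes = {x for x in labels if labels.count(x) > 1}
        if dupes:
            raise TreeError(f"duplicate tip labels: {sorted(dupes)}")
        for node in self.root.iter_preorder():
            if node.length is not None and node.length < 0:
                raise TreeError(
                    f"negative branch length {node.length} above "
                    f"{node.label or 'internal node'}"
                )

    # -- surgery ------------------------------------------------------

    def prune_tip(self, tip: Node) -> None:
        """Remove one tip, suppressing any unifurcation it leaves.

        The merged edge gets the sum of the two collapsed lengths
        (missing + missing stays missing; missing + x gives x).
        """
        parent = tip.parent
        if parent is None:
            raise TreeError("cannot prune the root")
        parent.remove_child(tip)
        self._suppress_if_unifurcation(parent)

    def _suppress_if_unifurcation(self, node: Node) -> None:
        if len(node.children) != 1:
            return
        only = node.children[0]
        if node.parent is None:
            # Root with a single child: the child becomes the new root.
            node.remove_child(only)
            only.length = None
            self.root = only
            return
        grand = node.parent
        idx = grand.children.index(node)
        grand.children[idx] = only
        only.parent = grand
        only.length = _add_lengths(only.length, node.length)
        node.parent = None
        node.children = []

    def prune_tips_by_label(self, labels: set[str]) -> None:
        for tip in [t for t in self.iter_tips() if t.label in labels]:
            self.prune_tip(tip)

    def keep_tips_by_label(self, labels: set[str]) -> None:
        drop = {t.label for t in self.iter_tips()} - set(labels)
        self.prune_tips_by_label(drop)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Tree {self.num_tips()} tips rooted={self.rooted}>"


def _add_lengths(a: Optional[float], b: Optional[float]) -> Optional[float]:
    if a is None:
        return b
    if b is None:
        return a
    return a + b


def edge_length(node: Node, warn_context: str = "") -> float:
    """Branch length above ``node``; missing lengths count as 0 with a warning."""
    if node.length is None:
        logger.warning(
            "missing branch length treated as 0%s",
            f" ({warn_context})" if warn_context else "",
        )
        return 0.0
    return node.length


# ---------------------------------------------------------------------------
# Newick parsing / writing
# ---------------------------------------------------------------------------

_LABEL_STOP = set("(),:;")


def read_newick(text: str) -> Tree:
    """Parse one newick tree from ``text``.

    Accepts optional branch lengths and internal-node labels.  A root
    with exactly two children is flagged rooted, three or more unrooted.
    Raises :class:`NewickError` with the offending character offset on
    malformed input, :class:`TreeError` on duplicate tip labels.
    """
    s = text.strip()
    if not s:
        raise NewickError("empty newick string", 0)
    pos = 0
    n = len(s)

    def skip_ws(p: int) -> int:
        while p < n and s[p].isspace():
            p += 1
        return p

    def parse_label(p: int) -> tuple[str, int]:
        start = p
        if p < n and s[p] in "'\"":
            quote = s[p]
            p += 1
            begin = p
            while p < n and s[p] != quote:
                p += 1
            if p >= n:
                raise NewickError("unterminated quoted label", start)
            return s[begin:p], p + 1
        while p < n and s[p] not in _LABEL_STOP and not s[p].isspace():
            p += 1
        return s[start:p], p

    def parse_length(p: int) -> tuple[Optional[float], int]:
        p = skip_ws(p)
        if p < n and s[p] == ":":
            p = skip_ws(p + 1)
            start = p
            while p < n and (s[p] not in _LABEL_STOP or s[p] == ":") and not s[p].isspace():
                if s[p] == ":":
                    raise NewickError("unexpected ':' in branch length", p)
                p += 1
            try:
                return float(s[start:p]), p
            except ValueError:
                raise NewickError(f"bad branch length {s[start:p]!r}", start) from None
        return None, p

    def parse_clade(p: int) -> tuple[Node, int]:
        p = skip_ws(p)
        node = Node()
        if p < n and s[p] == "(":
            open_at = p
            p = skip_ws(p + 1)
            while True:
                child, p = parse_clade(p)
                node.add_child(child)
                p = skip_ws(p)
                if p < n and s[p] == ",":
                    p += 1
                    continue
                if p < n and s[p] == ")":
                    p += 1
                    break
                raise NewickError(
                    "unbalanced parenthesis", open_at if p >= n else p
                )
            label, p = parse_label(p)
            node.label = label
        else:
            label, p = parse_label(p)
            if not label:
                raise NewickError("expected a tip label", p)
            node.label = label
        node.length, p = parse_length(p)
        return node, p

    root, pos = parse_clade(pos)
    pos = skip_ws(pos)
    if pos >= n or s[pos] != ";":
        raise NewickError("missing terminating ';'", pos)
    tree = Tree(root)
    tree.validate()
    return tree


def _format_length(x: float) -> str:
    out = f"{x:.10g}"
    return out


def _needs_quoting(label: str) -> bool:
    return any(c in _LABEL_STOP or c.isspace() for c in label)


def write_newick(tree: Tree, *, lengths: bool = True) -> str:
    """Serialize a tree; round-trips :func:`read_newick` output."""

    def fmt(node: Node) -> str:
        if node.is_tip:
            core = f"'{node.label}'" if _needs_quoting(node.label) else node.label
        else:
            inner = ",".join(fmt(c) for c in node.children)
            label = node.label
            if label and _needs_quoting(label):
                label = f"'{label}'"
            core = f"({inner}){label}"
        if lengths and node.length is not None:
            core += f":{_format_length(node.length)}"
        return core

    return fmt(tree.root) + ";"
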