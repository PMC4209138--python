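"""Cleaning homolog trees before orthology inference.

Three tree-surgery stages remove the artifacts that de novo
transcriptomes leave in gene trees:

* very long *internal* branches separate deep paralogs (or distinct
  gene families glued together by clustering) — they are cut and each
  resulting piece kept as its own homolog;
* very long *terminal* branches are usually misassembled or
  frameshifted sequences — a tip is discarded when its branch is both
  much longer than the typical depth of its sister clade and longer
  than an absolute cutoff;
* monophyletic clades and paraphyletic grades of tips from one taxon
  are isoforms of one gene — they are masked down to the single
  sequence with the most unambiguous aligned characters.

All cutoffs live in :class:`RefinementConfig`; the published
per-dataset values are available as presets in :mod:`orthoprune.config`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

from .seqio import DEFAULT_SCHEME, Alignment, TaxonNameScheme
from .tree import Node, Tree, edge_length

logger = logging.getLogger(__name__)

__all__ = [
    "RefinementConfig",
    "cut_long_internal_branches",
    "trim_spurious_tips",
    "mask_redundant_tips",
    "refine_homolog",
]


@dataclass(frozen=True)
class RefinementConfig:
    """Branch-length cutoffs (substitutions/site) and size limits.

    ``internal_branch_cutoff``: internal edges longer than this are cut
    (published values 1.5 / 1.0 / 0.3 for progressively younger
    datasets).  ``tip_absolute_cutoff`` and ``tip_relative_factor``:
    a tip is removed when its branch exceeds the absolute cutoff *and*
    ``factor`` times the mean distance to the tips of its sister clade
    (published absolute values 0.75 / 0.6 / 0.1; factor 10).
    """

    internal_branch_cutoff: float = 1.0
    tip_absolute_cutoff: float = 0.6
    tip_relative_factor: float = 10.0
    min_subtree_taxa: int = 8
    mask_paraphyletic: bool = True

    def __post_init__(self) -> None:
        if self.internal_branch_cutoff <= 0 or self.tip_absolute_cutoff <= 0:
            raise ValueError("branch-length cutoffs must be positive")
        if self.tip_relative_factor < 1:
            raise ValueError("tip_relative_factor must be >= 1")


def _suppress_all_unifurcations(tree: Tree) -> None:
    # drop internal nodes whose children were all cut away (no label => not a tip)
    changed = True
    while changed:
        changed = False
        for node in list(tree.root.iter_postorder()):
            if not node.children and not node.label and node.parent is not None:
                node.parent.remove_child(node)
                changed = True
    for node in list(tree.root.iter_postorder()):
        if node.children and len(node.children) == 1:
            tree._suppress_if_unifurcation(node)
    # the root itself may have been left unary by surgery above it
    while len(tree.root.children) == 1:
        tree._suppress_if_unifurcation(tree.root)


def cut_long_internal_branches(
    tree: Tree,
    cfg: RefinementConfig,
    scheme: TaxonNameScheme = DEFAULT_SCHEME,
    log: Optional[list[str]] = None,
) -> list[Tree]:
    """Cut every internal edge longer than the cutoff; keep big pieces.

    Each connected component left after cutting becomes its own tree;
    components with fewer than ``min_subtree_taxa`` distinct taxa are
    discarded.  The input is not modified.
    """
    work = tree.copy()
    to_cut = [
        node
        for node in work.root.iter_preorder()
        if node.parent is not None
        and node.children
        and edge_length(node, "internal branch cut") > cfg.internal_branch_cutoff
    ]
    roots = [work.root]
    for node in to_cut:
        if log is not None:
            log.append(
                f"cut\tinternal edge length {node.length:.6g} > "
                f"{cfg.internal_branch_cutoff:.6g}"
            )
        node.parent.remove_child(node)
        node.length = None
        roots.append(node)

    out: list[Tree] = []
    for root in roots:
        piece = Tree(root, rooted=tree.rooted if root is work.root else False)
        _suppress_all_unifurcations(piece)
        if piece.root.is_tip:  # emptied or reduced to a single tip
            continue
        if len(piece.taxa(scheme.taxon_of)) >= cfg.min_subtree_taxa:
            out.append(piece)
        elif log is not None:
            log.append(
                f"drop\tsubtree with {len(piece.taxa(scheme.taxon_of))} taxa "
                f"< {cfg.min_subtree_taxa}"
            )
    return out


def _sister_tip_distances(tip: Node) -> list[float]:
    """Distances from the tip's attachment node to each sister-clade tip.

    Each distance runs through the sibling edge into the sibling
    subtree (the inclusive convention); at a polytomy or the root of an
    unrooted tree all co-children are pooled.
    """
    parent = tip.parent
    dists: list[float] = []
    for sib in parent.children:
        if sib is tip:
            continue
        base = edge_length(sib, "sister distance")
        stack = [(sib, 0.0)]
        while stack:
            node, acc = stack.pop()
            if node.is_tip:
                dists.append(base + acc)
            else:
                for child in node.children:
                    stack.append((child, acc + edge_length(child, "sister distance")))
    return dists


def trim_spurious_tips(
    tree: Tree,
    cfg: RefinementConfig,
    log: Optional[list[str]] = None,
) -> Tree:
    """Remove aberrantly long terminal branches, iterating to a fixpoint.

    A tip goes when its pendant branch is longer than
    ``tip_relative_factor`` times the mean distance to the tips of its
    sister clade *and* longer than ``tip_absolute_cutoff``.  The worst
    offender is removed first and sister statistics recomputed, until
    no tip qualifies.  The input is not modified.
    """
    work = tree.copy()
    while work.num_tips() >= 3:
        worst: Optional[Node] = None
        worst_key: tuple[float, str] = (-1.0, "")
        for tip in work.iter_tips():
            pendant = edge_length(tip, "tip trim")
            if pendant <= cfg.tip_absolute_cutoff:
                continue
            dists = _sister_tip_distances(tip)
            if not dists:
                continue
            mean = sum(dists) / len(dists)
            if pendant > cfg.tip_relative_factor * mean:
                key = (pendant, tip.label)
                if key > worst_key:
                    worst, worst_key = tip, key
        if worst is None:
            break
        if log is not None:
            log.append(
                f"trim\t{worst.label}\tpendant {worst_key[0]:.6g} > "
                f"{cfg.tip_relative_factor:g}x sister mean and > "
                f"{cfg.tip_absolute_cutoff:.6g}"
            )
        work.prune_tip(worst)
    if work.num_tips() < 3:
        logger.warning("tree reduced below 3 tips during spurious-tip trimming")
    return work


def _collapse_group(
    tree: Tree,
    group: list[Node],
    char_counts: dict[str, int],
    log: Optional[list[str]],
) -> None:
    """Keep the member with the most unambiguous characters, prune the rest.

    Ties break toward the lexicographically smallest identifier.
    """
    best = max(group, key=lambda n: (char_counts[n.label], _neg_lex(n.label)))
    for node in group:
        if node is best:
            continue
        if log is not None:
            log.append(
                f"mask\t{node.label}\trepresentative {best.label} "
                f"({char_counts[best.label]} vs {char_counts[node.label]} chars)"
            )
        tree.prune_tip(node)


class _neg_lex(str):
    """Inverts lexicographic order so max() prefers the smaller string."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def mask_redundant_tips(
    tree: Tree,
    char_counts: dict[str, int],
    cfg: RefinementConfig,
    scheme: TaxonNameScheme = DEFAULT_SCHEME,
    log: Optional[list[str]] = None,
) -> Tree:
    """Mask same-taxon isoform tips, keeping the best-covered sequence.

    Monophyletic same-taxon groups: when every tip in a tip's sister
    subtree belongs to its own taxon, the whole group collapses to the
    member with the highest unambiguous-character count.  With
    ``mask_paraphyletic`` on, grades are also masked: a tip whose
    parent's sister is a same-taxon tip is merged with it.  Repeats to
    a fixpoint.  The input is not modified.
    """
    for tip_label in tree.tip_labels():
        if tip_label not in char_counts:
            raise KeyError(f"tip {tip_label!r} missing from character counts")

    work = tree.copy()
    changed = True
    while changed and work.num_tips() >= 2:
        changed = False
        # monophyletic rule
        for tip in list(work.iter_tips()):
            if tip.parent is None:
                continue
            taxon = scheme.taxon_of(tip.label)
            sister_tips: list[Node] = []
            for sib in tip.parent.children:
                if sib is tip:
                    continue
                sister_tips.extend(sib.iter_tips())
            if sister_tips and all(
                scheme.taxon_of(s.label) == taxon for s in sister_tips
            ):
                _collapse_group(work, [tip] + sister_tips, char_counts, log)
                changed = True
                break
        if changed:
            continue
        # paraphyletic rule: same-taxon tip one rank up the grade
        if cfg.mask_paraphyletic:
            for tip in list(work.iter_tips()):
                parent = tip.parent
                if parent is None or parent.parent is None:
                    continue
                taxon = scheme.taxon_of(tip.label)
                for uncle in parent.parent.children:
                    if uncle is parent:
                        continue
                    if uncle.is_tip and scheme.taxon_of(uncle.label) == taxon:
                        _collapse_group(work, [tip, uncle], char_counts, log)
                        changed = True
                        break
                if changed:
                    break
    return work


def refine_homolog(
    tree: Tree,
    alignment: Optional[Alignment],
    cfg: RefinementConfig,
    scheme: TaxonNameScheme = DEFAULT_SCHEME,
    char_counts: Optional[dict[str, int]] = None,
    log: Optional[list[str]] = None,
) -> list[Tree]:
    """Full cleaning pipeline: trim tips, mask isoforms, cut deep paralogs.

    ``char_counts`` may be given directly instead of an alignment.
    Returns the cleaned homolog trees (possibly none) with at least
    ``min_subtree_taxa`` distinct taxa each.
    """
    if char_counts is None:
        if alignment is None:
            raise ValueError("need an alignment or explicit character counts")
        char_counts = alignment.unambiguous_counts()
    t = trim_spurious_tips(tree, cfg, log=log)
    t = mask_redundant_tips(t, char_counts, cfg, scheme=scheme, log=log)
    return cut_long_internal_branches(t, cfg, scheme=scheme, log=log)
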