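"""Ortholog extraction from cleaned homolog trees.

Four strategies, each trading off differently between ortholog yield,
taxon occupancy and tolerance of gene/genome duplication:

* **MI** (maximum inclusion): iteratively cut out the edge-delimited
  subtree with the most taxa and no taxon duplication; works without
  outgroups and salvages orthologs from heavily duplicated families.
* **RT** (rooted tree): use designated outgroup taxa to extract rooted
  ingroup clades, then walk root-to-tip pruning the smaller side at
  every node where the two sides share a taxon; pruned sides re-enter
  the pool, so one homolog can yield several orthologs (outgroups are
  spent on rooting and absent from the results).
* **MO** (monophyletic outgroup): only homologs whose outgroup tips are
  monophyletic and non-repeating are used; the tree is rooted on the
  outgroup clade and duplications pruned as in RT, but pruned sides are
  discarded, giving at most one ortholog that retains the outgroups.
* **1to1**: keep only homologs that already contain no taxon
  duplication.

Every emitted ortholog is checked to contain at most one tip per
taxon.  All tie-breaks are deterministic: more distinct taxa, then
more tips, then more total unambiguous characters, then the
lexicographically smallest sorted tip-label tuple.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .homolog_refine import RefinementConfig, trim_spurious_tips
from .seqio import DEFAULT_SCHEME, TaxonNameScheme
from .tree import Node, Tree, TreeError

logger = logging.getLogger(__name__)

__all__ = [
    "TaxonRoles",
    "OrthologTree",
    "PruneConfig",
    "has_taxon_duplication",
    "prune_mi",
    "extract_rooted_ingroup_clades",
    "prune_paralogs_rt",
    "prune_paralogs_mo",
    "filter_1to1",
    "run_method",
    "occupancy_table",
]

METHODS = ("MI", "RT", "MO", "1to1")


@dataclass(frozen=True)
class TaxonRoles:
    """Ingroup taxa under study, outgroup taxa used only for rooting."""

    ingroup: frozenset[str]
    outgroup: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        overlap = self.ingroup & self.outgroup
        if overlap:
            raise ValueError(f"taxa in both ingroup and outgroup: {sorted(overlap)}")


@dataclass
class OrthologTree:
    """A pruned tree with at most one tip per taxon."""

    tree: Tree
    source_id: str
    method: str
    scheme: TaxonNameScheme = field(default=DEFAULT_SCHEME)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method tag {self.method!r}")
        if has_taxon_duplication(self.tree, self.scheme):
            raise TreeError(
                f"ortholog from {self.source_id} contains a repeated taxon"
            )

    @property
    def taxa(self) -> set[str]:
        return self.tree.taxa(self.scheme.taxon_of)

    @property
    def tips(self) -> set[str]:
        return set(self.tree.tip_labels())


@dataclass(frozen=True)
class PruneConfig:
    """Knobs shared by the pruning strategies.

    ``mi_tip_trim`` holds the (stricter) tip cutoffs applied to the MI
    remainder after each extraction; ``rt_reprocess_pruned`` selects
    whether RT sends pruned sides back through the pruner (on) or
    discards them (off, MO-style).
    """

    min_taxa: int = 8
    min_ingroup_taxa: Optional[int] = None
    mi_tip_trim: Optional[RefinementConfig] = None
    rt_reprocess_pruned: bool = True

    @property
    def ingroup_minimum(self) -> int:
        return self.min_ingroup_taxa if self.min_ingroup_taxa is not None else self.min_taxa


def has_taxon_duplication(
    tree: Tree, scheme: TaxonNameScheme = DEFAULT_SCHEME
) -> bool:
    """True iff two or more tips of the tree share a taxon."""
    seen: set[str] = set()
    for label in tree.tip_labels():
        taxon = scheme.taxon_of(label)
        if taxon in seen:
            return True
        seen.add(taxon)
    return False


# ---------------------------------------------------------------------------
# Shared machinery: edge-subtree enumeration and deterministic selection
# ---------------------------------------------------------------------------


def induced_subtree(tree: Tree, labels: Iterable[str]) -> Tree:
    """Copy of ``tree`` restricted to ``labels`` (unifurcations merged)."""
    keep = set(labels)
    out = tree.copy()
    out.keep_tips_by_label(keep)
    return out


def _clade_sets(tree: Tree) -> list[frozenset[str]]:
    """Tip-label set of every clade below a non-root node."""
    out: list[frozenset[str]] = []
    memo: dict[int, frozenset[str]] = {}
    for node in tree.root.iter_postorder():
        if node.is_tip:
            memo[id(node)] = frozenset([node.label])
        else:
            memo[id(node)] = frozenset().union(
                *(memo[id(c)] for c in node.children)
            )
        if node.parent is not None:
            out.append(memo[id(node)])
    return out


@dataclass
class _Candidate:
    labels: frozenset[str]
    n_taxa: int
    n_tips: int
    chars: int
    sorted_labels: tuple[str, ...]


def _make_candidate(
    labels: frozenset[str],
    scheme: TaxonNameScheme,
    char_counts: Optional[dict[str, int]],
) -> _Candidate:
    return _Candidate(
        labels=labels,
        n_taxa=len({scheme.taxon_of(x) for x in labels}),
        n_tips=len(labels),
        chars=sum(char_counts.get(x, 0) for x in labels) if char_counts else 0,
        sorted_labels=tuple(sorted(labels)),
    )


def _better(a: _Candidate, b: Optional[_Candidate]) -> bool:
    """Deterministic preference order used by every strategy."""
    if b is None:
        return True
    ka = (a.n_taxa, a.n_tips, a.chars)
    kb = (b.n_taxa, b.n_tips, b.chars)
    if ka != kb:
        return ka > kb
    return a.sorted_labels < b.sorted_labels


def _smaller(a: _Candidate, b: _Candidate) -> bool:
    """Inverse preference: which side to prune at a duplication."""
    ka = (a.n_taxa, a.n_tips, a.chars)
    kb = (b.n_taxa, b.n_tips, b.chars)
    if ka != kb:
        return ka < kb
    return a.sorted_labels < b.sorted_labels


def _is_duplication_free(labels: Iterable[str], scheme: TaxonNameScheme) -> bool:
    labels = list(labels)
    return len({scheme.taxon_of(x) for x in labels}) == len(labels)


# ---------------------------------------------------------------------------
# MI: maximum inclusion
# ---------------------------------------------------------------------------


def prune_mi(
    tree: Tree,
    min_taxa: int = 8,
    tip_trim: Optional[RefinementConfig] = None,
    scheme: TaxonNameScheme = DEFAULT_SCHEME,
    char_counts: Optional[dict[str, int]] = None,
    source_id: str = "",
) -> list[OrthologTree]:
    """Iteratively cut out the largest duplication-free subtree.

    Both orientations of every edge (clade and its complement) and the
    whole tree are candidate subtrees; among duplication-free
    candidates with at least ``min_taxa`` distinct taxa the best under
    the deterministic preference order is extracted, its tips removed,
    and — when ``tip_trim`` is given — the remainder cleared of long
    leftover tips before the next round.  Emitted tip sets are pairwise
    disjoint.
    """
    work: Optional[Tree] = tree.copy()
    out: list[OrthologTree] = []
    while work is not None and work.num_tips() >= min_taxa:
        all_tips = frozenset(work.tip_labels())
        seen: set[frozenset[str]] = set()
        best: Optional[_Candidate] = None
        for side in _clade_sets(work) + [all_tips]:
            for labels in (side, all_tips - side):
                if not labels or labels in seen:
                    continue
                seen.add(labels)
                if len(labels) < min_taxa:
                    continue
                if not _is_duplication_free(labels, scheme):
                    continue
                cand = _make_candidate(labels, scheme, char_counts)
                if cand.n_taxa < min_taxa:
                    continue
                if _better(cand, best):
                    best = cand
        if best is None:
            break
        out.append(
            OrthologTree(
                induced_subtree(work, best.labels), source_id, "MI", scheme
            )
        )
        remainder = all_tips - best.labels
        if not remainder:
            break
        work = induced_subtree(work, remainder)
        if tip_trim is not None and work.num_tips() >= 3:
            work = trim_spurious_tips(work, tip_trim)
    return out


# ---------------------------------------------------------------------------
# RT: rooted-ingroup extraction and root-to-tip duplication pruning
# ---------------------------------------------------------------------------


def extract_rooted_ingroup_clades(
    tree: Tree,
    roles: TaxonRoles,
    min_ingroup_taxa: int = 8,
    scheme: TaxonNameScheme = DEFAULT_SCHEME,
    char_counts: Optional[dict[str, int]] = None,
) -> list[Tree]:
    """Cut out maximal all-ingroup subtrees, oriented by the outgroups.

    While the working tree still contains an outgroup tip, the
    edge-delimited subtree consisting purely of ingroup tips with the
    most distinct ingroup taxa is cut out as a rooted tree; the
    remainder (which keeps all outgroup tips) is searched again.
    Clades with fewer than ``min_ingroup_taxa`` distinct taxa are
    discarded at the end.
    """

    def is_outgroup(label: str) -> bool:
        return scheme.taxon_of(label) in roles.outgroup

    work = tree.copy()
    clades: list[Tree] = []
    while any(is_outgroup(t) for t in work.tip_labels()):
        all_tips = frozenset(work.tip_labels())
        best: Optional[_Candidate] = None
        seen: set[frozenset[str]] = set()
        for side in _clade_sets(work):
            for labels in (side, all_tips - side):
                if not labels or labels in seen:
                    continue
                seen.add(labels)
                if any(is_outgroup(x) for x in labels):
                    continue
                if _better(
                    cand := _make_candidate(labels, scheme, char_counts), best
                ):
                    best = cand
        if best is None:
            break
        clade = induced_subtree(work, best.labels)
        clade.rooted = True
        clades.append(clade)
        work = induced_subtree(work, all_tips - best.labels)
    return [
        c
        for c in clades
        if len(c.taxa(scheme.taxon_of)) >= min_ingroup_taxa
    ]


def _resolve_duplications(
    tree: Tree,
    scheme: TaxonNameScheme,
    char_counts: Optional[dict[str, int]],
) -> list[Tree]:
    """Root-to-tip duplication pruning; returns the pruned-off sides.

    At every node whose child subtrees share at least one taxon, the
    smaller child (under the deterministic order) among those involved
    in an overlap is detached; at polytomies this repeats until no two
    children overlap.  ``tree`` is modified in place and ends
    duplication-free.
    """
    pruned: list[Tree] = []
    changed = True
    while changed:
        changed = False
        for node in tree.root.iter_preorder():
            if len(node.children) < 2:
                continue
            kids = node.children
            taxa_sets = [
                {scheme.taxon_of(t) for t in c.tip_labels()} for c in kids
            ]
            involved: set[int] = set()
            for i in range(len(kids)):
                for j in range(i + 1, len(kids)):
                    if taxa_sets[i] & taxa_sets[j]:
                        involved.update((i, j))
            if not involved:
                continue
            cands = {
                i: _make_candidate(
                    frozenset(kids[i].tip_labels()), scheme, char_counts
                )
                for i in involved
            }
            victim_i = min(
                involved, key=lambda i: _SortKey(cands[i])
            )
            victim = node.remove_child(kids[victim_i])
            victim.length = None
            pruned.append(Tree(victim, rooted=True))
            tree._suppress_if_unifurcation(node)
            changed = True
            break
    return pruned


class _SortKey:
    """Total order over candidates matching :func:`_smaller`."""

    def __init__(self, cand: _Candidate):
        self.cand = cand

    def __lt__(self, other: "_SortKey") -> bool:
        return _smaller(self.cand, other.cand)


def prune_paralogs_rt(
    tree: Tree,
    min_taxa: int = 8,
    scheme: TaxonNameScheme = DEFAULT_SCHEME,
    char_counts: Optional[dict[str, int]] = None,
    source_id: str = "",
    reprocess_pruned: bool = True,
) -> list[OrthologTree]:
    """Prune paralogs from a rooted (ingroup) tree, root to tips.

    Every pruned side re-enters the candidate pool as its own rooted
    subtree (with ``reprocess_pruned`` off it is discarded instead).
    Returns all duplication-free candidates with at least ``min_taxa``
    distinct taxa.
    """
    if not tree.rooted:
        raise TreeError("RT duplication pruning requires a rooted tree")
    pool: list[Tree] = [tree.copy()]
    out: list[OrthologTree] = []
    while pool:
        current = pool.pop(0)
        pruned = _resolve_duplications(current, scheme, char_counts)
        if reprocess_pruned:
            pool.extend(p for p in pruned if not p.root.is_tip)
        if len(current.taxa(scheme.taxon_of)) >= min_taxa:
            out.append(OrthologTree(current, source_id, "RT", scheme))
    return out


# ---------------------------------------------------------------------------
# MO: monophyletic-outgroup rooting
# ---------------------------------------------------------------------------


def prune_paralogs_mo(
    tree: Tree,
    roles: TaxonRoles,
    min_taxa: int = 8,
    scheme: TaxonNameScheme = DEFAULT_SCHEME,
    char_counts: Optional[dict[str, int]] = None,
    source_id: str = "",
) -> Optional[OrthologTree]:
    """Root on a monophyletic, non-repeating outgroup and prune paralogs.

    Returns ``None`` when no outgroup tip is present, an outgroup taxon
    occurs twice, the outgroup tips are not separated from all ingroup
    tips by a single edge, or the surviving tree is too small.  Pruned
    sides are discarded, so at most one ortholog (retaining the full
    outgroup clade) comes out of each homolog.
    """
    tips = tree.tip_labels()
    out_tips = [t for t in tips if scheme.taxon_of(t) in roles.outgroup]
    if not out_tips:
        logger.info("%s: no outgroup tips; MO not applicable", source_id)
        return None
    out_taxa = [scheme.taxon_of(t) for t in out_tips]
    if len(set(out_taxa)) != len(out_taxa):
        return None
    out_set = frozenset(out_tips)
    all_set = frozenset(tips)
    in_set = all_set - out_set
    if not in_set:
        return None
    # monophyly in the unrooted sense: one edge separates outgroup from ingroup
    if len(out_tips) < len(tips):
        sides = set(_clade_sets(tree))
        if out_set not in sides and in_set not in sides:
            return None

    ingroup_tree = induced_subtree(tree, in_set)
    ingroup_tree.rooted = True
    _resolve_duplications(ingroup_tree, scheme, char_counts)  # discard pruned

    outgroup_tree = induced_subtree(tree, out_set)
    root = Node()
    root.add_child(ingroup_tree.root)
    root.add_child(outgroup_tree.root)
    result = Tree(root, rooted=True)
    if len(result.taxa(scheme.taxon_of)) < min_taxa:
        return None
    return OrthologTree(result, source_id, "MO", scheme)


# ---------------------------------------------------------------------------
# 1to1 and the method dispatcher
# ---------------------------------------------------------------------------


def filter_1to1(
    tree: Tree,
    min_taxa: int = 8,
    scheme: TaxonNameScheme = DEFAULT_SCHEME,
    source_id: str = "",
) -> Optional[OrthologTree]:
    """The whole homolog is an ortholog iff it has no taxon duplication."""
    if has_taxon_duplication(tree, scheme):
        return None
    if len(tree.taxa(scheme.taxon_of)) < min_taxa:
        return None
    return OrthologTree(tree.copy(), source_id, "1to1", scheme)


def run_method(
    homologs: Sequence[tuple[str, Tree]],
    method: str,
    roles: TaxonRoles,
    cfg: PruneConfig,
    scheme: TaxonNameScheme = DEFAULT_SCHEME,
    char_counts: Optional[dict[str, dict[str, int]]] = None,
) -> tuple[list[OrthologTree], list[dict]]:
    """Apply one strategy to every homolog; return orthologs + report.

    For RT, homologs lacking outgroup tips are included only when
    duplication-free (as unrooted ortholog trees); homologs with
    duplications but no outgroups are skipped, since they cannot be
    rooted.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method tag {method!r}; expected one of {METHODS}")
    orthologs: list[OrthologTree] = []
    report: list[dict] = []
    for hid, tree in homologs:
        counts = (char_counts or {}).get(hid)
        n_before = tree.num_tips()
        got: list[OrthologTree] = []
        note = ""
        if method == "MI":
            got = prune_mi(
                tree, cfg.min_taxa, cfg.mi_tip_trim, scheme, counts, hid
            )
        elif method == "1to1":
            one = filter_1to1(tree, cfg.min_taxa, scheme, hid)
            got = [one] if one else []
        elif method == "MO":
            one = prune_paralogs_mo(
                tree, roles, cfg.min_taxa, scheme, counts, hid
            )
            got = [one] if one else []
        elif method == "RT":
            has_out = any(
                scheme.taxon_of(t) in roles.outgroup for t in tree.tip_labels()
            )
            if has_out:
                for clade in extract_rooted_ingroup_clades(
                    tree, roles, cfg.ingroup_minimum, scheme, counts
                ):
                    for orth in prune_paralogs_rt(
                        clade,
                        cfg.ingroup_minimum,
                        scheme,
                        counts,
                        hid,
                        reprocess_pruned=cfg.rt_reprocess_pruned,
                    ):
                        got.append(orth)
            elif not has_taxon_duplication(tree, scheme):
                if len(tree.taxa(scheme.taxon_of)) >= cfg.min_taxa:
                    got = [OrthologTree(tree.copy(), hid, "RT", scheme)]
            else:
                note = "skipped: duplicated taxa but no outgroup"
        orthologs.extend(got)
        report.append(
            {
                "homolog": hid,
                "method": method,
                "tips_in": n_before,
                "orthologs": len(got),
                "tips_out": sum(o.tree.num_tips() for o in got),
                "note": note,
            }
        )
    return orthologs, report


def occupancy_table(
    orthologs: Iterable[OrthologTree], taxa: Iterable[str]
) -> list[dict]:
    """Ortholog x taxon presence table (rows sorted by taxon count, descending)."""
    taxa = sorted(taxa)
    rows = []
    for i, orth in enumerate(orthologs):
        present = orth.taxa
        row = {"ortholog": f"{orth.source_id}|{orth.method}|{i}"}
        row.update({t: int(t in present) for t in taxa})
        row["n_taxa"] = len(present & set(taxa))
        rows.append(row)
    rows.sort(key=lambda r: (-r["n_taxa"], r["ortholog"]))
    return rows
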