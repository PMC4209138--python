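"""Synthetic gene families with known histories and injected artifacts.

The generator emulates the properties of transcriptome-derived gene
families that the cleaning and pruning stages are designed to handle:
gene duplication and loss along a species tree, isoform tips (near
identical same-taxon sisters), and misassembled sequences (aberrantly
long terminal branches).  Every event is recorded in an
:class:`EventLog`, which is the ground truth for recovery tests.

Species trees are pure-birth (Yule) topologies.  Branch lengths are
split into an internal part and a terminal stem: transcriptome
phylogenomic datasets sample taxa sparsely, so terminal branches carry
a substantial share of the root-to-tip path.  Sequence content is
placeholder (random residues at a configurable ambiguity fraction) —
only lengths and unambiguous-character counts matter to the
algorithms under test.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .seqio import Alignment, SequenceRecord, write_fasta
from .tree import Node, Tree, write_newick

__all__ = [
    "SimConfig",
    "EventLog",
    "simulate_species_tree",
    "simulate_gene_family",
    "inject_artifacts",
    "fake_alignment",
    "emit_fixture_set",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SimConfig:
    """Study conditions for the generator.

    ``depth`` is the expected root-to-tip path length in
    substitutions/site; ``internal_fraction`` of it is spent inside the
    tree, the rest on terminal stems.  Rates are events per unit branch
    length.  The misassembly multiplier stretches a pendant branch by
    20x, far past both tip cutoffs, as real misassemblies do.
    """

    n_taxa: int = 12
    depth: float = 0.4
    internal_fraction: float = 0.4
    dup_rate: float = 0.2
    loss_rate: float = 0.1
    isoform_prob: float = 0.1
    misassembly_prob: float = 0.05
    misassembly_multiplier: float = 20.0
    isoform_branch: float = 0.002
    rate_noise_sigma: float = 0.1
    seq_length: int = 300
    ambiguity_fraction: float = 0.05
    n_families: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 3:
            raise ValueError("need at least 3 taxa")
        if self.dup_rate < 0 or self.loss_rate < 0:
            raise ValueError("rates must be non-negative")
        for p in (self.isoform_prob, self.misassembly_prob):
            if not (0 <= p <= 1):
                raise ValueError("probabilities must be in [0, 1]")
        if not (0 < self.internal_fraction < 1):
            raise ValueError("internal_fraction must be in (0, 1)")


@dataclass
class EventLog:
    """Ground truth for one gene family.

    ``tip_history`` maps each surviving tip to its duplication-copy
    choices (event id -> 0/1).  Two tips are co-orthologs exactly when
    their histories agree on every event they share; an ortholog tip
    set "mixes paralogs" when some pair disagrees.  The canonical
    group label of a tip is its serialized history.
    """

    duplications: list[str] = field(default_factory=list)
    n_losses: int = 0
    tip_history: dict[str, dict[str, int]] = field(default_factory=dict)
    isoform_pairs: list[tuple[str, str]] = field(default_factory=list)
    misassembled_tips: list[str] = field(default_factory=list)

    def group_of(self, tip: str) -> str:
        h = self.tip_history[tip]
        return ",".join(f"{e}:{h[e]}" for e in sorted(h)) or "root"

    def compatible(self, tip_a: str, tip_b: str) -> bool:
        ha, hb = self.tip_history[tip_a], self.tip_history[tip_b]
        return all(hb[e] == c for e, c in ha.items() if e in hb)

    def mixes_paralogs(self, tips: list[str]) -> bool:
        """True if some pair of tips chose different copies of a duplication."""
        known = [t for t in tips if t in self.tip_history]
        return any(
            not self.compatible(a, b)
            for i, a in enumerate(known)
            for b in known[i + 1 :]
        )


# ---------------------------------------------------------------------------
# Species tree
# ---------------------------------------------------------------------------


def simulate_species_tree(
    n_taxa: int,
    depth: float = 0.4,
    seed: int = 0,
    internal_fraction: float = 0.4,
) -> Tree:
    """Yule topology, ultrametric, scaled to root-to-tip length ``depth``.

    Tips are labelled T1..Tn in order of lineage creation.  The
    internal part of the tree spans ``internal_fraction * depth``; the
    remainder is added to every terminal branch as a stem.
    """
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    rng = np.random.default_rng(seed)

    # grow a Yule tree: each active lineage splits at rate 1
    root = Node()
    birth: dict[int, float] = {}  # node id -> time its subtending edge began
    active: list[Node] = []
    t = 0.0
    for _ in range(2):
        child = root.add_child(Node())
        birth[id(child)] = 0.0
        active.append(child)
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / len(active))
        victim = active.pop(rng.integers(len(active)))
        victim.length = t - birth[id(victim)]
        for _ in range(2):
            child = victim.add_child(Node())
            birth[id(child)] = t
            active.append(child)
    t_end = t + rng.exponential(1.0 / len(active))
    for node in active:
        node.length = t_end - birth[id(node)]

    # scale internal structure, add terminal stems, label tips
    scale = internal_fraction * depth / t_end if t_end > 0 else 1.0
    stem = (1.0 - internal_fraction) * depth
    tree = Tree(root, rooted=True)
    k = 0
    for node in root.iter_preorder():
        if node.length is not None:
            node.length *= scale
        if node.is_tip:
            k += 1
            node.label = f"T{k}"
            node.length += stem
    return tree


# ---------------------------------------------------------------------------
# Gene family birth-death along the species tree
# ---------------------------------------------------------------------------


def simulate_gene_family(
    species_tree: Tree,
    dup_rate: float,
    loss_rate: float,
    seed: int = 0,
    rate_noise_sigma: float = 0.0,
) -> tuple[Optional[Tree], EventLog]:
    """Evolve one gene family along the species tree.

    Duplications split a gene lineage in two (copies 0 and 1, recorded
    in every descendant tip's history); losses terminate it.  With
    both rates 0 the gene tree is congruent to the species tree with
    exactly one tip per taxon.  Returns ``(None, log)`` when every
    lineage is lost.
    """
    rng = np.random.default_rng(seed)
    log = EventLog()
    total = dup_rate + loss_rate
    counters: dict[str, int] = {}
    dup_counter = [0]

    def evolve(sp_node: Node, remaining: float, history: dict[str, int]) -> Optional[Node]:
        consumed = 0.0
        while True:
            wait = rng.exponential(1.0 / total) if total > 0 else math.inf
            if wait >= remaining:
                consumed += remaining
                if sp_node.is_tip:
                    taxon = sp_node.label
                    counters[taxon] = counters.get(taxon, 0) + 1
                    label = f"{taxon}@g{counters[taxon]}"
                    log.tip_history[label] = dict(history)
                    return Node(label, consumed)
                kids = []
                for sp_child in sp_node.children:
                    sub = evolve(sp_child, sp_child.length, history)
                    if sub is not None:
                        kids.append(sub)
                if not kids:
                    return None
                if len(kids) == 1:  # one side lost: speciation leaves no node
                    kids[0].length += consumed
                    return kids[0]
                node = Node("", consumed)
                for kid in kids:
                    node.add_child(kid)
                return node
            consumed += wait
            remaining -= wait
            if rng.random() < (loss_rate / total if total > 0 else 0):
                log.n_losses += 1
                return None
            dup_counter[0] += 1
            event = f"D{dup_counter[0]}"
            log.duplications.append(event)
            sides = []
            for copy in (0, 1):
                sub = evolve(sp_node, remaining, {**history, event: copy})
                if sub is not None:
                    sides.append(sub)
            if not sides:
                return None
            if len(sides) == 1:
                sides[0].length += consumed
                return sides[0]
            node = Node("", consumed)
            for side in sides:
                node.add_child(side)
            return node

    tops = []
    for sp_child in species_tree.root.children:
        sub = evolve(sp_child, sp_child.length, {})
        if sub is not None:
            tops.append(sub)
    if not tops:
        return None, log
    if len(tops) == 1:
        root = tops[0]
        root.length = None
    else:
        root = Node()
        for top in tops:
            root.add_child(top)
    tree = Tree(root, rooted=len(root.children) == 2)
    if rate_noise_sigma > 0:
        for node in tree.root.iter_preorder():
            if node.length is not None:
                node.length *= float(rng.lognormal(0.0, rate_noise_sigma))
    return tree, log


def inject_artifacts(
    tree: Tree, cfg: SimConfig, log: EventLog, seed: int = 0
) -> Tree:
    """Add isoform sister tips and stretch misassembled pendants.

    Per original tip, mutually exclusive draws: with
    ``isoform_prob`` an isoform is attached as a near-zero-length
    sister (label suffix ``_iso``); with ``misassembly_prob`` the
    pendant branch is multiplied by ``misassembly_multiplier``.  The
    event log is updated in place; the input tree is not modified.
    """
    rng = np.random.default_rng(seed)
    out = tree.copy()
    for tip in list(out.iter_tips()):
        u = rng.random()
        if u < cfg.isoform_prob:
            iso_label = f"{tip.label}_iso"
            joint = Node("", tip.length)
            parent = tip.parent
            if parent is None:
                continue  # single-tip tree: nothing sensible to do
            idx = parent.children.index(tip)
            parent.children[idx] = joint
            joint.parent = parent
            tip.parent = joint
            tip.length = cfg.isoform_branch
            joint.children.append(tip)
            joint.add_child(Node(iso_label, cfg.isoform_branch))
            log.isoform_pairs.append((tip.label, iso_label))
            log.tip_history[iso_label] = dict(log.tip_history.get(tip.label, {}))
        elif u < cfg.isoform_prob + cfg.misassembly_prob:
            if tip.length is not None:
                tip.length *= cfg.misassembly_multiplier
            log.misassembled_tips.append(tip.label)
    return out


# ---------------------------------------------------------------------------
# Placeholder alignments and pseudo-hits
# ---------------------------------------------------------------------------


def fake_alignment(tip_labels: list[str], cfg: SimConfig, seed: int = 0) -> Alignment:
    """Random gap-free residue rows; ambiguity fraction via 'X' characters."""
    rng = np.random.default_rng(seed)
    records = []
    for label in tip_labels:
        chars = rng.choice(list(_AA), size=cfg.seq_length)
        mask = rng.random(cfg.seq_length) < cfg.ambiguity_fraction
        chars[mask] = "X"
        records.append(SequenceRecord(label, "".join(chars), "aa"))
    return Alignment(records)


def _pairwise_distances(tree: Tree) -> dict[tuple[str, str], float]:
    """Patristic distances between all tip pairs (missing lengths as 0)."""
    tips = list(tree.iter_tips())
    # root-to-node distances
    dist: dict[int, float] = {id(tree.root): 0.0}
    parent_of: dict[int, Node] = {}
    for node in tree.root.iter_preorder():
        for child in node.children:
            dist[id(child)] = dist[id(node)] + (child.length or 0.0)
            parent_of[id(child)] = node
    out = {}
    for i, a in enumerate(tips):
        # ancestors of a
        anc = {}
        node: Optional[Node] = a
        while node is not None:
            anc[id(node)] = dist[id(node)]
            node = parent_of.get(id(node))
        for b in tips[i + 1 :]:
            node = b
            while id(node) not in anc:
                node = parent_of[id(node)]
            mrca = dist[id(node)]
            d = dist[id(a)] + dist[id(b)] - 2 * mrca
            out[(a.label, b.label)] = d
            out[(b.label, a.label)] = d
    return out


def pseudo_blast_lines(tree: Tree, seq_length: int) -> list[str]:
    """Deterministic full-coverage hit records for all tip pairs of a family.

    E values fall off with patristic distance (more divergent pairs
    are less significant) but every within-family pair stays far below
    the 1e-5 cutoff, so the intended clusters survive filtering.
    Self-hits carry E = 0.
    """
    dists = _pairwise_distances(tree)
    labels = sorted(tree.tip_labels())
    lines = []
    for q in labels:
        for s in labels:
            if q == s:
                evalue, bits = 0.0, 600.0
            else:
                weight = max(20.0, 180.0 * math.exp(-dists[(q, s)]))
                evalue, bits = 10.0 ** (-weight), weight * 2.5
            lines.append(
                "\t".join(
                    [
                        q, s, "90.0", str(seq_length), "5", "0",
                        "1", str(seq_length), "1", str(seq_length),
                        f"{evalue:.3g}", f"{bits:.1f}",
                        str(seq_length), str(seq_length),
                    ]
                )
            )
    return lines


def _scope_labels_to_family(tree: Tree, log: EventLog, family: str) -> None:
    """Prefix gene ids with the family so tips are unique dataset-wide.

    ``T3@g1`` becomes ``T3@fam0.g1``; the taxon prefix is untouched.
    """

    def rename(label: str) -> str:
        taxon, gene = label.split("@", 1)
        return f"{taxon}@{family}.{gene}"

    for tip in tree.iter_tips():
        tip.label = rename(tip.label)
    log.tip_history = {rename(k): v for k, v in log.tip_history.items()}
    log.isoform_pairs = [(rename(a), rename(b)) for a, b in log.isoform_pairs]
    log.misassembled_tips = [rename(t) for t in log.misassembled_tips]


def emit_fixture_set(cfg: SimConfig, outdir: Union[str, Path]) -> dict:
    """Write a complete, self-consistent input set for every pipeline stage.

    Products (all plain text): the species tree, per-family gene trees
    with injected artifacts, placeholder FASTA alignments covering
    every tip, a pseudo-BLAST tabular file, a cluster file standing in
    for external MCL output, and the ground-truth event log TSV.
    Identical seeds give byte-identical output.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    species = simulate_species_tree(
        cfg.n_taxa, cfg.depth, int(rng.integers(2**31)), cfg.internal_fraction
    )
    (outdir / "species.nwk").write_text(write_newick(species) + "\n")

    hit_lines: list[str] = []
    cluster_lines: list[str] = []
    event_rows: list[str] = []
    manifest = {"families": [], "species_tree": "species.nwk"}
    made = 0
    while made < cfg.n_families:
        fam_seed = int(rng.integers(2**31))
        gene, log = simulate_gene_family(
            species, cfg.dup_rate, cfg.loss_rate, fam_seed, cfg.rate_noise_sigma
        )
        if gene is None or gene.num_tips() < 4:
            continue
        gene = inject_artifacts(gene, cfg, log, int(rng.integers(2**31)))
        fam = f"fam{made}"
        _scope_labels_to_family(gene, log, fam)
        (outdir / f"{fam}.nwk").write_text(write_newick(gene) + "\n")
        aln = fake_alignment(
            sorted(gene.tip_labels()), cfg, int(rng.integers(2**31))
        )
        write_fasta(list(aln), outdir / f"{fam}.fa")
        hit_lines.extend(pseudo_blast_lines(gene, cfg.seq_length))
        cluster_lines.append("\t".join(sorted(gene.tip_labels())))
        for tip in sorted(log.tip_history):
            kind = "tip"
            if tip in {iso for _, iso in log.isoform_pairs}:
                kind = "isoform"
            elif tip in log.misassembled_tips:
                kind = "misassembly"
            event_rows.append(f"{fam}\t{tip}\t{kind}\t{log.group_of(tip)}")
        manifest["families"].append(
            {
                "id": fam,
                "tree": f"{fam}.nwk",
                "alignment": f"{fam}.fa",
                "n_duplications": len(log.duplications),
                "n_losses": log.n_losses,
                "n_isoforms": len(log.isoform_pairs),
                "n_misassembled": len(log.misassembled_tips),
            }
        )
        made += 1

    (outdir / "hits.tsv").write_text("\n".join(hit_lines) + "\n")
    (outdir / "clusters.mcl").write_text("\n".join(cluster_lines) + "\n")
    (outdir / "events.tsv").write_text(
        "family\ttip\tkind\tgroup\n" + "\n".join(event_rows) + "\n"
    )
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    return manifest
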