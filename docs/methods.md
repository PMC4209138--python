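# Methods

## The problem and the approach

Orthology inference for species-tree estimation must separate
orthologs (related by speciation) from paralogs (related by
duplication) inside putative homolog groups. When the data are de
novo transcriptomes and low-coverage genomes, homolog gene trees
additionally contain isoform tips (near-identical same-taxon
sequences), misassembled or frameshifted sequences on aberrantly long
terminal branches, and deep paralogs glued together by coarse
clustering. `orthoprune` treats all of these as tree-surgery
problems on the homolog phylogeny, then extracts orthologs with four
alternative pruning strategies. Alignments and trees themselves are
computed by external tools; this package consumes their formats.

## Data model

Trees are stored rooted, with an explicit rooted-flag: a newick whose
outermost grouping has two children is genuinely rooted, one with
three or more is an unrooted tree in rooted notation. Branch lengths
are substitutions/site; a missing length is `None`, distinct from 0 —
any cutoff comparison that needs a number substitutes 0 and logs a
warning. Sequence identifiers carry the taxon as a prefix,
`taxon@sequenceId` (delimiter configurable); the taxon is the token
before the first delimiter.

Unambiguous-character counting (used to pick isoform representatives)
excludes gaps `-`, unknowns `?`, stops `*`, and the total-ambiguity
code of the alphabet (`X` for amino acids, `N` for nucleotides).
IUPAC partial ambiguities (R, Y, …) still restrict the state set and
count as informative.

## Similarity filtering and clustering support

The *hit fraction* of a query–subject record is the covered fraction
of a sequence, after merging HSP intervals by union. The default
takes the **minimum** over query and subject — both sequences must be
well covered — because partial-overlap chains of fragments are what
snowball gene families into unalignable mega-clusters; `max` mode is
available for the permissive reading. Filtering keeps hits with
fraction ≥ 0.4 and E ≤ 1e-5, removes self-hits, and collapses
reciprocal records to one undirected edge keeping the lower E value.
Edge weights for Markov clustering are −log₁₀ E capped at 180, the
floor at which BLAST E values saturate; E = 0 maps to the cap.

End trimming cuts each sequence to the span from its first to its
last hit-covered position; interior uncovered stretches are kept
(they are alignment gaps, not misassembly evidence). Filters run in
order end-trim → 40-residue length floor → 8-taxon cluster floor,
because trimming can push a sequence under the floor.

## Homolog refinement

Stage order is tip-trim → isoform-mask → long-branch-cut.

**Spurious tips.** A tip is removed when its pendant branch is both
longer than `tip_relative_factor` (10) times the mean distance from
its attachment node to the tips of its sister clade *and* longer than
an absolute cutoff. The sister-clade mean includes the sibling edge
(the inclusive convention — it measures how far the suspect tip sticks
out relative to local tree depth); at polytomies and at the root of an
unrooted tree all co-subtrees are pooled. Within a sweep the longest
offending pendant is removed first and statistics recomputed, to a
fixpoint; this is deterministic and prevents one aberrant tip from
shielding another.

**Isoform masking.** When every tip in a tip's sister subtree belongs
to its own taxon, the group collapses to the member with the most
unambiguous characters in the trimmed alignment (ties: smallest
identifier). Paraphyletic grades are masked too: a tip whose parent's
sister is a same-taxon tip merges with it. Both rules iterate to a
fixpoint, so chains and nested clades resolve; afterwards no tip's
sister subtree is mono-taxon identical to it.

**Deep paralogs.** Every internal edge longer than the internal
cutoff is removed; each connected component becomes its own homolog;
components under the minimum taxon count are discarded. Terminal
edges are never cut here (the tip trimmer owns those).

The whole refinement is idempotent: each stage's postcondition is
stable under re-application.

## Ortholog extraction

All strategies share one deterministic preference order for choosing
among candidate subtrees: more distinct taxa, then more tips, then
more total unambiguous characters, then the lexicographically
smallest sorted tip-label tuple. Pruning at a duplication uses the
inverse order to pick the victim. Every emitted ortholog is verified
to contain at most one tip per taxon (a hard invariant, enforced at
construction).

**MI** enumerates both orientations of every edge (each clade and its
complement) plus the whole tree, picks the best duplication-free
candidate with at least `min_taxa` taxa, cuts it out, optionally
trims leftover long tips in the remainder with the stricter MI-stage
cutoffs, and repeats. Emitted tip sets are pairwise disjoint. An
exhaustive brute-force enumeration (independent implementation) is
the test oracle.

**RT** first cuts out maximal all-ingroup edge-delimited subtrees as
rooted clades, oriented by the outgroup tips remaining in the
complement, repeating while the remainder still holds an outgroup
tip. Each rooted clade is then traversed root→tip: at any node whose
child subtrees share a taxon, the smaller child is detached; detached
sides re-enter the pool as their own rooted trees (a switch discards
them instead). Homologs without outgroup tips are used only when
already duplication-free; with duplications but no outgroup they are
skipped, since they cannot be rooted.

**MO** requires the outgroup tips to be non-repeating and separated
from all ingroup tips by a single edge (monophyly in the unrooted
sense); the tree is rooted there, the ingroup side pruned as in RT
but with pruned sides discarded, and the single resulting ortholog
keeps the full outgroup clade. When the root is reassembled the cut
edge's length is carried on the outgroup side.

**1to1** returns the homolog itself iff it has no taxon duplication.

## Supermatrix and jackknife

Ortholog rows are pulled from the homolog alignment, relabelled by
taxon, and columns that became gap-only are dropped. Column cleaning
removes columns whose occupied fraction (not `-`, not `?`; ambiguity
codes count as occupied) is below a threshold — 0.1 for homolog
alignments, 0.3 for ortholog alignments in the presets. Loci are
filtered by trimmed length (100 aa / 300 nt in the presets) and by
the number of missing taxa, then concatenated in lexicographic
locus-id order; absent taxon×locus blocks are gap-filled, partitions
are 1-based inclusive and contiguous by construction, and exports are
relaxed PHYLIP/FASTA plus RAxML-style partition lines (WAG for amino
acids, DNA for nucleotides, overridable).

Jackknife replicates resample whole loci without replacement —
proportion mode keeps round-half-up(p·n) loci, count mode exactly k —
from a seeded generator, so manifests are reproducible. Bipartition
support annotates each internal edge of a reference topology with the
percentage of replicate trees containing the same unordered split of
the shared taxon set.

## The simulator

The generator provides ground truth, not realism. Species trees are
pure-birth (Yule) topologies; tree shape is irrelevant to the
algorithms under test. Root-to-tip depth defaults to 0.4
substitutions/site, of which 40% is internal structure and 60% is
added to every terminal branch as a stem — sparse taxon sampling in
phylogenomic datasets leaves long terminal branches, and this is what
makes a 20× misassembly stretch clearly separable from normal tips.
Gene families evolve along the species tree by a birth–death process
(defaults: duplication 0.2, loss 0.1 events per unit branch length);
each duplication is logged, and every surviving tip records which
copy of each ancestral duplication it descends from. Branch lengths
get lognormal rate noise (σ = 0.1).

Artifacts are injected per tip, mutually exclusively: with
probability 0.1 an isoform joins as a near-zero-length sister
(suffix `_iso`, same taxon); with probability 0.05 the pendant branch
is multiplied by 20. Sequence content is placeholder — random
residues at a 5% ambiguity fraction, fixed length 300 — because only
lengths and unambiguous-character counts reach the algorithms.
Pseudo-similarity hits cover full sequence lengths with E values
decaying deterministically with patristic distance, so the intended
clusters survive filtering; emitted gene ids are family-scoped
(`T3@fam0.g1`) to keep identifiers unique dataset-wide.

**What passing tests show and do not show.** Recovery tests
demonstrate that the algorithms do what they claim on trees whose
artifacts match the injection model: long-pendant misassemblies,
cherry isoforms, clean duplication histories. They do not exercise
alignment error, chimeric sequences spanning two genes, gene-tree
estimation error, or incomplete lineage sorting — on real data the
branch-length cutoffs must be set empirically from the branch-length
distribution, exactly as the per-dataset presets differ.

**Ortholog-group ground truth.** Orthology across a duplication is
not an equivalence relation: taxa outside the duplicated clade are
orthologous to both copies. Each tip therefore carries its full
duplication-copy history, and "no paralog mixing" is checked
pairwise: two tips conflict iff they chose different copies of a
duplication event present in both histories. RT and MO outputs are
required to contain zero conflicting pairs on loss-free simulations.

## Numerical and design choices

- Round-half-up for proportion-mode jackknife sizes (`floor(x+0.5)`),
  so 10% of 25 loci is 3.
- Tie-breaks everywhere are total orders ending in lexicographic
  tip-label comparison: outputs are platform-independent.
- A tree reduced below 3 tips during tip trimming is returned as-is
  with a warning; an empty cluster after member filtering simply
  disappears.
- `cut_long_internal_branches` re-checks nothing after cutting: by
  construction no retained internal edge exceeds the cutoff.
- The misassembly detector's relative condition (10× sister-clade
  mean) loses sensitivity for tips attached next to very deep sister
  clades and for mutually sister misassembled tips (each inflates the
  other's reference depth). On simulated families the removal rate is
  typically 92–98% depending on species-tree shape; the absolute
  cutoff alone never suffices, by design, to protect genuinely
  divergent sequences.
- Problem sizes in the test suite and acceptance script — 12-taxon
  species trees, 200 families per recovery experiment, 500 trees for
  the maximum-inclusion oracle, 20-family end-to-end runs — were
  chosen to exercise every code path at desk scale; all complete in
  seconds.

## Known limitations

- No realignment after long-branch cutting: the published workflow
  re-aligns each piece before re-estimating trees; here that loop is
  external by design.
- Polytomy handling at duplication nodes removes the smallest child
  repeatedly; with many-way polytomies and heavy duplication this can
  prune more than a reconciliation-aware method would.
- Bipartition support requires replicate trees on the same taxon set
  (supersets are restricted; replicates missing reference taxa are
  compared on the shared set only).
- The simulator's E values and coverage are schematic; the similarity
  filter's discriminative behavior on borderline real hits is not
  modeled.
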