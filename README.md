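# orthoprune

Tree-based homology refinement and orthology inference for
phylogenomic datasets built from transcriptomes and low-coverage
genomes.

Transcriptome assemblies are incomplete and riddled with isoforms,
misassemblies and frameshifts. Similarity-based orthology heuristics
(reciprocal best hits, plain MCL clusters) inherit all of that noise.
`orthoprune` instead works on *gene trees*: putative homolog clusters
are cleaned as phylogenies, and orthologs are extracted from the
cleaned trees by explicit pruning algorithms. The package provides the
complete tool chain around externally computed similarity searches,
alignments and tree inferences:

1. **Similarity filtering** — all-by-all hits (BLAST outfmt-6 style)
   are filtered by a *hit fraction* (coverage of both sequences
   ≥ 0.4) and an E-value cutoff (≤ 1e-5), then exported as a weighted
   edge list for external MCL, with edge weight −log₁₀ E capped at 180.
2. **Cluster preparation** — MCL output is parsed; sequence ends with
   no hit coverage are cut off, members shorter than 40 residues and
   clusters with fewer than 8 taxa are dropped.
3. **Homolog-tree refinement** — internal branches longer than a
   cutoff (1.5/1.0/0.3 substitutions/site in the bundled presets) are
   cut to separate deep paralogs; a tip is removed when its branch is
   both >10× the mean distance to its sister clade's tips and longer
   than an absolute cutoff (0.75/0.6/0.1); monophyletic *and*
   paraphyletic same-taxon tips (isoforms) are masked down to the
   sequence with the most unambiguous aligned characters.
4. **Ortholog extraction** — four strategies:
   - **MI** (maximum inclusion): iteratively cut out the
     edge-delimited subtree with the most taxa and no taxon
     duplication; needs no outgroup.
   - **RT** (rooted tree): use outgroup taxa to extract rooted ingroup
     clades, then walk root→tip; where the two sides of a node share a
     taxon, the side with fewer taxa is pruned (and re-enters the
     pool). Outgroups are spent on rooting.
   - **MO** (monophyletic outgroup): only trees whose outgroup tips
     are monophyletic and non-repeating are rooted and pruned; pruned
     sides are discarded, outgroups are retained.
   - **1to1**: keep only homologs already free of taxon duplication.
5. **Supermatrix assembly** — per-ortholog alignments are extracted
   from the homolog alignments, trimmed by column occupancy, filtered
   by length and missing taxa, and concatenated with a RAxML-style
   partition table.
6. **Locus-intact jackknife** — replicates resample whole loci
   (10%/30% or a fixed 20), never individual columns; bipartition
   support of a reference topology is summarized across replicate
   trees.

External programs (BLAST, MCL, MAFFT, FastTree/RAxML) are never
executed — the package reads and writes their file formats, so every
stage is independently re-runnable inside an existing pipeline. A
simulator generates gene families with known duplication/loss
histories, isoform tips and misassembly artifacts, so the whole chain
is testable without any downloads.

## Worked example

Simulate a small dataset and run the full pipeline with the MIL-like
preset and maximum-inclusion pruning:

```bash
orthoprune simulate --seed 11 --n-families 8 --out demo/data
orthoprune pipeline --dir demo/data --preset MIL-like --method mi \
    --max-missing 2 -o demo/run
```

The run report (also in `demo/run/report.json`) prints, among others:

```
"filter_hits":    {"in": 1293, "out": 597}
"parse_clusters": {"in": 8,  "out": 7}
"refine":         {"in": 7,  "out": 7}
"prune":          {"in": 7,  "out": 7}
"supermatrix":    {"taxa": 12, "columns": 2100, "loci": 7, "occupancy": 0.9524}
```

Reading: of 1,293 pseudo-BLAST records, 597 pass the hit-fraction and
E-value filters as undirected edges; 7 of 8 clusters survive the
8-taxon floor; refinement yields 7 cleaned homolog trees (isoform and
misassembly tips removed — see `demo/run/refine_decisions.tsv`); MI
extracts 7 orthologs, whose trimmed alignments concatenate into a
12-taxon × 2,100-column supermatrix at 95.2% occupancy. The partition
file is ready for partitioned ML inference:

```
WAG, fam0.0.0 = 1-300
WAG, fam1.0.1 = 301-600
...
```

Individual stages are also exposed (`orthoprune filter-blast`,
`mcl-input`, `parse-clusters`, `refine`, `prune`, `supermatrix`,
`jackknife`, `support`); run any of them with `--help`.

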