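"""End-to-end orchestration over a directory of pipeline inputs.

Runs the stages in their flow-chart order — similarity filtering,
clustering graph export, cluster parsing, homolog-tree refinement,
ortholog pruning, supermatrix assembly, locus jackknife — with each
stage equally usable on its own.  External tools (BLAST, MCL, aligners,
tree inference) are never executed: the pipeline consumes their file
formats, and a fixture directory from
:func:`orthoprune.simulate.emit_fixture_set` provides stand-ins for
every external product.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Sequence, Union

from .cluster_prep import (
    coverage_map,
    filter_hits,
    parse_mcl_clusters,
    read_blast_tab,
    trim_unsupported_ends,
    write_mcl_input,
)
from .config import DatasetPreset
from .homolog_refine import refine_homolog
from .matrix_build import (
    JackknifeScheme,
    concatenate,
    extract_ortholog_alignment,
    filter_loci,
    jackknife_by_locus,
    occupancy_stats,
    trim_columns_by_occupancy,
    write_partitions,
    write_phylip,
)
from .ortholog_prune import TaxonRoles, occupancy_table, run_method
from .seqio import DEFAULT_SCHEME, Alignment, TaxonNameScheme, read_fasta
from .tree import read_newick, write_newick

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]


def run_pipeline(
    data_dir: Union[str, Path],
    out_dir: Union[str, Path],
    preset: DatasetPreset,
    method: str = "MI",
    outgroups: Sequence[str] = (),
    seed: int = 0,
    scheme: TaxonNameScheme = DEFAULT_SCHEME,
    max_missing_taxa: Optional[int] = None,
) -> dict:
    """Run every stage on a fixture-layout directory; return the run report.

    ``data_dir`` must contain ``hits.tsv``, ``clusters.mcl`` (the
    external clustering output), ``manifest.json`` and per-family
    ``fam*.nwk`` / ``fam*.fa`` files.  Products and a machine-readable
    ``report.json`` land in ``out_dir``.
    """
    data_dir, out_dir = Path(data_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"preset": preset.name, "method": method, "stages": {}}

    manifest_path = data_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(
            f"expected fixture manifest at {manifest_path}; generate inputs "
            "with `orthoprune simulate` or provide the external-tool outputs"
        )
    manifest = json.loads(manifest_path.read_text())

    # ---- similarity filtering and clustering graph -------------------
    hits = read_blast_tab(data_dir / "hits.tsv")
    kept = filter_hits(hits, preset.hit_fraction, preset.evalue_cutoff)
    write_mcl_input(kept, out_dir / "graph.abc")
    report["stages"]["filter_hits"] = {"in": len(hits), "out": len(kept)}

    # ---- end trimming and cluster parsing ---------------------------
    sequences = {}
    for fam in manifest["families"]:
        sequences.update(read_fasta(data_dir / fam["alignment"], preset.char_type))
    coverage = coverage_map(kept)
    trimmed = {
        sid: trim_unsupported_ends(rec, coverage.get(sid, []))
        for sid, rec in sequences.items()
    }
    clusters = parse_mcl_clusters(
        data_dir / "clusters.mcl",
        trimmed,
        min_taxa=preset.min_taxa,
        min_seq_length=preset.min_seq_length,
        scheme=scheme,
        is_path=True,
    )
    report["stages"]["parse_clusters"] = {
        "in": len(manifest["families"]),
        "out": len(clusters),
    }

    # ---- map clusters back to their family tree + alignment ---------
    tip_to_family = {}
    for fam in manifest["families"]:
        tree = read_newick((data_dir / fam["tree"]).read_text())
        for label in tree.tip_labels():
            tip_to_family[label] = fam
    homolog_dir = out_dir / "homologs"
    homolog_dir.mkdir(exist_ok=True)
    homologs = []
    char_counts: dict[str, dict[str, int]] = {}
    alignments: dict[str, Alignment] = {}
    decisions: list[str] = []
    refine_cfg = preset.refinement()
    for cluster in clusters:
        fam = tip_to_family[cluster.members[0]]
        tree = read_newick((data_dir / fam["tree"]).read_text())
        aln = Alignment(read_fasta(data_dir / fam["alignment"], preset.char_type).values())
        for i, cleaned in enumerate(
            refine_homolog(tree, aln, refine_cfg, scheme, log=decisions)
        ):
            hid = f"{fam['id']}.{i}"
            homologs.append((hid, cleaned))
            char_counts[hid] = aln.unambiguous_counts()
            alignments[hid] = aln
            (homolog_dir / f"{hid}.nwk").write_text(write_newick(cleaned) + "\n")
    (out_dir / "refine_decisions.tsv").write_text(
        "\n".join(decisions) + "\n" if decisions else ""
    )
    report["stages"]["refine"] = {"in": len(clusters), "out": len(homologs)}

    # ---- ortholog pruning -------------------------------------------
    all_taxa = {scheme.taxon_of(sid) for sid in sequences}
    roles = TaxonRoles(
        ingroup=frozenset(all_taxa - set(outgroups)),
        outgroup=frozenset(outgroups),
    )
    orthologs, method_report = run_method(
        homologs, method, roles, preset.pruning(), scheme, char_counts
    )
    ortho_dir = out_dir / "orthologs"
    ortho_dir.mkdir(exist_ok=True)
    for i, orth in enumerate(orthologs):
        (ortho_dir / f"{orth.source_id}.{method}.{i}.nwk").write_text(
            write_newick(orth.tree) + "\n"
        )
    occ_rows = occupancy_table(orthologs, sorted(all_taxa))
    if occ_rows:
        cols = list(occ_rows[0].keys())
        (out_dir / "occupancy.tsv").write_text(
            "\t".join(cols)
            + "\n"
            + "\n".join("\t".join(str(r[c]) for c in cols) for r in occ_rows)
            + "\n"
        )
    report["stages"]["prune"] = {
        "in": len(homologs),
        "out": len(orthologs),
        "per_homolog": method_report,
    }

    # ---- loci, supermatrix, jackknife -------------------------------
    mm = preset.max_missing_taxa if max_missing_taxa is None else max_missing_taxa
    loci = []
    for i, orth in enumerate(orthologs):
        locus = extract_ortholog_alignment(
            alignments[orth.source_id],
            orth.tips,
            f"{orth.source_id}.{i}",
            preset.char_type,
            scheme,
        )
        locus = trim_columns_by_occupancy(locus, preset.ortholog_clean)
        if locus.length:
            loci.append(locus)
    matrix_taxa = sorted(all_taxa) if method != "RT" else sorted(
        t for t in all_taxa if t not in roles.outgroup
    )
    good = filter_loci(loci, preset.min_locus_length, mm, matrix_taxa)
    report["stages"]["loci"] = {"in": len(loci), "out": len(good)}
    if good:
        matrix = concatenate(good, matrix_taxa)
        write_phylip(matrix, out_dir / "supermatrix.phy")
        write_partitions(matrix, out_dir / "supermatrix.partitions")
        stats = occupancy_stats(matrix)
        report["stages"]["supermatrix"] = {
            "taxa": len(matrix.taxa),
            "columns": matrix.n_columns,
            "loci": len(matrix.partitions),
            "occupancy": round(stats["overall"], 4),
        }
        scheme_jk = JackknifeScheme(
            mode="proportion",
            value=preset.jackknife_proportions[0],
            replicates=preset.jackknife_replicates,
            seed=seed,
        )
        try:
            manifests = jackknife_by_locus([l.locus_id for l in good], scheme_jk)
            (out_dir / "jackknife.tsv").write_text(
                "\n".join("\t".join(m) for m in manifests) + "\n"
            )
            report["stages"]["jackknife"] = {
                "replicates": len(manifests),
                "loci_per_replicate": len(manifests[0]),
            }
        except ValueError as exc:
            report["stages"]["jackknife"] = {"skipped": str(exc)}
    else:
        logger.warning("no loci passed the length/occupancy filters")
        report["stages"]["supermatrix"] = {"skipped": "no loci passed filters"}

    (out_dir / "report.json").write_text(json.dumps(report, indent=1) + "\n")
    return report
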