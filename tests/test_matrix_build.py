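"""Locus extraction, supermatrix assembly, jackknife and bipartition support."""

import itertools

import numpy as np
import pytest

from orthoprune.matrix_build import (
    JackknifeScheme,
    Locus,
    bipartition_support,
    concatenate,
    extract_ortholog_alignment,
    filter_loci,
    jackknife_by_locus,
    occupancy_stats,
    trim_columns_by_occupancy,
    write_partitions,
    write_phylip,
)
from orthoprune.seqio import Alignment, SequenceRecord
from orthoprune.tree import read_newick


def locus_from(rows: dict[str, str], locus_id="L1", char_type="aa") -> Locus:
    return Locus(
        locus_id,
        Alignment([SequenceRecord(k, v, char_type) for k, v in rows.items()]),
        char_type,
    )


def random_loci(rng, n_loci, taxa):
    loci = []
    for i in range(n_loci):
        width = int(rng.integers(5, 40))
        members = [t for t in taxa if rng.random() < 0.8] or [taxa[0]]
        rows = {}
        for t in members:
            chars = rng.choice(list("ACDEFGHIKLMNPQRSTVWY-"), size=width)
            rows[t] = "".join(chars)
        loci.append(locus_from(rows, f"L{i:03d}"))
    return loci


class TestExtractOrtholog:
    HOMOLOG = Alignment(
        [
            SequenceRecord("T1@g1", "MK-V"),
            SequenceRecord("T2@g1", "MK-V"),
            SequenceRecord("T3@g1", "MKAV"),
            SequenceRecord("T3@g2", "MKAV"),
            SequenceRecord("T4@g1", "--A-"),
            SequenceRecord("T5@g1", "MKAV"),
        ]
    )

    def test_rows_selected_and_relabelled_by_taxon(self):
        locus = extract_ortholog_alignment(
            self.HOMOLOG, ["T1@g1", "T2@g1", "T3@g1", "T5@g1"], "L1"
        )
        assert sorted(locus.taxa) == ["T1", "T2", "T3", "T5"]

    def test_all_gap_columns_dropped(self):
        locus = extract_ortholog_alignment(self.HOMOLOG, ["T1@g1", "T2@g1"], "L1")
        assert locus.length == 3  # the '-' column shared by T1/T2 is gone

    def test_duplicate_taxon_is_contract_error(self):
        with pytest.raises(ValueError, match="twice"):
            extract_ortholog_alignment(self.HOMOLOG, ["T3@g1", "T3@g2"], "L1")

    def test_missing_tip_is_error(self):
        with pytest.raises(KeyError):
            extract_ortholog_alignment(self.HOMOLOG, ["T9@g1"], "L1")


class TestColumnTrimming:
    def test_threshold_arithmetic(self):
        locus = locus_from(
            {"T1": "A-A", "T2": "A--", "T3": "A-A", "T4": "A-?"}
        )
        out = trim_columns_by_occupancy(locus, 0.3)
        # col2: 0/4 removed; col3: 2/4 kept; col1 kept
        assert out.length == 2
        assert out.alignment["T2"].residues == "A-"

    def test_exact_boundary_kept(self):
        locus = locus_from({"T1": "A", "T2": "-", "T3": "-", "T4": "-"})
        assert trim_columns_by_occupancy(locus, 0.25).length == 1
        assert trim_columns_by_occupancy(locus, 0.3).length == 0

    def test_identity_on_gapless(self):
        locus = locus_from({"T1": "ACD", "T2": "ACD"})
        assert trim_columns_by_occupancy(locus, 1.0).length == 3

    def test_idempotent_and_never_grows(self):
        rng = np.random.default_rng(5)
        for locus in random_loci(rng, 20, [f"T{i}" for i in range(6)]):
            once = trim_columns_by_occupancy(locus, 0.3)
            assert once.length <= locus.length
            twice = trim_columns_by_occupancy(once, 0.3)
            assert twice.length == once.length


class TestFilterLoci:
    FULL = {f"T{i}" for i in range(1, 13)}

    def test_length_and_missing_taxa_rules(self):
        full_rows = {t: "M" * 99 for t in self.FULL}
        short = locus_from(full_rows, "short")
        long_rows = {t: "M" * 300 for t in self.FULL}
        good = locus_from(long_rows, "good")
        missing2 = locus_from(
            {t: "M" * 300 for t in sorted(self.FULL)[:-2]}, "m2"
        )
        out = filter_loci([short, good, missing2], 100, 1, self.FULL)
        assert [l.locus_id for l in out] == ["good"]
        out = filter_loci([missing2], 100, 2, self.FULL)
        assert [l.locus_id for l in out] == ["m2"]


class TestConcatenate:
    def test_partition_coordinates(self):
        a = locus_from({"T1": "M" * 100, "T2": "M" * 100}, "a")
        b = locus_from({"T1": "K" * 200, "T3": "K" * 200}, "b")
        m = concatenate([b, a], ["T1", "T2", "T3"])
        assert m.n_columns == 300
        assert m.partitions == [("a", 1, 100), ("b", 101, 300)]
        assert m.rows["T2"][100:] == "-" * 200  # absent block gap-padded
        assert m.rows["T3"][:100] == "-" * 100

    def test_zero_loci_is_an_error(self):
        with pytest.raises(ValueError, match="nothing to concatenate"):
            concatenate([], ["T1"])

    def test_mixed_char_types_rejected(self):
        a = locus_from({"T1": "ACGT"}, "a", "nt")
        b = locus_from({"T1": "MKVA"}, "b", "aa")
        with pytest.raises(ValueError, match="mixed"):
            concatenate([a, b], ["T1"])

    def test_length_conservation_on_random_locus_sets(self):
        rng = np.random.default_rng(11)
        taxa = [f"T{i}" for i in range(8)]
        for _ in range(25):
            loci = random_loci(rng, int(rng.integers(2, 10)), taxa)
            m = concatenate(loci, taxa)
            assert m.n_columns == sum(l.length for l in loci)
            # contiguity is asserted by the Supermatrix constructor itself
            assert m.partitions[0][1] == 1
            assert m.partitions[-1][2] == m.n_columns


class TestOccupancy:
    def test_arithmetic(self):
        m = concatenate(
            [locus_from({"T1": "MMMMMMMM--", "T2": "MMMM------", "T3": "M" * 10}, "a")],
            ["T1", "T2", "T3"],
        )
        assert occupancy_stats(m)["overall"] == pytest.approx(22 / 30)

    def test_gapless_is_one(self):
        m = concatenate([locus_from({"T1": "MMM", "T2": "MMM"}, "a")], ["T1", "T2"])
        assert occupancy_stats(m)["overall"] == 1.0

    def test_curve_sorted_descending(self):
        loci = [
            locus_from({f"T{i}": "M" * 10 for i in range(1, 6)}, "a"),
            locus_from({f"T{i}": "M" * 10 for i in range(1, 5)}, "b"),
            locus_from({f"T{i}": "M" * 10 for i in range(1, 3)}, "c"),
        ]
        stats = occupancy_stats(concatenate(loci, [f"T{i}" for i in range(1, 6)]))
        assert stats["occupancy_curve"] == [5, 4, 2]

    def test_matches_independent_cell_count(self):
        rng = np.random.default_rng(23)
        taxa = [f"T{i}" for i in range(6)]
        for _ in range(20):
            m = concatenate(random_loci(rng, 4, taxa), taxa)
            cells = np.array([list(m.rows[t]) for t in m.taxa])
            expected = np.mean((cells != "-") & (cells != "?"))
            assert occupancy_stats(m)["overall"] == pytest.approx(expected)


class TestJackknife:
    IDS = [f"L{i:02d}" for i in range(50)]

    def test_proportion_mode_sizes(self):
        scheme = JackknifeScheme("proportion", 0.1, replicates=200, seed=4)
        reps = jackknife_by_locus(self.IDS, scheme)
        assert len(reps) == 200
        assert all(len(set(r)) == 5 for r in reps)

    def test_count_mode_exact(self):
        scheme = JackknifeScheme("count", 20, replicates=50, seed=4)
        reps = jackknife_by_locus([f"L{i}" for i in range(1000)], scheme)
        assert all(len(set(r)) == 20 for r in reps)

    def test_round_half_up(self):
        assert JackknifeScheme("proportion", 0.1).sample_size(25) == 3  # 2.5 -> 3
        assert JackknifeScheme("proportion", 0.3).sample_size(50) == 15

    def test_seed_determinism(self):
        s = JackknifeScheme("proportion", 0.3, replicates=20, seed=99)
        assert jackknife_by_locus(self.IDS, s) == jackknife_by_locus(self.IDS, s)
        other = JackknifeScheme("proportion", 0.3, replicates=20, seed=100)
        assert jackknife_by_locus(self.IDS, other) != jackknife_by_locus(self.IDS, s)

    def test_count_exceeding_loci_is_error(self):
        with pytest.raises(ValueError, match="cannot draw"):
            jackknife_by_locus(["a", "b"], JackknifeScheme("count", 3))

    def test_inclusion_frequency_near_proportion(self):
        scheme = JackknifeScheme("proportion", 0.1, replicates=200, seed=7)
        reps = jackknife_by_locus(self.IDS, scheme)
        freq = {i: sum(i in set(r) for r in reps) / 200 for i in self.IDS}
        se = (0.1 * 0.9 / 200) ** 0.5
        assert all(abs(f - 0.1) <= 4 * se for f in freq.values())


class TestBipartitionSupport:
    REF = "((A:1,B:1):1,(C:1,D:1):1);"

    def test_identical_replicates_give_100(self):
        ref = read_newick(self.REF)
        reps = [read_newick(self.REF) for _ in range(3)]
        out = bipartition_support(ref, reps)
        labels = [
            n.label
            for n in out.root.iter_preorder()
            if n.children and n.parent is not None
        ]
        assert labels == ["100", "100"]

    def test_absent_split_gives_0(self):
        ref = read_newick(self.REF)
        reps = [read_newick("((A:1,C:1):1,(B:1,D:1):1);")] * 3
        out = bipartition_support(ref, reps)
        labels = {
            n.label
            for n in out.root.iter_preorder()
            if n.children and n.parent is not None
        }
        assert labels == {"0"}

    def test_four_taxon_frequencies(self):
        """Support equals the replicate frequency of each resolution."""
        resolutions = [
            "((A:1,B:1):1,(C:1,D:1):1);",
            "((A:1,C:1):1,(B:1,D:1):1);",
            "((A:1,D:1):1,(B:1,C:1):1);",
        ]
        rng = np.random.default_rng(3)
        picks = rng.integers(0, 3, size=200)
        reps = [read_newick(resolutions[i]) for i in picks]
        out = bipartition_support(read_newick(self.REF), reps)
        label = next(
            n.label
            for n in out.root.iter_preorder()
            if n.children and n.parent is not None
        )
        expected = 100.0 * np.mean(picks == 0)
        assert float(label) == pytest.approx(expected)

    def test_no_replicates_is_error(self):
        with pytest.raises(ValueError, match="replicate"):
            bipartition_support(read_newick(self.REF), [])


def test_exports_roundtrip(tmp_path):
    a = locus_from({"T1": "M" * 10, "T2": "K" * 10}, "a")
    b = locus_from({"T1": "R" * 5}, "b")
    m = concatenate([a, b], ["T1", "T2"])
    write_phylip(m, tmp_path / "m.phy")
    write_partitions(m, tmp_path / "m.part")
    lines = (tmp_path / "m.phy").read_text().splitlines()
    assert lines[0] == "2 15"
    assert lines[2].split()[1].endswith("-----")
    assert (tmp_path / "m.part").read_text() == "WAG, a = 1-10\nWAG, b = 11-15\n"
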