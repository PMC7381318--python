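"""Probe placement: read splitting, quality and consistency filters,
positional dedup, and the chromosome tally."""

import pytest

from coreselect import MarkerRecord
from coreselect.placement import (
    AlignmentRecord,
    PlacedMarker,
    consistency_filter,
    dedupe_placements,
    filter_alignments,
    place_markers,
    read_alignments_bed,
    read_alignments_sam,
    reference_lookup_from_dict,
    revcomp,
    split_context_sequence,
    tally_by_chromosome,
    write_alignments_sam,
    write_placements_bed,
)
from coreselect.synthetic import generate_placement_fixture


def _aln(read_id, start, end, strand, mapq=60, chrom="chr1", **kw):
    return AlignmentRecord(
        read_id=read_id, chromosome=chrom, start=start, end=end,
        strand=strand, mapq=mapq, cigar=f"{end - start + 1}M", **kw
    )


class TestSplitContextSequence:
    def test_right_read_is_reverse_complement(self):
        left, right, alleles = split_context_sequence(MarkerRecord("m", "AC[T/C]GA"))
        assert left == "AC" and right == "TC" and alleles == ("T", "C")

    def test_palindromic_right_flank_is_fixed_point(self):
        _, right, _ = split_context_sequence(MarkerRecord("m", "GG[A/G]AT"))
        assert right == "AT"

    def test_reembedding_reconstructs_reference(self):
        fx = generate_placement_fixture(100, flank_len=20, seed=13)
        truth = fx.truth.set_index("marker_id")
        for marker in fx.markers:
            row = truth.loc[marker.marker_id]
            if row["expected"] != "kept":
                continue
            left, right, alleles = split_context_sequence(marker)
            pos = int(row["position"])
            rebuilt = left + alleles[0] + revcomp(right)
            ref = fx.reference[row["chromosome"]]
            assert ref[pos - 1 - len(left) : pos + len(right)] == rebuilt


class TestFilterAlignments:
    def test_mapq_threshold_is_inclusive(self):
        kept = filter_alignments([_aln("m/1", 1, 10, "+", mapq=20)])
        assert len(kept) == 1
        assert filter_alignments([_aln("m/1", 1, 10, "+", mapq=19)]) == []

    def test_secondary_and_unmapped_removed(self):
        recs = [
            _aln("m/1", 1, 10, "+", mapq=60, is_secondary=True),
            AlignmentRecord("m/2", "*", 1, 1, "+", 60, is_mapped=False),
        ]
        assert filter_alignments(recs) == []


class TestConsistencyFilter:
    LOOKUP = staticmethod(lambda chrom, pos: "G")

    def test_one_nucleotide_gap_places_at_gap_base(self):
        recs = [_aln("m/1", 100, 119, "+"), _aln("m/2", 121, 140, "-")]
        placed, rejected = consistency_filter(recs, self.LOOKUP)
        assert rejected == {}
        (p,) = placed
        assert (p.chromosome, p.snp_position, p.strand) == ("chr1", 120, "+")

    def test_two_nucleotide_gap_rejected(self):
        recs = [_aln("m/1", 100, 119, "+"), _aln("m/2", 122, 141, "-")]
        placed, rejected = consistency_filter(recs, self.LOOKUP)
        assert placed == [] and rejected == {"m": "gap"}

    def test_missing_mate_rejected(self):
        placed, rejected = consistency_filter([_aln("m/1", 100, 119, "+")], self.LOOKUP)
        assert rejected == {"m": "mate"}

    def test_n_at_snp_site_rejected(self):
        recs = [_aln("m/1", 100, 119, "+"), _aln("m/2", 121, 140, "-")]
        placed, rejected = consistency_filter(recs, lambda c, p: "N")
        assert rejected == {"m": "N-site"}

    def test_ambiguous_multi_mapping_rejected(self):
        recs = [
            _aln("m/1", 100, 119, "+"),
            _aln("m/1", 500, 519, "+"),
            _aln("m/2", 121, 140, "-"),
        ]
        _, rejected = consistency_filter(recs, self.LOOKUP)
        assert rejected == {"m": "ambiguous"}

    def test_gapped_cigar_rejected(self):
        recs = [_aln("m/1", 100, 119, "+"), _aln("m/2", 121, 140, "-")]
        recs[1].cigar = "10M2D10M"
        recs[1].end = 142
        _, rejected = consistency_filter(recs, self.LOOKUP)
        assert rejected == {"m": "cigar"}

    def test_same_strand_pair_rejected(self):
        recs = [_aln("m/1", 100, 119, "+"), _aln("m/2", 121, 140, "+")]
        _, rejected = consistency_filter(recs, self.LOOKUP)
        assert rejected == {"m": "orientation"}

    def test_minus_strand_placement_complements_alleles(self):
        # mate 2 (right flank, written revcomp) maps forward: the marker
        # sits on the reference minus strand
        recs = [_aln("m/2", 100, 119, "+"), _aln("m/1", 121, 140, "-")]
        placed, rejected = consistency_filter(
            recs, self.LOOKUP, alleles={"m": ("A", "G")}
        )
        assert rejected == {}
        (p,) = placed
        assert p.strand == "-" and p.alleles == ("T", "C")
        assert p.snp_position == 120

    def test_lookup_failure_rejects_marker(self):
        def boom(chrom, pos):
            raise IndexError("outside")

        recs = [_aln("m/1", 100, 119, "+"), _aln("m/2", 121, 140, "-")]
        _, rejected = consistency_filter(recs, boom)
        assert rejected == {"m": "lookup"}


class TestDedupePlacements:
    def test_first_in_input_order_kept(self):
        placed = [
            PlacedMarker("mB", "chr2", 500),
            PlacedMarker("mA", "chr2", 500),
        ]
        kept, removed = dedupe_placements(placed, input_order=["mA", "mB"])
        assert [p.marker_id for p in kept] == ["mA"]
        assert removed == {"mB": "mA"}

    def test_unique_positions_pass_through(self):
        placed = [PlacedMarker("a", "chr1", 1), PlacedMarker("b", "chr1", 2)]
        kept, removed = dedupe_placements(placed)
        assert len(kept) == 2 and removed == {}

    def test_three_markers_one_position(self):
        placed = [PlacedMarker(m, "chr3", 9) for m in ("x", "y", "z")]
        kept, removed = dedupe_placements(placed)
        assert len(kept) == 1 and set(removed) == {"y", "z"}


class TestFixtureEndToEnd:
    def test_cascade_reproduces_truth_table(self):
        for seed in (0, 1, 99):
            fx = generate_placement_fixture(100, flank_len=20, seed=seed)
            placed, report = place_markers(
                fx.markers, fx.alignments, reference_lookup_from_dict(fx.reference)
            )
            merged = fx.truth.merge(report, on="marker_id")
            assert (
                (merged["expected"] == "kept") == (merged["status"] == "placed")
            ).all()
            removed = merged[merged["expected"] == "removed"]
            assert (removed["reason_x"] == removed["reason_y"]).all()
            pos = {p.marker_id: p.snp_position for p in placed}
            kept = fx.truth[fx.truth["expected"] == "kept"]
            assert all(pos[r.marker_id] == r.position for r in kept.itertuples())

    def test_counts_monotone_along_cascade(self):
        fx = generate_placement_fixture(60, flank_len=15, seed=4)
        surviving = filter_alignments(fx.alignments)
        assert len(surviving) <= len(fx.alignments)
        placed, _ = consistency_filter(
            surviving, reference_lookup_from_dict(fx.reference)
        )
        deduped, _ = dedupe_placements(placed)
        n_markers = len(fx.markers)
        assert len({r.marker_id for r in surviving}) <= n_markers
        assert len(placed) <= len({r.marker_id for r in surviving})
        assert len(deduped) <= len(placed)

    def test_rejection_reasons_partition_rejected_set(self):
        fx = generate_placement_fixture(80, flank_len=15, seed=8)
        _, report = place_markers(
            fx.markers, fx.alignments, reference_lookup_from_dict(fx.reference)
        )
        rejected = report[report["status"] == "rejected"]
        assert (rejected["reason"] != "").all()
        assert len(report) == len(fx.markers)


class TestTally:
    def test_hand_count_and_shares(self):
        placed = [PlacedMarker(f"m{i}", "1A", i + 1) for i in range(2)] + [
            PlacedMarker(f"n{i}", "1B", i + 1) for i in range(3)
        ]
        t = tally_by_chromosome(placed)
        assert t.loc["All", "Total"] == 5
        assert t.loc["Share%", "A"] == pytest.approx(40.0)
        assert t.loc["Share%", "B"] == pytest.approx(60.0)

    def test_empty_input_all_zero(self):
        t = tally_by_chromosome([])
        assert t.loc["All", "Total"] == 0 and t.loc["Total", "Total"] == 0

    def test_unparseable_labels_counted_unknown(self):
        t = tally_by_chromosome([PlacedMarker("m", "scaffold_17", 5)])
        assert t.loc["Unknown", "Total"] == 1

    def test_published_map_distribution(self):
        # per-chromosome counts of uniquely placed 15K-array markers on
        # the bread-wheat reference assembly
        table = {
            ("1", "A"): 451, ("1", "B"): 580, ("1", "D"): 270,
            ("2", "A"): 480, ("2", "B"): 710, ("2", "D"): 289,
            ("3", "A"): 415, ("3", "B"): 556, ("3", "D"): 142,
            ("4", "A"): 287, ("4", "B"): 258, ("4", "D"): 62,
            ("5", "A"): 508, ("5", "B"): 595, ("5", "D"): 186,
            ("6", "A"): 485, ("6", "B"): 530, ("6", "D"): 169,
            ("7", "A"): 546, ("7", "B"): 485, ("7", "D"): 144,
        }
        placed = []
        i = 0
        for (grp, sub), count in table.items():
            for _ in range(count):
                placed.append(PlacedMarker(f"m{i}", f"{grp}{sub}", i + 1))
                i += 1
        for _ in range(73):
            placed.append(PlacedMarker(f"m{i}", "Un", i + 1))
            i += 1
        t = tally_by_chromosome(placed)
        assert t.loc["All", "Total"] == 8221
        assert t.loc["Total", "A"] == 3172
        assert t.loc["Total", "B"] == 3714
        assert t.loc["Total", "D"] == 1262
        assert t.loc["Total", "Total"] == 8148
        assert t.loc["Unknown", "Total"] == 73
        assert round(t.loc["Share%", "A"]) == 39
        assert round(t.loc["Share%", "B"]) == 45
        assert round(t.loc["Share%", "D"]) == 15


class TestAlignmentIo:
    def test_sam_round_trip(self, tmp_path):
        fx = generate_placement_fixture(12, flank_len=10, seed=2)
        p = tmp_path / "aln.sam"
        write_alignments_sam(fx.alignments, p, fx.reference)
        back = read_alignments_sam(p)
        orig = [(r.read_id, r.chromosome, r.start, r.end, r.strand, r.mapq, r.is_secondary)
                for r in fx.alignments]
        got = [(r.read_id, r.chromosome, r.start, r.end, r.strand, r.mapq, r.is_secondary)
               for r in back]
        assert got == orig

    def test_bed_parsing_converts_coordinates(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t99\t119\tm/1\t60\t+\t20M\n")
        (rec,) = read_alignments_bed(p)
        assert (rec.start, rec.end) == (100, 119)

    def test_placements_bed_is_zero_based_half_open(self, tmp_path):
        p = tmp_path / "out.bed"
        write_placements_bed([PlacedMarker("m", "chr1", 120)], p)
        assert p.read_text() == "chr1\t119\t120\tm\t0\t+\n"
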