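"""Placement of SNP-array probe sequences onto a reference genome.

An array marker is described by its context sequence with the polymorphic
site in bracket notation (``ACGT[A/G]ACGT``).  The sequence is split at
the site into a pseudo paired-end read pair (the right flank reverse
complemented), the pair is aligned externally (e.g. with ``bwa mem``),
and the alignments are then screened by a consistency filter: both mates
must map uniquely to the same chromosome in convergent orientation with
an inner gap of exactly one reference base — that base is the SNP — and
the reference base there must not be 'N'.  Markers landing on the same
physical position are collapsed, keeping the first in manifest order.

Running the aligner is out of scope; this module consumes parsed SAM or
BED records.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from .matrix import MarkerRecord

__all__ = [
    "AlignmentRecord",
    "PlacedMarker",
    "split_context_sequence",
    "filter_alignments",
    "consistency_filter",
    "dedupe_placements",
    "tally_by_chromosome",
    "place_markers",
    "read_alignments_sam",
    "read_alignments_bed",
    "write_alignments_sam",
    "write_placements_bed",
    "reference_lookup_from_fasta",
]

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class AlignmentRecord:
    """One alignment of a pseudo mate read (1-based inclusive coordinates)."""

    read_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    mapq: int
    cigar: str = ""
    is_secondary: bool = False
    is_mapped: bool = True

    def __post_init__(self) -> None:
        if self.is_mapped and self.start > self.end:
            raise ValueError(f"{self.read_id}: start > end")
        if self.mapq < 0:
            raise ValueError(f"{self.read_id}: negative MAPQ")
        if self.strand not in "+-":
            raise ValueError(f"{self.read_id}: strand must be + or -")

    @property
    def marker_id(self) -> str:
        return re.sub(r"/[12]$", "", self.read_id)

    @property
    def mate(self) -> int:
        m = re.search(r"/([12])$", self.read_id)
        if not m:
            raise ValueError(f"read id {self.read_id!r} lacks /1 or /2 mate tag")
        return int(m.group(1))


@dataclass
class PlacedMarker:
    """A marker assigned a unique chromosome and 1-based SNP coordinate."""

    marker_id: str
    chromosome: str
    snp_position: int
    alleles: tuple | None = None
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.snp_position < 1:
            raise ValueError("snp_position must be >= 1")
        if self.alleles is not None and self.alleles[0] == self.alleles[1]:
            raise ValueError("alleles must be distinct")


def split_context_sequence(marker: MarkerRecord) -> tuple[str, str, tuple]:
    """Split a context sequence into a pseudo read pair.

    Returns ``(left_read, right_read, alleles)`` where ``left_read`` is
    the flank before the bracket site and ``right_read`` is the reverse
    complement of the flank after it, so the two reads face each other
    across the SNP like a proper paired-end fragment.
    """
    left, alleles, right = marker.parse()
    return left, revcomp(right), alleles


def filter_alignments(
    records: Iterable[AlignmentRecord], mapq_min: int = 20
) -> list:
    """Drop unmapped reads, secondary alignments, and MAPQ < `mapq_min`.

    The threshold is inclusive: MAPQ exactly equal to `mapq_min` is kept.
    """
    return [
        r
        for r in records
        if r.is_mapped and not r.is_secondary and r.mapq >= mapq_min
    ]


_FULL_MATCH_CIGAR = re.compile(r"^(\d+)(?:M|=)$")


def _cigar_full_match(rec: AlignmentRecord) -> bool:
    """Eligible alignments must match the flank end-to-end without gaps."""
    if not rec.cigar or rec.cigar == "*":
        return True  # no CIGAR carried (e.g. minimal BED): assume ungapped
    m = _FULL_MATCH_CIGAR.match(rec.cigar)
    return bool(m) and int(m.group(1)) == rec.end - rec.start + 1


def consistency_filter(
    records: Iterable[AlignmentRecord],
    reference_base_lookup: Callable[[str, int], str],
    alleles: Mapping[str, tuple] | None = None,
    marker_ids: Sequence[str] | None = None,
) -> tuple[list, dict]:
    """Resolve each marker's read pair to a unique SNP position.

    A marker is placed iff, after quality filtering, each mate has
    exactly one eligible (end-to-end matched) alignment, the two
    alignments sit on the same chromosome in convergent orientation
    exactly one reference nucleotide apart, and the reference base in
    that gap is not 'N'.  The gap base's coordinate is the SNP position.

    Parameters
    ----------
    records
        Alignments that already passed :func:`filter_alignments`.
    reference_base_lookup
        ``(chromosome, 1-based position) -> base``.
    alleles
        Optional ``marker_id -> (x, y)`` from the manifest; for a marker
        placed on the reference minus strand the alleles are complemented.
    marker_ids
        Optional full marker universe so markers with no surviving
        alignment at all are reported (reason ``mate``).

    Returns
    -------
    (placed, rejected)
        Placed markers in first-seen record order, and a dict mapping
        each rejected marker to exactly one primary reason among
        ``mate``, ``cigar``, ``ambiguous``, ``orientation``, ``gap``,
        ``N-site``, ``lookup``.
    """
    by_marker: dict[str, dict[int, list]] = defaultdict(lambda: {1: [], 2: []})
    order: list[str] = []
    for rec in records:
        mid = rec.marker_id
        if mid not in by_marker:
            order.append(mid)
        by_marker[mid][rec.mate].append(rec)
    if marker_ids is not None:
        for mid in marker_ids:
            if mid not in by_marker:
                by_marker[mid]  # creates empty entry
                order.append(mid)

    placed: list[PlacedMarker] = []
    rejected: dict[str, str] = {}
    for mid in order:
        mates = by_marker[mid]
        reason = None
        if not mates[1] or not mates[2]:
            reason = "mate"
        else:
            eligible = {t: [r for r in mates[t] if _cigar_full_match(r)] for t in (1, 2)}
            if not eligible[1] or not eligible[2]:
                reason = "cigar"
            elif len(eligible[1]) > 1 or len(eligible[2]) > 1:
                reason = "ambiguous"
        if reason:
            rejected[mid] = reason
            continue

        a, b = eligible[1][0], eligible[2][0]
        if a.chromosome != b.chromosome or a.strand == b.strand:
            rejected[mid] = "orientation"
            continue
        fwd, rev = (a, b) if a.strand == "+" else (b, a)
        if fwd.start > rev.start:
            rejected[mid] = "orientation"
            continue
        if rev.start - fwd.end != 2:  # inner gap must be exactly one base
            rejected[mid] = "gap"
            continue
        pos = fwd.end + 1
        try:
            base = reference_base_lookup(fwd.chromosome, pos).upper()
        except Exception:
            rejected[mid] = "lookup"
            continue
        if base == "N":
            rejected[mid] = "N-site"
            continue

        strand = "+" if a.strand == "+" else "-"  # mate 1 carries the left flank
        pair = None
        if alleles is not None and mid in alleles:
            x, y = alleles[mid]
            if strand == "-":
                x, y = x.translate(_COMP), y.translate(_COMP)
            pair = (x, y)
        placed.append(
            PlacedMarker(
                marker_id=mid, chromosome=fwd.chromosome, snp_position=pos,
                alleles=pair, strand=strand,
            )
        )
    return placed, rejected


def dedupe_placements(
    placed: Sequence[PlacedMarker], input_order: Sequence[str] | None = None
) -> tuple[list, dict]:
    """Collapse markers sharing a physical position, keeping the first.

    Ties are resolved by `input_order` (the manifest order) when given,
    otherwise by position in `placed`.  Returns the retained placements
    and a dict mapping each removed marker to the id of the marker kept
    at its position.
    """
    items = list(placed)
    if input_order is not None:
        rank = {mid: i for i, mid in enumerate(input_order)}
        items.sort(key=lambda p: rank.get(p.marker_id, len(rank)))
    kept: dict[tuple, PlacedMarker] = {}
    removed: dict[str, str] = {}
    for p in items:
        key = (p.chromosome, p.snp_position)
        if key in kept:
            removed[p.marker_id] = kept[key].marker_id
        else:
            kept[key] = p
    return list(kept.values()), removed


_CHROM_RE = re.compile(r"^(?:chr)?([1-7])([ABD])$", re.IGNORECASE)

SUBGENOMES = ("A", "B", "D")


def tally_by_chromosome(placed: Sequence[PlacedMarker]) -> pd.DataFrame:
    """Count placements per wheat chromosome and sub-genome.

    Chromosome labels are expected in the 1A..7D convention (an optional
    ``chr`` prefix is tolerated); anything else is counted under
    ``Unknown``.  The returned table has one row per chromosome group
    1..7 plus ``Total``, ``Unknown`` and ``All`` rows, sub-genome columns
    A/B/D plus a ``Total`` column, and a final ``Share%`` row giving each
    sub-genome's percentage of all placed markers.
    """
    counts = {g: {s: 0 for s in SUBGENOMES} for g in range(1, 8)}
    unknown = 0
    for p in placed:
        m = _CHROM_RE.match(str(p.chromosome))
        if m:
            counts[int(m.group(1))][m.group(2).upper()] += 1
        else:
            unknown += 1
    grand_total = len(placed)
    rows = {}
    for g in range(1, 8):
        row = {s: counts[g][s] for s in SUBGENOMES}
        row["Total"] = sum(row.values())
        rows[str(g)] = row
    totals = {s: sum(counts[g][s] for g in range(1, 8)) for s in SUBGENOMES}
    totals["Total"] = sum(totals.values())
    rows["Total"] = totals
    rows["Unknown"] = {"A": 0, "B": 0, "D": 0, "Total": unknown}
    rows["All"] = {"A": 0, "B": 0, "D": 0, "Total": grand_total}
    share = {
        s: (100.0 * totals[s] / grand_total if grand_total else 0.0)
        for s in SUBGENOMES
    }
    share["Total"] = sum(share.values())
    rows["Share%"] = share
    return pd.DataFrame.from_dict(rows, orient="index")[list(SUBGENOMES) + ["Total"]]


def place_markers(
    markers: Sequence[MarkerRecord],
    records: Iterable[AlignmentRecord],
    reference_base_lookup: Callable[[str, int], str],
    mapq_min: int = 20,
) -> tuple[list, pd.DataFrame]:
    """Full placement cascade: quality filter, consistency filter, dedup.

    Returns the deduplicated placements plus a per-marker report with
    columns ``marker_id``, ``status`` (``placed``/``rejected``) and
    ``reason`` (empty when placed; ``duplicate`` when removed by the
    same-position rule).
    """
    manifest_ids = [m.marker_id for m in markers]
    allele_map = {m.marker_id: m.parse()[1] for m in markers}
    surviving = filter_alignments(records, mapq_min=mapq_min)
    placed, rejected = consistency_filter(
        surviving, reference_base_lookup, alleles=allele_map, marker_ids=manifest_ids
    )
    deduped, dup_removed = dedupe_placements(placed, input_order=manifest_ids)
    report_rows = []
    placed_ids = {p.marker_id for p in deduped}
    for mid in manifest_ids:
        if mid in placed_ids:
            report_rows.append((mid, "placed", ""))
        elif mid in dup_removed:
            report_rows.append((mid, "rejected", "duplicate"))
        else:
            report_rows.append((mid, "rejected", rejected.get(mid, "mate")))
    report = pd.DataFrame(report_rows, columns=["marker_id", "status", "reason"])
    return deduped, report


# ---------------------------------------------------------------------------
# I/O helpers
# ---------------------------------------------------------------------------


def read_alignments_sam(path) -> list:
    """Parse a SAM file's mandatory fields into :class:`AlignmentRecord` s."""
    import pysam

    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                out.append(
                    AlignmentRecord(
                        read_id=aln.query_name, chromosome="*", start=1, end=1,
                        strand="+", mapq=aln.mapping_quality, cigar="*",
                        is_secondary=aln.is_secondary, is_mapped=False,
                    )
                )
                continue
            out.append(
                AlignmentRecord(
                    read_id=aln.query_name,
                    chromosome=aln.reference_name,
                    start=aln.reference_start + 1,
                    end=aln.reference_end,  # pysam end is 0-based exclusive == 1-based inclusive
                    strand="-" if aln.is_reverse else "+",
                    mapq=aln.mapping_quality,
                    cigar=aln.cigarstring or "",
                    is_secondary=aln.is_secondary,
                )
            )
    return out


def write_alignments_sam(
    records: Sequence[AlignmentRecord], path, reference: Mapping[str, str]
) -> None:
    """Write records as a minimal SAM file (used for fixtures and exports)."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": name, "LN": len(seq)} for name, seq in reference.items()],
    }
    ref_index = {name: i for i, name in enumerate(reference)}
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for rec in records:
            a = pysam.AlignedSegment(fh.header)
            a.query_name = rec.read_id
            flag = 0
            if not rec.is_mapped:
                flag |= 4
            if rec.strand == "-":
                flag |= 16
            if rec.is_secondary:
                flag |= 256
            a.flag = flag
            a.mapping_quality = rec.mapq
            if rec.is_mapped:
                a.reference_id = ref_index[rec.chromosome]
                a.reference_start = rec.start - 1
                length = rec.end - rec.start + 1
                a.cigarstring = rec.cigar if rec.cigar else f"{length}M"
                seq = reference[rec.chromosome][rec.start - 1 : rec.end]
                a.query_sequence = revcomp(seq) if rec.strand == "-" else seq
            else:
                a.reference_id = -1
                a.reference_start = -1
            fh.write(a)


def read_alignments_bed(path) -> list:
    """Parse BED6(+CIGAR in column 7) alignment intervals.

    BED is 0-based half-open; records are converted to the 1-based
    inclusive convention used internally.  Unmapped reads do not appear
    in BED output, so every parsed record is mapped and primary.
    """
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{ln}: expected >= 6 BED columns")
            chrom, start, end, name, score, strand = fields[:6]
            cigar = fields[6] if len(fields) > 6 else ""
            out.append(
                AlignmentRecord(
                    read_id=name, chromosome=chrom, start=int(start) + 1,
                    end=int(end), strand=strand, mapq=int(score), cigar=cigar,
                )
            )
    return out


def write_placements_bed(placed: Sequence[PlacedMarker], path, mapq: int = 0) -> None:
    """Write placed SNPs as BED (0-based half-open single-base intervals)."""
    with open(path, "w") as fh:
        for p in placed:
            fh.write(
                f"{p.chromosome}\t{p.snp_position - 1}\t{p.snp_position}\t"
                f"{p.marker_id}\t{mapq}\t{p.strand}\n"
            )


def reference_lookup_from_fasta(path) -> Callable[[str, int], str]:
    """Return a ``(chromosome, 1-based position) -> base`` FASTA lookup."""
    import pysam

    ref = pysam.FastaFile(str(path))

    def lookup(chromosome: str, position: int) -> str:
        base = ref.fetch(chromosome, position - 1, position)
        if len(base) != 1:
            raise IndexError(f"{chromosome}:{position} outside reference")
        return base

    return lookup


def reference_lookup_from_dict(reference: Mapping[str, str]) -> Callable[[str, int], str]:
    """In-memory variant of :func:`reference_lookup_from_fasta`."""

    def lookup(chromosome: str, position: int) -> str:
        seq = reference[chromosome]
        if not (1 <= position <= len(seq)):
            raise IndexError(f"{chromosome}:{position} outside reference")
        return seq[position - 1]

    return lookup
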