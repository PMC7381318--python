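"""Synthetic genotype data with controlled population structure.

The generator emulates a genebank-style panel: several collections of a
selfing crop that diverged from a common ancestral pool.  Population
structure follows the Balding-Nichols model: each marker has an ancestral
reference-allele frequency ``p``, and every collection draws its own
frequency from ``Beta(p(1-F)/F, (1-p)(1-F)/F)``, whose mean is ``p`` and
whose differentiation between collections equals ``F``.  Genotypes are
then sampled per accession from the collection frequency, with an
inbreeding coefficient that depresses heterozygosity to the low levels
typical of inbred cereal lines.

The defaults mirror a winter-wheat diversity panel of 890 accessions in
five collections of sizes 92/284/40/220/254.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import GenotypeMatrix, MarkerRecord
from .placement import AlignmentRecord

__all__ = [
    "SyntheticConfig",
    "WHEAT_PANEL_SIZES",
    "generate_structured_population",
    "inject_missingness",
    "generate_placement_fixture",
    "PlacementFixture",
]

#: collection sizes of the emulated wheat panel (total 890)
WHEAT_PANEL_SIZES = (92, 284, 40, 220, 254)


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the structured-population generator.

    Parameters
    ----------
    collection_sizes
        Number of accessions per collection; at least two accessions in
        total.
    n_markers
        Number of biallelic markers.
    divergence
        Balding-Nichols differentiation parameter F in [0, 1); expected
        Fst between collections.
    ancestral_freq_range
        Ancestral reference-allele frequencies are drawn uniformly from
        this open interval.
    missing_rate
        Probability that any individual call is set to missing.
    inbreeding
        Probability that a would-be heterozygote is collapsed to a
        homozygote (Wright's F_IS); 0.9 emulates a selfing crop.
    seed
        Master seed; identical config and seed give bit-identical output.
    """

    collection_sizes: tuple = WHEAT_PANEL_SIZES
    n_markers: int = 1000
    divergence: float = 0.10
    ancestral_freq_range: tuple = (0.1, 0.9)
    missing_rate: float = 0.0
    inbreeding: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        sizes = tuple(int(s) for s in self.collection_sizes)
        if any(s <= 0 for s in sizes):
            raise ValueError("collection sizes must be positive")
        if sum(sizes) < 2:
            raise ValueError("need at least 2 accessions in total")
        if self.n_markers < 1:
            raise ValueError("n_markers must be >= 1")
        if not (0.0 <= self.divergence < 1.0):
            raise ValueError("divergence F must lie in [0, 1)")
        lo, hi = self.ancestral_freq_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("ancestral_freq_range must satisfy 0 < low < high < 1")
        if not (0.0 <= self.missing_rate <= 1.0):
            raise ValueError("missing_rate must lie in [0, 1]")
        if not (0.0 <= self.inbreeding <= 1.0):
            raise ValueError("inbreeding must lie in [0, 1]")
        object.__setattr__(self, "collection_sizes", sizes)


def generate_structured_population(config: SyntheticConfig) -> GenotypeMatrix:
    """Draw a dosage matrix with collection labels under Balding-Nichols.

    All randomness flows from one seeded generator in a fixed order:
    ancestral frequencies, then collection frequencies, then genotypes,
    then missingness.
    """
    rng = np.random.default_rng(config.seed)
    sizes = config.collection_sizes
    n_coll = len(sizes)
    n = sum(sizes)
    m = config.n_markers
    F = config.divergence

    lo, hi = config.ancestral_freq_range
    p_anc = rng.uniform(lo, hi, size=m)

    if F == 0.0:
        # degenerate Beta limit: point mass at the ancestral frequency
        p_coll = np.broadcast_to(p_anc, (n_coll, m)).copy()
    else:
        c = (1.0 - F) / F
        p_coll = rng.beta(p_anc * c, (1.0 - p_anc) * c, size=(n_coll, m))
        # Beta draws can underflow to exactly 0/1; keep frequencies interior
        eps = 1e-12
        np.clip(p_coll, eps, 1.0 - eps, out=p_coll)

    calls = np.empty((n, m), dtype=float)
    row = 0
    f_is = config.inbreeding
    for c_idx, size in enumerate(sizes):
        p = p_coll[c_idx]
        # genotype class probabilities under HWE with inbreeding F_IS
        p_het = 2.0 * p * (1.0 - p) * (1.0 - f_is)
        p_hom_ref = p * p + f_is * p * (1.0 - p)
        u = rng.random(size=(size, m))
        g = np.where(u < p_hom_ref, 1.0, np.where(u < p_hom_ref + p_het, 0.5, 0.0))
        calls[row : row + size] = g
        row += size

    if config.missing_rate > 0:
        miss = rng.random(size=(n, m)) < config.missing_rate
        calls[miss] = np.nan

    accession_ids = []
    collections = []
    for c_idx, size in enumerate(sizes, start=1):
        for i in range(1, size + 1):
            accession_ids.append(f"C{c_idx}_{i:04d}")
            collections.append(f"collection{c_idx}")

    return GenotypeMatrix(
        accession_ids=accession_ids,
        marker_ids=[f"snp{j + 1:05d}" for j in range(m)],
        calls=calls,
        accession_meta=pd.DataFrame({"collection": collections}, index=accession_ids),
    )


def inject_missingness(matrix: GenotypeMatrix, rate: float, seed: int) -> GenotypeMatrix:
    """Return a copy with each call independently missing with probability `rate`."""
    if not (0.0 <= rate <= 1.0):
        raise ValueError("rate must lie in [0, 1]")
    out = matrix.copy()
    if rate > 0:
        rng = np.random.default_rng(seed)
        miss = rng.random(size=out.calls.shape) < rate
        out.calls[miss] = np.nan
    return out


# ---------------------------------------------------------------------------
# placement fixtures
# ---------------------------------------------------------------------------

_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


@dataclass
class PlacementFixture:
    """A toy reference plus marker manifest, alignments, and ground truth."""

    markers: list  # list[MarkerRecord]
    reference: dict  # chromosome -> sequence string
    alignments: list  # list[AlignmentRecord]
    truth: pd.DataFrame  # marker_id, expected ("kept"/"removed"), reason, chromosome, position


# kinds of deliberately broken markers, cycled deterministically
_BREAK_KINDS = (
    "clean",
    "clean",
    "clean",
    "missing_mate",
    "gap2",
    "n_site",
    "low_mapq",
    "duplicate_position",
    "secondary_extra",
    "clean",
)


def generate_placement_fixture(
    n_markers: int, flank_len: int = 20, seed: int = 0
) -> PlacementFixture:
    """Build a reference with embedded markers and matching mate-pair alignments.

    Besides clean cases the fixture plants the failure modes the
    consistency filter must catch: a missing mate, a 2-nt inner gap, an
    'N' at the SNP site, a sub-threshold MAPQ, a duplicated physical
    position, and a spurious secondary alignment.  The returned truth
    table states, per marker, whether it must survive the filter cascade
    and why not otherwise.
    """
    if flank_len < 1:
        raise ValueError("flank_len must be >= 1")
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    chrom = "chr1"
    slot = 3 * flank_len + 10  # per-marker stride; markers never overlap
    ref_len = n_markers * slot + slot
    ref = rng.choice(bases, size=ref_len)

    markers: list[MarkerRecord] = []
    alignments: list[AlignmentRecord] = []
    truth_rows = []
    dup_target: tuple[int, str] | None = None  # (snp_pos, allele pair) of previous clean marker

    for i in range(n_markers):
        kind = _BREAK_KINDS[i % len(_BREAK_KINDS)]
        mid = f"marker{i + 1:04d}"
        snp_pos = i * slot + flank_len + 5  # 1-based SNP coordinate

        if kind == "duplicate_position" and dup_target is not None:
            snp_pos = dup_target[0]
        ref_allele = str(ref[snp_pos - 1])
        alt = rng.choice([b for b in "ACGT" if b != ref_allele])
        if kind == "n_site":
            ref[snp_pos - 1] = "N"

        left = "".join(ref[snp_pos - 1 - flank_len : snp_pos - 1])
        right = "".join(ref[snp_pos : snp_pos + flank_len])
        if kind == "n_site":
            # context keeps real flanks; only the reference N is broken
            pass
        markers.append(
            MarkerRecord(mid, f"{left}[{ref_allele}/{alt}]{right}", origin="fixture")
        )

        mapq = 60 if kind != "low_mapq" else 5
        left_start = snp_pos - flank_len
        right_start = snp_pos + 1
        if kind == "gap2":
            right_start += 1  # inner gap becomes 2 nt
        cig = f"{flank_len}M"
        a1 = AlignmentRecord(
            read_id=f"{mid}/1", chromosome=chrom, start=left_start,
            end=left_start + flank_len - 1, strand="+", mapq=mapq, cigar=cig,
        )
        a2 = AlignmentRecord(
            read_id=f"{mid}/2", chromosome=chrom, start=right_start,
            end=right_start + flank_len - 1, strand="-", mapq=mapq, cigar=cig,
        )
        alignments.append(a1)
        if kind != "missing_mate":
            alignments.append(a2)
        if kind == "secondary_extra":
            alignments.append(
                AlignmentRecord(
                    read_id=f"{mid}/1", chromosome=chrom, start=left_start + slot // 2,
                    end=left_start + slot // 2 + flank_len - 1, strand="+",
                    mapq=0, cigar=cig, is_secondary=True,
                )
            )

        if kind in ("clean", "secondary_extra"):
            expected, reason = "kept", ""
            dup_target = (snp_pos, ref_allele)
        elif kind == "duplicate_position":
            if dup_target is None:
                expected, reason = "kept", ""
                dup_target = (snp_pos, ref_allele)
            else:
                expected, reason = "removed", "duplicate"
        else:
            expected = "removed"
            reason = {
                "missing_mate": "mate",
                "gap2": "gap",
                "n_site": "N-site",
                "low_mapq": "mate",  # both mates fall below MAPQ -> no mapped mate survives
            }[kind]
        truth_rows.append(
            {
                "marker_id": mid,
                "expected": expected,
                "reason": reason,
                "chromosome": chrom,
                "position": snp_pos if expected == "kept" else -1,
            }
        )

    return PlacementFixture(
        markers=markers,
        reference={chrom: "".join(ref)},
        alignments=alignments,
        truth=pd.DataFrame(truth_rows),
    )
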