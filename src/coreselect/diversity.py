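"""Evaluation statistics for core sets.

Two distance aggregations introduced for core-collection evaluation:

average entry-to-nearest-entry (E-NE)
    mean, over selected entries, of each entry's distance to its closest
    other entry; high values mean a maximally spread (CC-X) core.

average accession-to-nearest-entry (A-NE)
    mean, over *all* accessions, of the distance to the closest entry
    (entries contribute zero); low values mean the core uniformly
    represents the collection (CC-I).

Plus three allele-frequency statistics over the entries' pooled
genotypes: Shannon's diversity index (entropy of the pooled allele
frequencies across all loci jointly, natural log), expected
heterozygosity (mean per-locus ``1 - sum_a p_a^2``), and allele
coverage (fraction of the full collection's observed alleles retained).
Heterozygous calls contribute dosage-weighted allele counts (one of
each allele).
"""

from __future__ import annotations

import numpy as np
from scipy.special import xlogy

from .matrix import CoreSet, DistanceMatrix, GenotypeMatrix

__all__ = [
    "average_entry_to_nearest_entry",
    "average_accession_to_nearest_entry",
    "shannon_diversity",
    "expected_heterozygosity",
    "allele_coverage",
    "evaluate_core",
]


def _entry_index(core: CoreSet, ids) -> np.ndarray:
    lookup = {a: i for i, a in enumerate(ids)}
    try:
        return np.array([lookup[e] for e in core.entry_ids], dtype=int)
    except KeyError as e:
        raise ValueError(f"core entry {e.args[0]!r} not in the accession universe") from None


def average_entry_to_nearest_entry(core: CoreSet, d: DistanceMatrix) -> float:
    """Mean distance from each entry to its closest other entry."""
    if core.k < 2:
        raise ValueError("E-NE is undefined for cores with fewer than 2 entries")
    idx = _entry_index(core, d.accession_ids)
    sub = d.values[np.ix_(idx, idx)].copy()
    np.fill_diagonal(sub, np.inf)
    return float(sub.min(axis=1).mean())


def average_accession_to_nearest_entry(core: CoreSet, d: DistanceMatrix) -> float:
    """Mean distance from every accession to its closest entry (entries count 0)."""
    idx = _entry_index(core, d.accession_ids)
    return float(d.values[:, idx].min(axis=1).mean())


def _pooled_ref_counts(core: CoreSet, matrix: GenotypeMatrix) -> np.ndarray:
    idx = _entry_index(core, matrix.accession_ids)
    sub = matrix.calls[idx]
    if np.isnan(sub).any():
        raise ValueError("entries carry missing calls; impute first")
    return 2.0 * sub.sum(axis=0)  # reference-allele count per locus, of 2k total


def shannon_diversity(core: CoreSet, matrix: GenotypeMatrix) -> float:
    """Entropy of the pooled allele frequencies over all loci jointly.

    With ``f_la`` the count of allele ``a`` at locus ``l`` divided by the
    grand total ``2 * k * m``, returns ``H = -sum f_la * ln(f_la)``; the
    maximum ``ln(2m)`` is reached when every allele of every locus is
    equally frequent in the pool.
    """
    ref = _pooled_ref_counts(core, matrix)
    total = 2.0 * core.k * matrix.n_markers
    f = np.concatenate([ref, 2.0 * core.k - ref]) / total
    return float(-xlogy(f, f).sum())


def expected_heterozygosity(core: CoreSet, matrix: GenotypeMatrix) -> float:
    """Mean per-locus gene diversity ``1 - p^2 - (1-p)^2`` among entries."""
    ref = _pooled_ref_counts(core, matrix)
    p = ref / (2.0 * core.k)
    return float((1.0 - p**2 - (1.0 - p) ** 2).mean())


def allele_coverage(core: CoreSet, matrix: GenotypeMatrix) -> float:
    """Fraction of the full collection's observed alleles present in the core."""
    if np.isnan(matrix.calls).any():
        raise ValueError("allele coverage requires complete data")
    full_ref = matrix.calls.sum(axis=0)
    n = matrix.n_accessions
    full_present = np.concatenate([full_ref > 0, full_ref < n])
    core_ref = _pooled_ref_counts(core, matrix) / 2.0
    core_present = np.concatenate([core_ref > 0, core_ref < core.k])
    denom = int(full_present.sum())
    if denom == 0:
        return 1.0
    return float((core_present & full_present).sum() / denom)


def evaluate_core(
    core: CoreSet,
    d: DistanceMatrix | None = None,
    matrix: GenotypeMatrix | None = None,
) -> dict:
    """All applicable statistics for one core as a flat dict."""
    out: dict[str, float] = {}
    if d is not None:
        if core.k >= 2:
            out["ENE"] = average_entry_to_nearest_entry(core, d)
        out["ANE"] = average_accession_to_nearest_entry(core, d)
    if matrix is not None:
        out["SD"] = shannon_diversity(core, matrix)
        out["EH"] = expected_heterozygosity(core, matrix)
        out["AC"] = allele_coverage(core, matrix)
    return out
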