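"""Marker quality-control cascade and perfect-LD haplotype collapse.

The cascade runs in a fixed order: (1) remove markers with too much
missing data, monomorphic markers, and exact duplicates; (2) impute the
remaining missing calls; (3) filter on minor allele frequency and
heterozygous-call fraction.  Boundary semantics follow genebank array
practice: missing fraction >= the threshold removes, MAF >= the
threshold keeps, heterozygosity <= the threshold keeps.

Imputation here is a deliberately simple seeded draw from each marker's
observed genotype-class frequencies; externally imputed matrices (e.g.
from a haplotype-aware imputer) can be supplied instead through the
normal readers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import GenotypeMatrix

__all__ = [
    "QcReport",
    "filter_pre_imputation",
    "impute_naive",
    "filter_post_imputation",
    "collapse_perfect_ld",
    "run_qc",
]


@dataclass
class QcReport:
    """Per-stage accounting of the filter cascade."""

    stages: list = field(default_factory=list)  # (stage, n_in, n_removed, n_retained)
    removal_reason: dict = field(default_factory=dict)  # marker_id -> reason
    thresholds: dict = field(default_factory=dict)

    def add_stage(self, name: str, n_in: int, removed_ids: list, reason: str) -> None:
        self.stages.append((name, n_in, len(removed_ids), n_in - len(removed_ids)))
        for mid in removed_ids:
            self.removal_reason[mid] = reason

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages, columns=["stage", "input", "removed", "retained"])

    def check_balance(self) -> None:
        for name, n_in, n_rm, n_keep in self.stages:
            assert n_in == n_rm + n_keep, f"stage {name} does not balance"


def filter_pre_imputation(
    matrix: GenotypeMatrix, max_missing: float = 0.30, report: QcReport | None = None
) -> tuple[GenotypeMatrix, QcReport]:
    """Remove high-missingness, monomorphic, and duplicate markers.

    A marker is removed when its missing fraction is greater than or
    equal to `max_missing`, when all its non-missing calls are equal
    (heterozygote-only markers count as polymorphic: both alleles are
    observed), or when its full call vector (including the missing
    pattern) duplicates an earlier marker's.
    """
    if matrix.n_markers == 0 or matrix.n_accessions == 0:
        raise ValueError("empty genotype matrix")
    report = report or QcReport()
    report.thresholds["max_missing"] = max_missing
    calls = matrix.calls
    n = matrix.n_accessions

    miss_frac = np.isnan(calls).mean(axis=0)
    drop_missing = miss_frac >= max_missing
    report.add_stage(
        "missing",
        matrix.n_markers,
        [matrix.marker_ids[j] for j in np.nonzero(drop_missing)[0]],
        "missing",
    )
    keep = ~drop_missing

    # monomorphic over non-missing calls (all observed calls identical and
    # homozygous, or no observed calls at all)
    with np.errstate(invalid="ignore"):
        mn = np.nanmin(np.where(np.isnan(calls), np.inf, calls), axis=0)
        mx = np.nanmax(np.where(np.isnan(calls), -np.inf, calls), axis=0)
    n_obs = (~np.isnan(calls)).sum(axis=0)
    mono = keep & ((n_obs == 0) | ((mn == mx) & (mn != 0.5)))
    report.add_stage(
        "monomorphic",
        int(keep.sum()),
        [matrix.marker_ids[j] for j in np.nonzero(mono)[0]],
        "monomorphic",
    )
    keep &= ~mono

    # duplicates: identical call vectors including missingness pattern
    seen: dict[bytes, int] = {}
    dup_ids = []
    dup_mask = np.zeros(matrix.n_markers, dtype=bool)
    coded = np.where(np.isnan(calls), -1.0, calls)
    for j in np.nonzero(keep)[0]:
        key = coded[:, j].tobytes()
        if key in seen:
            dup_ids.append(matrix.marker_ids[j])
            dup_mask[j] = True
        else:
            seen[key] = j
    report.add_stage("duplicate", int(keep.sum()), dup_ids, "duplicate")
    keep &= ~dup_mask

    return matrix.take_markers(np.nonzero(keep)[0]), report


def impute_naive(matrix: GenotypeMatrix, seed: int) -> GenotypeMatrix:
    """Fill missing calls by seeded draws from observed per-marker genotype frequencies."""
    out = matrix.copy()
    calls = out.calls
    miss = np.isnan(calls)
    if not miss.any():
        return out
    rng = np.random.default_rng(seed)
    for j in np.nonzero(miss.any(axis=0))[0]:
        col = calls[:, j]
        obs = col[~np.isnan(col)]
        if obs.size == 0:
            raise ValueError(
                f"marker {out.marker_ids[j]!r} is fully missing; "
                "run filter_pre_imputation first"
            )
        classes, counts = np.unique(obs, return_counts=True)
        probs = counts / counts.sum()
        idx = np.isnan(col)
        col[idx] = rng.choice(classes, size=int(idx.sum()), p=probs)
    return out


def filter_post_imputation(
    matrix: GenotypeMatrix,
    maf_min: float = 0.05,
    het_max: float = 0.125,
    report: QcReport | None = None,
) -> tuple[GenotypeMatrix, QcReport]:
    """Keep markers with MAF >= `maf_min` and heterozygosity <= `het_max`.

    MAF is ``min(q, 1 - q)`` with ``q`` the mean dosage; heterozygosity
    is the fraction of calls equal to 0.5.  Requires complete data.
    """
    if matrix.has_missing():
        raise ValueError("matrix still has missing calls; impute or filter first")
    report = report or QcReport()
    report.thresholds.update({"maf_min": maf_min, "het_max": het_max})
    calls = matrix.calls
    q = calls.mean(axis=0)
    maf = np.minimum(q, 1.0 - q)
    drop_maf = maf < maf_min
    report.add_stage(
        "maf",
        matrix.n_markers,
        [matrix.marker_ids[j] for j in np.nonzero(drop_maf)[0]],
        "maf",
    )
    keep = ~drop_maf
    het = (calls == 0.5).mean(axis=0)
    drop_het = keep & (het > het_max)
    report.add_stage(
        "heterozygosity",
        int(keep.sum()),
        [matrix.marker_ids[j] for j in np.nonzero(drop_het)[0]],
        "heterozygosity",
    )
    keep &= ~drop_het
    return matrix.take_markers(np.nonzero(keep)[0]), report


def collapse_perfect_ld(matrix: GenotypeMatrix, keep: int = 1) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Collapse haplotype blocks of markers in perfect linkage disequilibrium.

    Two markers belong to one block when their call vectors are identical
    or exactly complementary (dosage ``d`` vs ``1 - d`` at every
    accession) — i.e. the same signal up to allele coding.  The first
    `keep` markers of each block (input order) are retained.  Returns
    the reduced matrix and a block table mapping every marker to its
    block representative and its retention status.
    """
    if matrix.has_missing():
        raise ValueError("collapse_perfect_ld requires complete data")
    if keep not in (1, 2):
        raise ValueError("keep must be 1 or 2")
    calls = matrix.calls
    blocks: dict[bytes, list] = {}
    order: list[bytes] = []
    for j in range(matrix.n_markers):
        v = calls[:, j]
        key_f, key_r = v.tobytes(), (1.0 - v).tobytes()
        # canonical key: lexicographically smaller of the two codings
        key = min(key_f, key_r)
        if key not in blocks:
            blocks[key] = []
            order.append(key)
        blocks[key].append(j)

    keep_idx: list[int] = []
    rows = []
    for key in order:
        members = blocks[key]
        rep = matrix.marker_ids[members[0]]
        for rank, j in enumerate(members):
            retained = rank < keep
            if retained:
                keep_idx.append(j)
            rows.append(
                {
                    "marker_id": matrix.marker_ids[j],
                    "block_representative": rep,
                    "block_size": len(members),
                    "retained": retained,
                }
            )
    keep_idx.sort()
    table = pd.DataFrame(rows)
    return matrix.take_markers(keep_idx), table


def run_qc(
    matrix: GenotypeMatrix,
    max_missing: float = 0.30,
    maf_min: float = 0.05,
    het_max: float = 0.125,
    impute_seed: int | None = 0,
) -> tuple[GenotypeMatrix, QcReport]:
    """The full cascade: missing/mono/duplicate -> impute -> MAF/het.

    With ``impute_seed=None`` imputation is skipped; the post filters
    then operate on observed calls only and the output may retain
    missing values (pairwise-complete distance mode downstream).
    """
    filtered, report = filter_pre_imputation(matrix, max_missing=max_missing)
    if impute_seed is not None:
        filtered = impute_naive(filtered, seed=impute_seed)
        final, report2 = filter_post_imputation(filtered, maf_min=maf_min, het_max=het_max)
    else:
        final, report2 = _filter_post_observed(filtered, maf_min=maf_min, het_max=het_max)
    report.stages.extend(report2.stages)
    report.removal_reason.update(report2.removal_reason)
    report.thresholds.update(report2.thresholds)
    return final, report


def _filter_post_observed(
    matrix: GenotypeMatrix, maf_min: float, het_max: float
) -> tuple[GenotypeMatrix, QcReport]:
    """MAF/het filter over observed (non-missing) calls only."""
    report = QcReport()
    report.thresholds.update({"maf_min": maf_min, "het_max": het_max})
    calls = matrix.calls
    q = np.nanmean(calls, axis=0)
    maf = np.minimum(q, 1.0 - q)
    drop_maf = maf < maf_min
    report.add_stage(
        "maf", matrix.n_markers,
        [matrix.marker_ids[j] for j in np.nonzero(drop_maf)[0]], "maf",
    )
    keep = ~drop_maf
    n_obs = (~np.isnan(calls)).sum(axis=0)
    het = np.where(n_obs > 0, (calls == 0.5).sum(axis=0) / np.maximum(n_obs, 1), 0.0)
    drop_het = keep & (het > het_max)
    report.add_stage(
        "heterozygosity", int(keep.sum()),
        [matrix.marker_ids[j] for j in np.nonzero(drop_het)[0]], "heterozygosity",
    )
    keep &= ~drop_het
    return matrix.take_markers(np.nonzero(keep)[0]), report
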