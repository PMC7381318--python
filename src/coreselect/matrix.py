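"""Core in-memory containers for the pipeline.

Genotypes are stored as reference-allele dosage per individual: 1 for
homozygous reference, 0.5 for heterozygous, 0 for homozygous alternate,
``numpy.nan`` for a missing call.  This coding makes each call a
per-individual allele frequency, so genetic-distance and diversity
formulas operate on it directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "DistanceMatrix",
    "CoreSet",
    "MarkerRecord",
    "VALID_DOSAGES",
]

#: the only legal non-missing call values (reference-allele dosage)
VALID_DOSAGES = (0.0, 0.5, 1.0)


def _check_unique(ids: Sequence[str], what: str) -> list:
    ids = list(ids)
    seen = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what} id: {x!r}")
        seen.add(x)
    return ids


@dataclass
class GenotypeMatrix:
    """Accessions x biallelic markers dosage matrix.

    Parameters
    ----------
    accession_ids
        Unique accession labels, one per row of `calls`.
    marker_ids
        Unique marker labels, one per column of `calls`.
    calls
        ``(n_accessions, n_markers)`` float array with values in
        {0, 0.5, 1} or NaN for missing.
    marker_meta
        Optional per-marker metadata (e.g. ``chromosome``, ``position``),
        indexed by marker id.
    accession_meta
        Optional per-accession metadata (e.g. ``collection``), indexed by
        accession id.
    """

    accession_ids: list
    marker_ids: list
    calls: np.ndarray
    marker_meta: pd.DataFrame | None = None
    accession_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.accession_ids = _check_unique(self.accession_ids, "accession")
        self.marker_ids = _check_unique(self.marker_ids, "marker")
        calls = np.asarray(self.calls, dtype=float)
        if calls.ndim != 2:
            raise ValueError("calls must be a 2-D array")
        if calls.shape != (len(self.accession_ids), len(self.marker_ids)):
            raise ValueError(
                f"calls shape {calls.shape} does not match "
                f"{len(self.accession_ids)} accessions x {len(self.marker_ids)} markers"
            )
        finite = calls[~np.isnan(calls)]
        bad = ~np.isin(finite, VALID_DOSAGES)
        if bad.any():
            raise ValueError(
                f"calls contain {int(bad.sum())} values outside {{0, 0.5, 1, NaN}}"
            )
        self.calls = calls

    # -- basic geometry -------------------------------------------------
    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return self.calls.shape

    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.calls)

    def has_missing(self) -> bool:
        return bool(np.isnan(self.calls).any())

    # -- subsetting ------------------------------------------------------
    def take_markers(self, index: np.ndarray | Sequence[int]) -> "GenotypeMatrix":
        index = np.asarray(index, dtype=int)
        meta = None
        if self.marker_meta is not None:
            meta = self.marker_meta.iloc[index].copy()
        return GenotypeMatrix(
            accession_ids=list(self.accession_ids),
            marker_ids=[self.marker_ids[i] for i in index],
            calls=self.calls[:, index].copy(),
            marker_meta=meta,
            accession_meta=None if self.accession_meta is None else self.accession_meta.copy(),
        )

    def take_accessions(self, index: np.ndarray | Sequence[int]) -> "GenotypeMatrix":
        index = np.asarray(index, dtype=int)
        meta = None
        if self.accession_meta is not None:
            meta = self.accession_meta.iloc[index].copy()
        return GenotypeMatrix(
            accession_ids=[self.accession_ids[i] for i in index],
            marker_ids=list(self.marker_ids),
            calls=self.calls[index, :].copy(),
            marker_meta=None if self.marker_meta is None else self.marker_meta.copy(),
            accession_meta=meta,
        )

    def accession_index(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {a: i for i, a in enumerate(self.accession_ids)}
        try:
            return np.array([lookup[x] for x in ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"unknown accession id {e.args[0]!r}") from None

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            accession_ids=list(self.accession_ids),
            marker_ids=list(self.marker_ids),
            calls=self.calls.copy(),
            marker_meta=None if self.marker_meta is None else self.marker_meta.copy(),
            accession_meta=None if self.accession_meta is None else self.accession_meta.copy(),
        )

    def __eq__(self, other: object) -> bool:  # value equality, NaN == NaN
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.accession_ids == other.accession_ids
            and self.marker_ids == other.marker_ids
            and self.calls.shape == other.calls.shape
            and bool(
                np.all(
                    (self.calls == other.calls)
                    | (np.isnan(self.calls) & np.isnan(other.calls))
                )
            )
        )


@dataclass
class DistanceMatrix:
    """Symmetric accession-by-accession dissimilarity matrix in [0, 1]."""

    accession_ids: list
    values: np.ndarray
    metric: str = "other"

    _ATOL = 1e-9

    def __post_init__(self) -> None:
        self.accession_ids = _check_unique(self.accession_ids, "accession")
        v = np.asarray(self.values, dtype=float)
        n = len(self.accession_ids)
        if v.shape != (n, n):
            raise ValueError(f"distance matrix shape {v.shape} != ({n}, {n})")
        if not np.allclose(v, v.T, atol=self._ATOL, equal_nan=False):
            raise ValueError("distance matrix is not symmetric")
        if np.abs(np.diag(v)).max(initial=0.0) > self._ATOL:
            raise ValueError("distance matrix diagonal is not zero")
        if v.min(initial=0.0) < -self._ATOL or v.max(initial=0.0) > 1 + self._ATOL:
            raise ValueError("distance values must lie in [0, 1]")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.accession_ids)

    def submatrix(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {a: i for i, a in enumerate(self.accession_ids)}
        idx = np.array([lookup[x] for x in ids], dtype=int)
        return self.values[np.ix_(idx, idx)]


@dataclass
class CoreSet:
    """An ordered subset of accessions of fixed size k, with provenance."""

    entry_ids: list
    method: str = ""
    metric: str | None = None
    seed: int | None = None
    run_index: int | None = None

    def __post_init__(self) -> None:
        self.entry_ids = _check_unique(self.entry_ids, "entry")
        if len(self.entry_ids) < 1:
            raise ValueError("a core set needs at least one entry")

    @property
    def k(self) -> int:
        return len(self.entry_ids)

    def validate_against(self, universe: Sequence[str]) -> None:
        missing = set(self.entry_ids) - set(universe)
        if missing:
            raise ValueError(
                f"core entries not in the accession universe: {sorted(missing)!r}"
            )


_DNA = set("ACGTN")
_ALLELES = set("ACGT")


@dataclass
class MarkerRecord:
    """A SNP-array marker: id plus context sequence in bracket notation.

    The context sequence contains exactly one polymorphic site written as
    ``[X/Y]`` (e.g. ``ACGT[A/G]ACGT``) flanked by non-empty DNA on both
    sides.
    """

    marker_id: str
    context_sequence: str
    origin: str = ""

    def __post_init__(self) -> None:
        self.parse()  # validates

    def parse(self) -> tuple[str, tuple[str, str], str]:
        """Return (left_flank, (allele_x, allele_y), right_flank)."""
        s = self.context_sequence.upper()
        if s.count("[") != 1 or s.count("]") != 1:
            raise ValueError(
                f"marker {self.marker_id!r}: expected exactly one [X/Y] site"
            )
        left, rest = s.split("[", 1)
        site, right = rest.split("]", 1)
        parts = site.split("/")
        if len(parts) != 2 or any(p not in _ALLELES for p in parts) or parts[0] == parts[1]:
            raise ValueError(
                f"marker {self.marker_id!r}: malformed allele site [{site}]"
            )
        if not left or not right:
            raise ValueError(f"marker {self.marker_id!r}: empty flank")
        for flank in (left, right):
            if set(flank) - _DNA:
                raise ValueError(
                    f"marker {self.marker_id!r}: non-DNA characters in flank"
                )
        return left, (parts[0], parts[1]), right
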