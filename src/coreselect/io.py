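"""Readers and writers for the tabular/VCF formats the pipeline touches.

The tabular genotype dialect has markers as rows and accessions as
columns, tab-separated, with ``--`` (configurable) marking a missing
call.  Calls may be written either as letter genotypes ``AA``/``AB``/
``BB`` or directly as reference-allele dosages ``1``/``0.5``/``0``.
Readers validate invariants and fail loudly rather than repairing input.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .matrix import DistanceMatrix, GenotypeMatrix, MarkerRecord

logger = logging.getLogger(__name__)

__all__ = [
    "read_genotype_table",
    "write_genotype_table",
    "read_vcf_biallelic",
    "read_distance_matrix",
    "write_distance_matrix",
    "read_marker_manifest",
    "write_marker_manifest",
    "read_core_set",
    "write_core_set",
]

_LETTER_CALLS = {"AA": 1.0, "AB": 0.5, "BA": 0.5, "BB": 0.0}
_NUMERIC_CALLS = {"0": 0.0, "0.0": 0.0, "0.5": 0.5, "1": 1.0, "1.0": 1.0}


def _parse_call(token: str, missing_token: str, where: str) -> float:
    if token == missing_token or token in ("", "NA", "nan"):
        return np.nan
    t = token.strip().upper()
    if t in _LETTER_CALLS:
        return _LETTER_CALLS[t]
    if t in _NUMERIC_CALLS:
        return _NUMERIC_CALLS[t]
    raise ValueError(f"unknown call token {token!r} at {where}")


def read_genotype_table(path, missing_token: str = "--") -> GenotypeMatrix:
    """Read a markers-by-accessions TSV into a :class:`GenotypeMatrix`.

    The header row carries accession ids; each subsequent row is one
    marker.  ``AA`` maps to dosage 1, ``AB`` to 0.5, ``BB`` to 0.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ValueError(f"{path}: empty genotype table")
    header = lines[0].split("\t")
    accession_ids = header[1:]
    if len(set(accession_ids)) != len(accession_ids):
        raise ValueError(f"{path}: duplicate accession ids in header")
    marker_ids: list[str] = []
    rows: list[list[float]] = []
    seen = set()
    for ln, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(header):
            raise ValueError(
                f"{path}: row {ln} has {len(fields)} fields, expected {len(header)}"
            )
        mid = fields[0]
        if mid in seen:
            raise ValueError(f"{path}: duplicate marker id {mid!r} at row {ln}")
        seen.add(mid)
        marker_ids.append(mid)
        rows.append(
            [
                _parse_call(tok, missing_token, f"row {ln} column {j + 2}")
                for j, tok in enumerate(fields[1:])
            ]
        )
    calls = np.array(rows, dtype=float).T  # file is markers x accessions
    if calls.size == 0:
        calls = calls.reshape(len(accession_ids), len(marker_ids))
    return GenotypeMatrix(accession_ids=accession_ids, marker_ids=marker_ids, calls=calls)


def write_genotype_table(matrix: GenotypeMatrix, path, missing_token: str = "--") -> None:
    """Write dosages as a markers-by-accessions TSV (lossless round trip)."""

    def fmt(v: float) -> str:
        if np.isnan(v):
            return missing_token
        return "0.5" if v == 0.5 else str(int(v))

    with open(path, "w") as fh:
        fh.write("marker\t" + "\t".join(matrix.accession_ids) + "\n")
        for j, mid in enumerate(matrix.marker_ids):
            fh.write(mid + "\t" + "\t".join(fmt(v) for v in matrix.calls[:, j]) + "\n")


def read_vcf_biallelic(path) -> GenotypeMatrix:
    """Read biallelic diploid records from a VCF into dosages.

    GT ``0/0`` maps to dosage 1 (homozygous reference), ``0/1``/``1/0``
    to 0.5, ``1/1`` to 0 and ``./.`` to missing; phase is ignored.
    Multi-allelic records are skipped and the skip count logged.
    """
    import pysam

    marker_ids: list[str] = []
    rows: list[np.ndarray] = []
    chroms: list[str] = []
    positions: list[int] = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            alts = rec.alts or ()
            if len(alts) != 1:
                skipped += 1
                continue
            row = np.empty(len(samples), dtype=float)
            for i, s in enumerate(samples):
                gt = rec.samples[s].get("GT")
                if gt is None or any(a is None for a in gt):
                    row[i] = np.nan
                else:
                    row[i] = 1.0 - sum(gt) / 2.0  # reference-allele dosage
            mid = rec.id if rec.id not in (None, ".") else f"{rec.chrom}_{rec.pos}"
            marker_ids.append(mid)
            chroms.append(rec.chrom)
            positions.append(rec.pos)
            rows.append(row)
    if skipped:
        logger.warning("skipped %d multi-allelic record(s) in %s", skipped, path)
    calls = (
        np.array(rows, dtype=float).T
        if rows
        else np.empty((len(samples), 0), dtype=float)
    )
    meta = pd.DataFrame({"chromosome": chroms, "position": positions}, index=marker_ids)
    return GenotypeMatrix(
        accession_ids=samples, marker_ids=marker_ids, calls=calls, marker_meta=meta
    )


def write_distance_matrix(d: DistanceMatrix, path) -> None:
    """Write a labeled square distance matrix as TSV."""
    with open(path, "w") as fh:
        fh.write(f"# metric={d.metric}\n")
        fh.write("id\t" + "\t".join(d.accession_ids) + "\n")
        for i, aid in enumerate(d.accession_ids):
            fh.write(aid + "\t" + "\t".join(repr(float(v)) for v in d.values[i]) + "\n")


def read_distance_matrix(path) -> DistanceMatrix:
    metric = "other"
    with open(path) as fh:
        lines = []
        for ln in fh:
            if ln.startswith("# metric="):
                metric = ln.strip().split("=", 1)[1]
            elif ln.strip():
                lines.append(ln.rstrip("\n"))
    header = lines[0].split("\t")[1:]
    values = []
    row_ids = []
    for line in lines[1:]:
        fields = line.split("\t")
        row_ids.append(fields[0])
        values.append([float(x) for x in fields[1:]])
    if row_ids != header:
        raise ValueError(f"{path}: row and column labels differ")
    return DistanceMatrix(accession_ids=header, values=np.array(values), metric=metric)


def read_marker_manifest(path) -> list:
    """Read marker context sequences from TSV or FASTA (by extension).

    TSV columns: ``marker_id``, ``context_sequence`` and optional
    ``origin``.  In FASTA the bracket site sits inside the sequence and
    the header is ``>marker_id [origin]``.
    """
    path = str(path)
    markers: list[MarkerRecord] = []
    if path.endswith((".fa", ".fasta", ".fna")):
        from Bio import SeqIO

        for rec in SeqIO.parse(path, "fasta"):
            markers.append(
                MarkerRecord(rec.id, str(rec.seq), origin=rec.description[len(rec.id):].strip())
            )
        return markers
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "marker_id" not in df.columns or "context_sequence" not in df.columns:
        raise ValueError(f"{path}: manifest needs marker_id and context_sequence columns")
    for _, r in df.iterrows():
        markers.append(
            MarkerRecord(r["marker_id"], r["context_sequence"], origin=r.get("origin", "") or "")
        )
    return markers


def write_marker_manifest(markers: Sequence[MarkerRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("marker_id\tcontext_sequence\torigin\n")
        for m in markers:
            fh.write(f"{m.marker_id}\t{m.context_sequence}\t{m.origin}\n")


def write_core_set(core, path) -> None:
    """One accession id per line, provenance in header comments."""
    with open(path, "w") as fh:
        fh.write(f"# method={core.method} metric={core.metric} seed={core.seed} k={core.k}\n")
        for e in core.entry_ids:
            fh.write(e + "\n")


def read_core_set(path):
    from .matrix import CoreSet

    meta = {}
    entries = []
    with open(path) as fh:
        for ln in fh:
            ln = ln.strip()
            if not ln:
                continue
            if ln.startswith("#"):
                for kv in ln[1:].split():
                    if "=" in kv:
                        k, v = kv.split("=", 1)
                        meta[k] = v
            else:
                entries.append(ln)
    seed = meta.get("seed")
    return CoreSet(
        entry_ids=entries,
        method=meta.get("method", ""),
        metric=None if meta.get("metric") in (None, "None") else meta.get("metric"),
        seed=None if seed in (None, "None") else int(seed),
    )
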