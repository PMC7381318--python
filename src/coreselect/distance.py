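"""Genetic distances between accessions and classical PCoA.

Two normalized distances on per-individual allele frequencies (dosage
``p`` of the reference allele, ``1 - p`` of the alternate):

Modified Rogers distance (MRD)
    ``d(i,j) = sqrt( (1/(2m)) * sum_l sum_a (p_ila - p_jla)^2 )``.
    For biallelic loci the inner sum is ``2 * (dp)^2``, so MRD equals
    the Euclidean distance between dosage vectors divided by sqrt(m).

Cavalli-Sforza & Edwards chord-type distance (CSE)
    ``d(i,j) = sqrt( (1/m) * sum_l (1 - sum_a sqrt(p_ila * p_jla)) )``.

Both lie in [0, 1], with 1 attained by opposite homozygotes at every
locus.  By default complete data is required (the intended post-
imputation workflow); a pairwise-complete mode restricts each pair's sum
to loci observed in both accessions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .matrix import DistanceMatrix, GenotypeMatrix

__all__ = ["mrd_matrix", "cse_matrix", "pcoa", "PcoaResult"]


def _require_complete(matrix: GenotypeMatrix, pairwise_complete: bool) -> None:
    if not pairwise_complete and matrix.has_missing():
        raise ValueError(
            "matrix has missing calls; impute first or pass pairwise_complete=True"
        )


def _check_shared(counts: np.ndarray, ids) -> None:
    i, j = np.nonzero(counts == 0)
    off = i < j
    if off.any():
        a, b = i[off][0], j[off][0]
        raise ValueError(f"no shared genotyped loci for pair ({ids[a]!r}, {ids[b]!r})")


def mrd_matrix(matrix: GenotypeMatrix, pairwise_complete: bool = False) -> DistanceMatrix:
    """Modified Rogers distance matrix (metric label ``MRD``)."""
    _require_complete(matrix, pairwise_complete)
    X = matrix.calls
    if not matrix.has_missing():
        d = squareform(pdist(X, metric="euclidean")) / np.sqrt(matrix.n_markers)
    else:
        obs = ~np.isnan(X)
        Z = np.where(obs, X, 0.0)
        Mf = obs.astype(float)
        counts = Mf @ Mf.T
        _check_shared(counts, matrix.accession_ids)
        sq = Z * Z
        ss = sq @ Mf.T + Mf @ sq.T - 2.0 * (Z @ Z.T)
        d = np.sqrt(np.clip(ss, 0.0, None) / counts)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 1.0)
    return DistanceMatrix(list(matrix.accession_ids), d, metric="MRD")


def cse_matrix(matrix: GenotypeMatrix, pairwise_complete: bool = False) -> DistanceMatrix:
    """Cavalli-Sforza & Edwards distance matrix (metric label ``CSE``)."""
    _require_complete(matrix, pairwise_complete)
    X = matrix.calls
    obs = ~np.isnan(X)
    Z = np.where(obs, X, 0.0)
    A = np.sqrt(Z)
    B = np.sqrt(np.where(obs, 1.0 - Z, 0.0))
    if not matrix.has_missing():
        counts = float(matrix.n_markers)
    else:
        Mf = obs.astype(float)
        counts = Mf @ Mf.T
        _check_shared(counts, matrix.accession_ids)
    s = A @ A.T + B @ B.T
    d = np.sqrt(np.clip(1.0 - s / counts, 0.0, 1.0))
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 1.0)
    return DistanceMatrix(list(matrix.accession_ids), d, metric="CSE")


@dataclass
class PcoaResult:
    """Principal-coordinate embedding of a distance matrix."""

    coordinates: np.ndarray  # N x n_axes, columns ordered by eigenvalue
    eigenvalues: np.ndarray  # positive eigenvalues, non-increasing
    proportion_explained: np.ndarray  # percent of sum of positive eigenvalues
    accession_ids: list


def pcoa(d: DistanceMatrix, n_axes: int = 2) -> PcoaResult:
    """Classical (Torgerson) scaling of a distance matrix.

    The squared-distance matrix is double-centered, eigendecomposed, and
    coordinates are eigenvectors scaled by sqrt(eigenvalue).  Negative
    eigenvalues (non-Euclidean input) are excluded both from the
    coordinates and from the variance-explained denominator; if fewer
    than `n_axes` positive eigenvalues exist, fewer axes are returned.
    """
    n = d.n
    if n_axes > n - 1:
        raise ValueError("n_axes must be <= N - 1")
    D2 = d.values**2
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ D2 @ J
    G = (G + G.T) / 2.0
    w, v = np.linalg.eigh(G)
    idx = np.argsort(w)[::-1]
    w, v = w[idx], v[:, idx]
    tol = 1e-9 * max(abs(w[0]), 1.0)
    pos = w > tol
    w_pos, v_pos = w[pos], v[:, pos]
    if n_axes > w_pos.size:
        import warnings

        warnings.warn(
            f"only {w_pos.size} positive eigenvalues; returning that many axes",
            stacklevel=2,
        )
        n_axes = w_pos.size
    coords = v_pos[:, :n_axes] * np.sqrt(w_pos[:n_axes])
    rel = 100.0 * w_pos / w_pos.sum()
    return PcoaResult(
        coordinates=coords,
        eigenvalues=w_pos[:n_axes],
        proportion_explained=rel[:n_axes],
        accession_ids=list(d.accession_ids),
    )
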