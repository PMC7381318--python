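"""Core-set construction: PAM k-medoids, objective-driven local search,
and a uniform random baseline.

``pam_kmedoids`` is the classical partitioning-around-medoids algorithm
on a precomputed distance matrix: a greedy BUILD phase followed by
best-improving SWAP exchanges until no exchange lowers the total
point-to-nearest-medoid cost.  The medoids, being real accessions, form
the core set.

``local_search_select`` is a seeded stochastic improver over k-subsets
for the five evaluation objectives (maximize E-NE/Shannon/expected
heterozygosity/allele coverage, minimize A-NE): starting from a random
subset it proposes single-entry swaps and accepts strictly improving
ones (random descent), stopping at an evaluation budget or after a
patience window without improvement, optionally restarting.  The inner
loops are compiled (numba) with incremental objective updates, so a
proposal costs O(k), O(N) or O(m) rather than a full re-evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix import CoreSet, DistanceMatrix, GenotypeMatrix

__all__ = [
    "ObjectiveSpec",
    "SearchBudget",
    "pam_kmedoids",
    "local_search_select",
    "random_core",
    "objective_value",
]

STATISTICS = ("ENE", "ANE", "SD", "EH", "AC")
_DISTANCE_BASED = ("ENE", "ANE")


@dataclass(frozen=True)
class ObjectiveSpec:
    """One of the five selection objectives, with its optimization direction.

    A-NE is minimized (representativeness); the other four are maximized
    (diversity).  Distance-based objectives (E-NE, A-NE) additionally
    name the metric (``MRD`` or ``CSE``) they are evaluated under.
    """

    statistic: str
    metric: str | None = None

    def __post_init__(self) -> None:
        if self.statistic not in STATISTICS:
            raise ValueError(f"unknown statistic {self.statistic!r}")
        if self.statistic in _DISTANCE_BASED:
            if self.metric not in ("MRD", "CSE"):
                raise ValueError(f"{self.statistic} needs metric MRD or CSE")
        elif self.metric is not None:
            raise ValueError(f"{self.statistic} takes no metric")

    @property
    def direction(self) -> str:
        return "minimize" if self.statistic == "ANE" else "maximize"

    @property
    def label(self) -> str:
        return self.statistic if self.metric is None else f"{self.statistic}-{self.metric}"


@dataclass(frozen=True)
class SearchBudget:
    """Evaluation budget of one local-search run (seeded, deterministic)."""

    max_evaluations: int = 50_000
    patience: int = 5_000
    seed: int = 0
    restarts: int = 1

    def __post_init__(self) -> None:
        if self.max_evaluations < 1 or self.patience < 1 or self.restarts < 1:
            raise ValueError("budget fields must be positive")


# ---------------------------------------------------------------------------
# PAM k-medoids
# ---------------------------------------------------------------------------


def _nearest_two(V: np.ndarray, med: np.ndarray) -> tuple:
    """Per accession: distance to nearest & second-nearest medoid, nearest id."""
    sub = V[:, med]
    if med.size == 1:
        d1 = sub[:, 0]
        return d1.copy(), np.full(V.shape[0], np.inf), np.full(V.shape[0], med[0])
    part = np.argpartition(sub, 1, axis=1)
    rows = np.arange(V.shape[0])
    a, b = part[:, 0], part[:, 1]
    da, db = sub[rows, a], sub[rows, b]
    swap = db < da
    a2 = np.where(swap, b, a)
    d1 = np.where(swap, db, da)
    d2 = np.where(swap, da, db)
    return d1, d2, med[a2]


def pam_kmedoids(
    d: DistanceMatrix,
    k: int,
    seed: int | None = None,
    initial_medoids: list | None = None,
) -> tuple[CoreSet, np.ndarray, float]:
    """Partitioning around medoids on a precomputed distance matrix.

    With `initial_medoids` given, BUILD is skipped and SWAP starts from
    them (the mechanism used to probe run-to-run stability with random
    starts).  Ties in BUILD and SWAP are broken toward the lowest
    position/accession index, so the algorithm is fully deterministic.

    The SWAP step scores all (medoid, candidate) exchanges at once by
    splitting each exchange's cost change into a candidate-only gain
    plus a per-cluster correction (the FastPAM decomposition), which
    reduces one sweep to elementwise work plus a matrix product.

    Returns ``(core, assignment, total_cost)`` where ``assignment[i]``
    is the accession index of the medoid serving accession ``i``.
    """
    V = d.values
    n = V.shape[0]
    if not (1 <= k <= n):
        raise ValueError(f"k={k} outside [1, {n}]")
    if initial_medoids is not None:
        idx_of = {a: i for i, a in enumerate(d.accession_ids)}
        med_list = [idx_of[m] if isinstance(m, str) else int(m) for m in initial_medoids]
        if len(set(med_list)) != k:
            raise ValueError("initial_medoids must be k distinct accessions")
        med = np.array(med_list, dtype=int)
    else:
        # BUILD: start from the 1-medoid optimum, then greedily add the
        # accession that most reduces total cost.
        med = np.array([int(np.argmin(V.sum(axis=1)))], dtype=int)
        d_near = V[:, med[0]].copy()
        in_med = np.zeros(n, dtype=bool)
        in_med[med[0]] = True
        while med.size < k:
            gains = np.maximum(d_near[:, None] - V, 0.0).sum(axis=0)
            gains[in_med] = -np.inf
            c = int(np.argmax(gains))
            med = np.append(med, c)
            in_med[c] = True
            np.minimum(d_near, V[:, c], out=d_near)

    # SWAP: best-improving exchange until no exchange lowers the cost
    eps = 1e-12
    in_med = np.zeros(n, dtype=bool)
    in_med[med] = True
    while True:
        d1, d2, near = _nearest_two(V, med)
        unsel = np.nonzero(~in_med)[0]
        if unsel.size == 0:
            break
        C = V[:, unsel]  # n x u
        # gain every exchange shares when candidate o undercuts d1
        g = np.minimum(C - d1[:, None], 0.0)
        # correction applying only to the removed medoid's own cluster
        p = np.minimum(C, d2[:, None]) - d1[:, None] - g
        # map each accession to its nearest medoid's position in `med`
        pos_arr = np.empty(n, dtype=int)
        pos_arr[med] = np.arange(med.size)
        ind = np.zeros((med.size, n))
        ind[pos_arr[near], np.arange(n)] = 1.0
        delta = ind @ p + g.sum(axis=0)[None, :]
        flat = int(np.argmin(delta))  # ties -> lowest medoid position, then candidate
        best_delta = delta.flat[flat]
        if best_delta >= -eps:
            break
        pos, j = divmod(flat, unsel.size)
        in_med[med[pos]] = False
        med[pos] = unsel[j]
        in_med[med[pos]] = True

    d1, _, near = _nearest_two(V, med)
    core = CoreSet(
        entry_ids=[d.accession_ids[i] for i in med],
        method="kmedoids",
        metric=d.metric,
        seed=seed,
    )
    return core, near, float(d1.sum())


# ---------------------------------------------------------------------------
# local search over the five objectives
# ---------------------------------------------------------------------------


def local_search_select(
    objective: ObjectiveSpec,
    data,
    k: int,
    budget: SearchBudget,
) -> CoreSet:
    """Random-descent subset search for one objective.

    Starts from a seeded uniform k-subset, repeatedly proposes swapping
    one selected accession against one unselected, and accepts strictly
    improving swaps until the evaluation budget or patience is
    exhausted; with ``restarts > 1`` the best subset over all restarts
    is returned.  Identical (objective, data, k, budget) gives an
    identical core.
    """
    from . import _kernels

    ids = data.accession_ids
    n = len(ids)
    if objective.statistic == "ENE" and k < 2:
        raise ValueError("E-NE is undefined for k < 2")
    if not (1 <= k <= n):
        raise ValueError(f"k={k} outside [1, {n}]")
    seed = int(budget.seed) % (2**32)
    if objective.statistic in _DISTANCE_BASED:
        if not isinstance(data, DistanceMatrix):
            raise TypeError(f"{objective.statistic} needs a DistanceMatrix")
        fn = _kernels.ene_search if objective.statistic == "ENE" else _kernels.ane_search
        sel, _ = fn(
            data.values, k, seed, budget.max_evaluations, budget.patience, budget.restarts
        )
    else:
        if not isinstance(data, GenotypeMatrix):
            raise TypeError(f"{objective.statistic} needs a GenotypeMatrix")
        X = data.calls
        if np.isnan(X).any():
            raise ValueError("objective requires complete genotype data")
        X2 = np.rint(2.0 * X).astype(np.int64)
        stat = {"SD": _kernels.STAT_SD, "EH": _kernels.STAT_EH, "AC": _kernels.STAT_AC}[
            objective.statistic
        ]
        full_ref = X2.sum(axis=0) > 0
        full_alt = X2.sum(axis=0) < 2 * n
        denom = max(int(full_ref.sum() + full_alt.sum()), 1)
        sel, _ = _kernels.pooled_search(
            X2, k, stat, full_ref, full_alt, denom, seed,
            budget.max_evaluations, budget.patience, budget.restarts,
        )
    return CoreSet(
        entry_ids=[ids[i] for i in np.sort(sel)],
        method=objective.label,
        metric=objective.metric,
        seed=budget.seed,
    )


def random_core(accession_ids, k: int, seed: int) -> CoreSet:
    """Uniform k-subset without replacement (the random baseline)."""
    ids = list(accession_ids)
    if not (1 <= k <= len(ids)):
        raise ValueError(f"k={k} outside [1, {len(ids)}]")
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(ids), size=k, replace=False)
    return CoreSet(entry_ids=[ids[i] for i in pick], method="random", seed=seed)


def objective_value(objective: ObjectiveSpec, core: CoreSet, data) -> float:
    """Evaluate one objective for an existing core (same conventions as search)."""
    from . import diversity

    if objective.statistic == "ENE":
        return diversity.average_entry_to_nearest_entry(core, data)
    if objective.statistic == "ANE":
        return diversity.average_accession_to_nearest_entry(core, data)
    fn = {
        "SD": diversity.shannon_diversity,
        "EH": diversity.expected_heterozygosity,
        "AC": diversity.allele_coverage,
    }[objective.statistic]
    return fn(core, data)
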