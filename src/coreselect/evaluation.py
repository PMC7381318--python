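"""Replicated comparison of core-selection methods.

Each method is run R times with distinct seeds; per-accession selection
frequencies over the replicates summarize run-to-run stability (a
method is stable when every accession is either always or never
selected, maximally unstable when all frequencies sit at k/N around
0.5).  Every produced core is additionally scored by average A-NE and
average E-NE under a common metric, giving the representativeness /
spread quality trade-off per method.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .distance import cse_matrix, mrd_matrix
from .diversity import (
    average_accession_to_nearest_entry,
    average_entry_to_nearest_entry,
)
from .matrix import CoreSet, DistanceMatrix, GenotypeMatrix
from .selection import (
    ObjectiveSpec,
    SearchBudget,
    local_search_select,
    pam_kmedoids,
    random_core,
)

__all__ = [
    "StabilityResult",
    "QualityRecord",
    "Ecdf",
    "ecdf_of_frequencies",
    "stability_index",
    "run_stability_experiment",
    "quality_table",
    "ComparisonConfig",
    "ComparisonReport",
    "compare_methods",
    "DEFAULT_SETTINGS",
]

#: the seven optimizer settings of the replicated comparison:
#: the two distance-based objectives under each metric, plus the three
#: metric-free allele statistics
DEFAULT_SETTINGS = (
    ObjectiveSpec("ENE", "MRD"),
    ObjectiveSpec("ENE", "CSE"),
    ObjectiveSpec("ANE", "MRD"),
    ObjectiveSpec("ANE", "CSE"),
    ObjectiveSpec("SD"),
    ObjectiveSpec("EH"),
    ObjectiveSpec("AC"),
)


class Ecdf:
    """Right-continuous empirical cumulative distribution function."""

    def __init__(self, values: np.ndarray):
        v = np.asarray(values, dtype=float)
        if v.size == 0:
            raise ValueError("ecdf of an empty sample")
        self._sorted = np.sort(v)
        self._n = v.size

    def __call__(self, x) -> np.ndarray | float:
        r = np.searchsorted(self._sorted, np.asarray(x, dtype=float), side="right") / self._n
        return float(r) if np.isscalar(x) else r


def ecdf_of_frequencies(f: np.ndarray) -> Ecdf:
    """``F(x) = #{i : f_i <= x} / N`` over per-accession selection frequencies."""
    return Ecdf(f)


def stability_index(f: np.ndarray) -> float:
    """``S = 1 - mean(4 f (1-f))``: 1 iff every frequency is 0 or 1, 0 when all 0.5."""
    f = np.asarray(f, dtype=float)
    return float(1.0 - (4.0 * f * (1.0 - f)).mean())


@dataclass
class StabilityResult:
    """Selection frequencies of one method at one core size over R runs."""

    method: str
    k: int
    r_replicates: int
    frequencies: np.ndarray  # per accession, in [0, 1]
    accession_ids: list
    cores: list = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        if f.min(initial=0) < 0 or f.max(initial=0) > 1:
            raise ValueError("frequencies must lie in [0, 1]")
        total = f.sum() * self.r_replicates
        if abs(total - self.k * self.r_replicates) > 1e-6 * max(self.k, 1):
            raise ValueError(
                f"frequency conservation violated: sum f = {f.sum()!r}, expected k = {self.k}"
            )
        self.frequencies = f

    @property
    def stability(self) -> float:
        return stability_index(self.frequencies)

    def ecdf(self) -> Ecdf:
        return ecdf_of_frequencies(self.frequencies)


def run_stability_experiment(
    method: str | ObjectiveSpec,
    k: int,
    r_replicates: int,
    base_seed: int,
    distances: dict | None = None,
    genotypes: GenotypeMatrix | None = None,
    budget: SearchBudget | None = None,
    kmedoids_metric: str = "MRD",
    keep_cores: bool = True,
) -> StabilityResult:
    """Run one selector R times with seeds ``base_seed + 1 .. base_seed + R``.

    `method` is ``"kmedoids"`` (PAM from fresh random initial medoids
    each run), ``"random"``, or an :class:`ObjectiveSpec` for the local
    search.  Distance-based methods read the matrix for their metric
    from `distances`; allele statistics read `genotypes`.
    """
    if r_replicates < 1:
        raise ValueError("need at least one replicate")
    if isinstance(method, ObjectiveSpec):
        data = (
            distances[method.metric]
            if method.statistic in ("ENE", "ANE")
            else genotypes
        )
        if data is None:
            raise ValueError(f"method {method.label} lacks its input data")
        ids = data.accession_ids
        label = method.label

        def one_run(seed: int, run: int) -> CoreSet:
            b = replace(budget or SearchBudget(), seed=seed)
            core = local_search_select(method, data, k, b)
            core.run_index = run
            return core

    elif method == "kmedoids":
        d = distances[kmedoids_metric]
        ids = d.accession_ids
        label = "kmedoids"

        def one_run(seed: int, run: int) -> CoreSet:
            rng = np.random.default_rng(seed)
            init = list(rng.choice(len(ids), size=k, replace=False))
            core, _, _ = pam_kmedoids(d, k, seed=seed, initial_medoids=init)
            core.run_index = run
            return core

    elif method == "random":
        src = distances[kmedoids_metric] if distances else genotypes
        ids = src.accession_ids
        label = "random"

        def one_run(seed: int, run: int) -> CoreSet:
            core = random_core(ids, k, seed)
            core.run_index = run
            return core

    else:
        raise ValueError(f"unknown method {method!r}")

    index = {a: i for i, a in enumerate(ids)}
    hits = np.zeros(len(ids), dtype=float)
    cores: list[CoreSet] = []
    for run in range(1, r_replicates + 1):
        core = one_run(base_seed + run, run)
        for e in core.entry_ids:
            hits[index[e]] += 1
        if keep_cores:
            cores.append(core)
    return StabilityResult(
        method=label,
        k=k,
        r_replicates=r_replicates,
        frequencies=hits / r_replicates,
        accession_ids=list(ids),
        cores=cores,
    )


@dataclass
class QualityRecord:
    method: str
    seed: int | None
    run_index: int | None
    k: int
    ane: float
    ene: float


def quality_table(cores, d_common: DistanceMatrix) -> list:
    """Average A-NE and E-NE of each core under one common metric."""
    out = []
    for core in cores:
        core.validate_against(d_common.accession_ids)
        ane = average_accession_to_nearest_entry(core, d_common)
        ene = (
            average_entry_to_nearest_entry(core, d_common) if core.k >= 2 else float("nan")
        )
        out.append(
            QualityRecord(
                method=core.method, seed=core.seed, run_index=core.run_index,
                k=core.k, ane=ane, ene=ene,
            )
        )
    return out


@dataclass
class ComparisonConfig:
    """Layout of the replicated method comparison.

    Defaults mirror the full study design: core sizes 178 and 320, the
    seven optimizer settings, 1000 replicates each, plus k-medoids and
    random baselines, everything evaluated under MRD.
    """

    sizes: tuple = (178, 320)
    r_replicates: int = 1000
    base_seed: int = 0
    settings: tuple = DEFAULT_SETTINGS
    include_kmedoids: bool = True
    include_random: bool = True
    evaluation_metric: str = "MRD"
    budget: SearchBudget = field(default_factory=SearchBudget)
    keep_cores: bool = False


@dataclass
class ComparisonReport:
    stability: list  # StabilityResult per (method, size)
    quality: pd.DataFrame  # one row per produced core
    summary: pd.DataFrame  # per (method, size): S, mean A-NE, mean E-NE
    n_optimizer_cores: int
    n_total_cores: int

    def stability_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"method": s.method, "k": s.k, "R": s.r_replicates, "S": s.stability}
                for s in self.stability
            ]
        )

    def frequency_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.stability:
            for a, f in zip(s.accession_ids, s.frequencies):
                rows.append({"method": s.method, "k": s.k, "accession": a, "f": f})
        return pd.DataFrame(rows)


def compare_methods(
    matrix: GenotypeMatrix, config: ComparisonConfig
) -> ComparisonReport:
    """Execute the full replicated grid and aggregate stability + quality.

    Every optimizer setting and baseline is run ``R`` times per core
    size; run seeds are derived deterministically from
    ``config.base_seed`` so the whole report is replayable.
    """
    distances = {"MRD": mrd_matrix(matrix), "CSE": cse_matrix(matrix)}
    d_common = distances[config.evaluation_metric]

    methods: list = list(config.settings)
    if config.include_kmedoids:
        methods.append("kmedoids")
    if config.include_random:
        methods.append("random")

    stability_results: list[StabilityResult] = []
    quality_rows: list[dict] = []
    n_optimizer = 0
    n_total = 0
    for s_idx, k in enumerate(config.sizes):
        for m_idx, method in enumerate(methods):
            base = config.base_seed + 1_000_000 * (s_idx * len(methods) + m_idx)
            res = run_stability_experiment(
                method,
                k,
                config.r_replicates,
                base,
                distances=distances,
                genotypes=matrix,
                budget=config.budget,
                keep_cores=True,
            )
            n_total += len(res.cores)
            if isinstance(method, ObjectiveSpec):
                n_optimizer += len(res.cores)
            for rec in quality_table(res.cores, d_common):
                quality_rows.append(
                    {
                        "method": rec.method, "k": rec.k, "run": rec.run_index,
                        "seed": rec.seed, "ANE": rec.ane, "ENE": rec.ene,
                    }
                )
            if not config.keep_cores:
                res.cores = []
            stability_results.append(res)

    quality = pd.DataFrame(quality_rows)
    summary = (
        quality.groupby(["method", "k"], sort=False)
        .agg(mean_ANE=("ANE", "mean"), mean_ENE=("ENE", "mean"), n_cores=("ANE", "size"))
        .reset_index()
    )
    s_frame = pd.DataFrame(
        [{"method": s.method, "k": s.k, "S": s.stability} for s in stability_results]
    )
    summary = summary.merge(s_frame, on=["method", "k"], how="left")
    return ComparisonReport(
        stability=stability_results,
        quality=quality,
        summary=summary.sort_values(["k", "S"], ascending=[True, False]).reset_index(drop=True),
        n_optimizer_cores=n_optimizer,
        n_total_cores=n_total,
    )
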