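"""PAM k-medoids and the random-descent subset search, checked against
brute-force oracles on tiny instances and an external reference
implementation where available."""

import itertools
import shutil
import subprocess

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from coreselect import CoreSet, DistanceMatrix
from coreselect.diversity import (
    allele_coverage,
    average_accession_to_nearest_entry,
    average_entry_to_nearest_entry,
    expected_heterozygosity,
    shannon_diversity,
)
from coreselect.selection import (
    ObjectiveSpec,
    SearchBudget,
    local_search_select,
    objective_value,
    pam_kmedoids,
    random_core,
)

from conftest import make_distance, make_matrix


def brute_force_medoid_cost(V, k):
    n = V.shape[0]
    return min(
        V[:, list(c)].min(axis=1).sum() for c in itertools.combinations(range(n), k)
    )


class TestPamKmedoids:
    def test_k_equals_n_costs_zero(self, small_mrd):
        sub = DistanceMatrix(
            small_mrd.accession_ids[:6],
            small_mrd.values[:6, :6],
            metric="MRD",
        )
        core, assign, cost = pam_kmedoids(sub, 6)
        assert core.k == 6 and cost == 0.0

    def test_two_separated_triplets_find_optimum(self):
        # within-cluster distance 0.1, between 0.9: one medoid per cluster
        v = np.full((6, 6), 0.9)
        for block in (slice(0, 3), slice(3, 6)):
            v[block, block] = 0.1
        np.fill_diagonal(v, 0)
        d = make_distance(v)
        core, assign, cost = pam_kmedoids(d, 2)
        idx = sorted(d.accession_ids.index(e) for e in core.entry_ids)
        assert idx[0] < 3 <= idx[1]
        assert cost == pytest.approx(brute_force_medoid_cost(v, 2))

    def test_deterministic_given_initial_medoids(self, small_mrd):
        a = pam_kmedoids(small_mrd, 5, initial_medoids=["C1_0001", "C1_0010", "C2_0005", "C2_0020", "C1_0020"])
        b = pam_kmedoids(small_mrd, 5, initial_medoids=["C1_0001", "C1_0010", "C2_0005", "C2_0020", "C1_0020"])
        assert a[0].entry_ids == b[0].entry_ids and a[2] == b[2]

    def test_swap_never_worse_than_initial_medoids(self, small_mrd):
        rng = np.random.default_rng(17)
        V = small_mrd.values
        for _ in range(10):
            init = list(rng.choice(small_mrd.n, size=8, replace=False))
            init_cost = V[:, init].min(axis=1).sum()
            _, _, cost = pam_kmedoids(small_mrd, 8, initial_medoids=init)
            assert cost <= init_cost + 1e-12

    def test_near_optimal_on_random_instances(self):
        """BUILD+SWAP lands at or within a few percent of the global
        optimum on small random instances (it is a local optimizer)."""
        worst = 0.0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            n, k = int(rng.integers(5, 11)), int(rng.integers(2, 4))
            pts = rng.random((n, 3))
            V = squareform(pdist(pts))
            V /= max(V.max(), 1e-9) * 1.01
            d = make_distance(V)
            _, _, cost = pam_kmedoids(d, k)
            best = brute_force_medoid_cost(V, k)
            worst = max(worst, cost / best - 1 if best > 0 else 0)
        assert worst < 0.10

    def test_matches_reference_pam_implementation(self, tmp_path, small_mrd):
        """Same final objective as R cluster::pam from the BUILD start."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        V = small_mrd.values[:25, :25].copy()
        d = DistanceMatrix(small_mrd.accession_ids[:25], V, metric="MRD")
        np.savetxt(tmp_path / "d.txt", V)
        script = tmp_path / "pam.R"
        script.write_text(
            'V <- as.matrix(read.table("%s"))\n'
            "library(cluster)\n"
            "for (k in c(2, 4, 7)) {\n"
            "  p <- pam(as.dist(V), k, diss=TRUE)\n"
            '  cat(sprintf("%%d %%.12f\\n", k, p$objective["swap"] * nrow(V)))\n'
            "}\n" % (tmp_path / "d.txt")
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        ).stdout
        for line in out.strip().splitlines():
            k, ref_cost = line.split()
            _, _, cost = pam_kmedoids(d, int(k))
            assert cost == pytest.approx(float(ref_cost), abs=1e-9)

    def test_invalid_arguments(self, small_mrd):
        with pytest.raises(ValueError):
            pam_kmedoids(small_mrd, 0)
        with pytest.raises(ValueError):
            pam_kmedoids(small_mrd, 3, initial_medoids=["C1_0001", "C1_0001", "C1_0002"])


ALL_OBJECTIVES = [
    ObjectiveSpec("ENE", "MRD"),
    ObjectiveSpec("ANE", "MRD"),
    ObjectiveSpec("SD"),
    ObjectiveSpec("EH"),
    ObjectiveSpec("AC"),
]


def _signed_value(obj, entry_idx, d, mat):
    c = CoreSet(entry_ids=[mat.accession_ids[i] for i in entry_idx])
    if obj.statistic == "ENE":
        return average_entry_to_nearest_entry(c, d)
    if obj.statistic == "ANE":
        return -average_accession_to_nearest_entry(c, d)
    fn = {"SD": shannon_diversity, "EH": expected_heterozygosity, "AC": allele_coverage}
    return fn[obj.statistic](c, mat)


class TestLocalSearch:
    @pytest.mark.parametrize("obj", ALL_OBJECTIVES, ids=lambda o: o.label)
    def test_attains_exhaustive_optimum_on_tiny_instance(self, obj, tiny_panel):
        from coreselect import mrd_matrix

        d = mrd_matrix(tiny_panel)
        best = max(
            _signed_value(obj, c, d, tiny_panel)
            for c in itertools.combinations(range(8), 3)
        )
        data = d if obj.statistic in ("ENE", "ANE") else tiny_panel
        hits = 0
        for seed in range(30):
            core = local_search_select(
                obj, data, 3,
                SearchBudget(max_evaluations=3000, patience=500, seed=seed, restarts=3),
            )
            idx = [tiny_panel.accession_ids.index(e) for e in core.entry_ids]
            if _signed_value(obj, idx, d, tiny_panel) >= best - 1e-12:
                hits += 1
        assert hits >= 28

    def test_determinism(self, small_mrd):
        b = SearchBudget(max_evaluations=2000, patience=400, seed=77)
        a = local_search_select(ObjectiveSpec("ENE", "MRD"), small_mrd, 6, b)
        c = local_search_select(ObjectiveSpec("ENE", "MRD"), small_mrd, 6, b)
        assert a.entry_ids == c.entry_ids

    def test_allele_coverage_attains_perfect_cover(self):
        # three accessions jointly carry every allele; k=3 can reach 1.0
        calls = np.array(
            [
                [1, 1, 1, 1],
                [0, 0, 1, 1],
                [1, 1, 0, 0],
                [1, 1, 1, 1],
                [1, 1, 1, 1],
                [1, 1, 1, 1],
            ],
            dtype=float,
        )
        mat = make_matrix(calls)
        core = local_search_select(
            ObjectiveSpec("AC"), mat, 3, SearchBudget(max_evaluations=2000, patience=500, seed=1)
        )
        assert allele_coverage(core, mat) == 1.0

    def test_beats_random_core_on_its_objective(self, small_panel, small_mrd):
        for obj in ALL_OBJECTIVES:
            data = small_mrd if obj.statistic in ("ENE", "ANE") else small_panel
            core = local_search_select(
                obj, data, 10, SearchBudget(max_evaluations=4000, patience=600, seed=5)
            )
            rand_vals = [
                objective_value(obj, random_core(small_panel.accession_ids, 10, s), data)
                for s in range(20)
            ]
            opt_val = objective_value(obj, core, data)
            mean_rand = float(np.mean(rand_vals))
            if obj.direction == "maximize":
                assert opt_val >= mean_rand
            else:
                assert opt_val <= mean_rand

    def test_ene_needs_k_of_two(self, small_mrd):
        with pytest.raises(ValueError, match="k < 2"):
            local_search_select(
                ObjectiveSpec("ENE", "MRD"), small_mrd, 1, SearchBudget(seed=1)
            )


class TestObjectiveSpec:
    def test_directions(self):
        assert ObjectiveSpec("ANE", "MRD").direction == "minimize"
        assert ObjectiveSpec("SD").direction == "maximize"

    def test_metric_required_only_for_distance_objectives(self):
        with pytest.raises(ValueError):
            ObjectiveSpec("ENE")
        with pytest.raises(ValueError):
            ObjectiveSpec("EH", "MRD")


class TestRandomCore:
    def test_k_equals_n_returns_everyone(self):
        ids = [f"a{i}" for i in range(7)]
        assert sorted(random_core(ids, 7, seed=0).entry_ids) == sorted(ids)

    def test_reproducible(self):
        ids = [f"a{i}" for i in range(30)]
        assert random_core(ids, 6, 5).entry_ids == random_core(ids, 6, 5).entry_ids

    def test_uniform_selection_frequencies(self):
        ids = [f"a{i}" for i in range(50)]
        counts = {a: 0 for a in ids}
        draws = 10_000
        for s in range(draws):
            for e in random_core(ids, 10, seed=s).entry_ids:
                counts[e] += 1
        freqs = np.array([counts[a] / draws for a in ids])
        assert np.abs(freqs - 0.2).max() < 0.02
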