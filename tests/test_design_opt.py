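"""Design families and the GA + SAA optimizer."""

import numpy as np
import pandas as pd
import pytest

from metcd import (
    METDesign,
    OptimizerConfig,
    make_design,
    objective,
    optimize_design,
    exhaustive_search,
    vanraden_kinship,
)
from metcd.design_opt import configuration_covariances, enumerate_allocations
from metcd.simulate import synthetic_genotypes


@pytest.fixture(scope="module")
def pool():
    geno = synthetic_genotypes(25, 300, 5, seed=60)
    return vanraden_kinship(geno)


class TestFamilies:
    def test_unreplicated_design_uses_each_genotype_once(self, pool):
        d = make_design("I", list(pool.ids), 10, 2, seed=0)
        counts = d.plots["genotype"].value_counts()
        assert len(counts) == 20 and (counts == 1).all()

    def test_complete_two_replicates(self, pool):
        d = make_design("C2", list(pool.ids), 10, 2, seed=1)
        per_trial = d.plots.groupby(["trial", "genotype"]).size()
        assert (per_trial == 2).all()
        assert d.plots["genotype"].nunique() == 5

    def test_c1_uses_same_set_in_every_trial(self, pool):
        d = make_design("C1", list(pool.ids), 8, 3, seed=2)
        sets = d.plots.groupby("trial")["genotype"].apply(set)
        assert all(s == sets.iloc[0] for s in sets)
        assert len(sets.iloc[0]) == 8

    def test_infeasible_budgets_are_rejected(self, pool):
        with pytest.raises(ValueError, match="needs"):
            make_design("I", list(pool.ids), 20, 2, seed=0)
        with pytest.raises(ValueError, match="divisible"):
            make_design("C2", list(pool.ids), 9, 2, seed=0)
        with pytest.raises(ValueError, match="unknown design family"):
            make_design("X3", list(pool.ids), 4, 2, seed=0)

    def test_seed_reproducibility(self, pool):
        a = make_design("I", list(pool.ids), 6, 2, seed=11)
        b = make_design("I", list(pool.ids), 6, 2, seed=11)
        pd.testing.assert_frame_equal(a.plots, b.plots)


class TestObjective:
    def test_worked_example_design_scores_mean_of_its_cds(self, worked_example):
        cfg = OptimizerConfig(cov=worked_example["cov"], known_fixed=True, seed=0)
        score = objective(worked_example["designs"]["D"], cfg, worked_example["K"])
        # mean of the six per-trial CDs of the optimal design
        expected = np.mean([0.533, 0.533, 0.508, 0.220, 0.220, 0.508])
        assert score == pytest.approx(expected, abs=0.002)

    def test_swapping_the_related_pair_between_trials_keeps_the_score(self, worked_example):
        from conftest import make_design as md
        cfg = OptimizerConfig(cov=worked_example["cov"], known_fixed=True, seed=0)
        d = worked_example["designs"]["D"]
        swapped = md([(1, 1, "1"), (1, 2, "3"), (2, 1, "1"), (2, 2, "2")])
        assert objective(d, cfg, worked_example["K"]) == pytest.approx(
            objective(swapped, cfg, worked_example["K"]), abs=1e-10
        )

    def test_empty_design_scores_zero(self, worked_example):
        empty = METDesign(
            ["trial1", "trial2"],
            pd.DataFrame(columns=["trial", "plot", "genotype"]),
            ["1", "2", "3"],
        )
        cfg = OptimizerConfig(cov=worked_example["cov"], known_fixed=True, seed=0)
        assert objective(empty, cfg, worked_example["K"]) == 0.0


class TestOptimizer:
    def _small_config(self, seed, **kw):
        base = dict(ga_iterations=25, population=30, elites=6, saa_iterations=5,
                    mutation_rate=0.15, seed=seed)
        base.update(kw)
        return OptimizerConfig(**base)

    def test_reaches_global_optimum_on_worked_example(self, worked_example):
        cfg = self._small_config(1, cov=worked_example["cov"], known_fixed=True)
        best, trace = optimize_design(["1", "2", "3"], 2, 2, worked_example["K"], cfg)
        ref, ref_score = exhaustive_search(["1", "2", "3"], 2, 2, worked_example["K"], cfg)
        assert trace[-1] == pytest.approx(ref_score, abs=1e-10)
        # the optimum allocates the two related genotypes to different trials
        by_trial = best.plots.groupby("trial")["genotype"].apply(set)
        assert {"2", "3"} not in by_trial.values
        assert all("1" in s for s in by_trial)

    def test_trace_is_monotone_non_decreasing(self, pool):
        cfg = self._small_config(2)
        _, trace = optimize_design(list(pool.ids)[:10], 3, 2, pool, cfg)
        assert np.all(np.diff(trace) >= -1e-12)

    def test_same_seed_gives_identical_trace_and_design(self, pool):
        cfg = self._small_config(3)
        d1, t1 = optimize_design(list(pool.ids)[:10], 3, 2, pool, cfg)
        d2, t2 = optimize_design(list(pool.ids)[:10], 3, 2, pool, cfg)
        assert np.array_equal(t1, t2)
        pd.testing.assert_frame_equal(d1.plots, d2.plots)

    def test_beats_random_search_baseline(self, pool):
        ids = list(pool.ids)
        cfg = self._small_config(4)
        _, trace = optimize_design(ids, 5, 2, pool, cfg)
        rng = np.random.default_rng(4)
        baseline = max(
            objective(make_design("I", ids, 5, 2, seed=rng), cfg, pool)
            for _ in range(50)
        )
        assert trace[-1] >= baseline - 1e-9

    def test_within_trial_replication_never_occurs(self, pool):
        cfg = self._small_config(5)
        best, _ = optimize_design(list(pool.ids)[:8], 4, 2, pool, cfg)
        per_trial = best.plots.groupby(["trial", "genotype"]).size()
        assert (per_trial == 1).all()

    def test_infeasible_budget_is_rejected(self, pool):
        with pytest.raises(ValueError, match="candidates"):
            optimize_design(list(pool.ids)[:3], 4, 2, pool, self._small_config(6))


def test_enumeration_counts_designs_without_within_trial_replication():
    allocs = list(enumerate_allocations(3, 2, 2))
    assert len(allocs) == 9  # C(3,2)^2


def test_configuration_parameter_sets():
    for tag, rho in [("S", 1.0), ("W", 0.0), ("M", 0.5)]:
        cov = configuration_covariances(tag, 3)
        assert np.allclose(np.diag(cov.omega_G), 1.0)
        assert np.allclose(cov.sigma2_E, 1.0)
        off = cov.omega_G[~np.eye(3, dtype=bool)]
        assert np.allclose(off, rho)
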