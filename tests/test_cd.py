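"""CD criteria: published worked example, structure identities, both routes."""

import numpy as np
import pytest

from metcd import (
    KinshipMatrix,
    TrialCovariances,
    cd_mean,
    cd_mme,
    cd_trial,
    cd_with_structure,
)
from metcd.design_opt import configuration_covariances

from conftest import make_design, random_instance


class TestWorkedExample:
    def test_all_printed_values_reproduce(self, worked_example):
        K, cov = worked_example["K"], worked_example["cov"]
        for name, design in worked_example["designs"].items():
            per_trial = cd_trial(design, cov, K, known_fixed=True)
            mean_perf = cd_mean(design, cov, K, known_fixed=True)
            # half-up rounding to two decimals: a printed value of 0.13 admits
            # anything in [0.125, 0.135), so compare with a 0.005 band plus
            # an epsilon for the exact boundary case
            tol = 0.005 + 1e-9
            for i, gid in enumerate(design.candidates):
                e1, e2, em = worked_example["expected"][name][gid]
                assert per_trial[i, 0] == pytest.approx(e1, abs=tol), (name, gid)
                assert per_trial[i, 1] == pytest.approx(e2, abs=tol), (name, gid)
                assert mean_perf[i] == pytest.approx(em, abs=tol), (name, gid)

    def test_known_fixed_toggle_changes_values(self, worked_example):
        d = worked_example["designs"]["D"]
        a = cd_trial(d, worked_example["cov"], worked_example["K"], known_fixed=True)
        b = cd_trial(d, worked_example["cov"], worked_example["K"], known_fixed=False)
        assert np.max(np.abs(a - b)) > 0.01


def test_single_plot_known_mean_cd_equals_heritability():
    K = KinshipMatrix(["a"], [[1.0]])
    d = make_design([(1, 1, "a")], trials=("trial1",), candidates=("a",))
    for h2, s2g in [(0.2, 1.0), (0.5, 5.0), (0.8, 2.0)]:
        s2e = (1 - h2) / h2 * s2g
        cov = TrialCovariances([[s2g]], [[s2e]])
        assert cd_trial(d, cov, K, known_fixed=True)[0, 0] == pytest.approx(h2, abs=1e-12)
        assert cd_mean(d, cov, K, known_fixed=True)[0] == pytest.approx(h2, abs=1e-12)


def test_unobserved_unrelated_genotype_has_zero_cd(worked_example):
    d = worked_example["designs"]["A"]  # only genotype 1 observed; 2, 3 unrelated to it
    per_trial = cd_trial(d, worked_example["cov"], worked_example["K"], known_fixed=True)
    assert np.allclose(per_trial[1:], 0.0, atol=1e-12)


def test_single_trial_mean_cd_collapses_to_trial_cd():
    rng = np.random.default_rng(20)
    K, cov, design, _ = random_instance(rng, n=5, T=1)
    assert np.allclose(
        cd_mean(design, cov, K), cd_trial(design, cov, K)[:, 0], atol=1e-12
    )


class TestStructureIdentities:
    def test_standard_cd_is_one_number_per_genotype(self, worked_example):
        r = cd_with_structure("S", worked_example["designs"]["D"],
                              worked_example["cov"], worked_example["K"])
        assert np.allclose(r.per_trial[:, 0], r.per_trial[:, 1], atol=1e-10)
        assert np.allclose(r.per_trial[:, 0], r.mean_perf, atol=1e-10)

    def test_within_trial_mean_cd_is_average_under_equal_variances(self, worked_example):
        cov = configuration_covariances("W", 2)
        r = cd_with_structure("W", worked_example["designs"]["D"], cov, worked_example["K"])
        assert np.allclose(r.mean_perf, r.per_trial.mean(axis=1), atol=1e-10)

    def test_within_trial_mean_cd_is_variance_weighted_in_general(self, worked_example):
        # with unequal genetic variances CD_i. is the sigma2_G-weighted mean
        r = cd_with_structure("W", worked_example["designs"]["D"],
                              worked_example["cov"], worked_example["K"])
        s2g = np.diag(worked_example["cov"].omega_G)
        weighted = (r.per_trial * s2g).sum(axis=1) / s2g.sum()
        assert np.allclose(r.mean_perf, weighted, atol=1e-10)

    def test_multi_trial_mean_cd_exceeds_average_with_positive_correlation(self, worked_example):
        for name in ("C", "D"):
            r = cd_with_structure("M", worked_example["designs"][name],
                                  worked_example["cov"], worked_example["K"])
            nz = r.per_trial.mean(axis=1) > 1e-8
            assert np.all(r.mean_perf[nz] > r.per_trial.mean(axis=1)[nz])


class TestMMERoute:
    def test_worked_example_same_values_both_routes(self, worked_example):
        K, cov = worked_example["K"], worked_example["cov"]
        for design in worked_example["designs"].values():
            r = cd_mme(design, cov, K, known_fixed=True, structure="M")
            assert np.allclose(r.per_trial, cd_trial(design, cov, K, known_fixed=True), atol=1e-8)
            assert np.allclose(r.mean_perf, cd_mean(design, cov, K, known_fixed=True), atol=1e-8)

    @pytest.mark.parametrize("structure", ["S", "W", "M"])
    def test_random_instance_agreement(self, structure):
        rng = np.random.default_rng(21)
        for _ in range(5):
            K, cov, design, _ = random_instance(rng, n=6, T=3)
            direct = cd_with_structure(structure, design, cov, K)
            mme = cd_mme(design, cov, K, structure=structure)
            assert np.max(np.abs(direct.per_trial - mme.per_trial)) < 1e-8
            assert np.max(np.abs(direct.mean_perf - mme.mean_perf)) < 1e-8


class TestProperties:
    def test_values_lie_in_unit_interval(self):
        rng = np.random.default_rng(22)
        for _ in range(10):
            K, cov, design, _ = random_instance(rng, n=int(rng.integers(4, 9)),
                                                T=int(rng.integers(1, 4)))
            per_trial = cd_trial(design, cov, K)
            mean_perf = cd_mean(design, cov, K)
            assert np.all((per_trial >= -1e-10) & (per_trial <= 1 + 1e-10))
            assert np.all((mean_perf >= -1e-10) & (mean_perf <= 1 + 1e-10))

    def test_adding_a_plot_never_decreases_cd(self):
        rng = np.random.default_rng(23)
        for _ in range(8):
            K, cov, design, _ = random_instance(rng, n=6, T=2, plots_per_trial=2)
            base = cd_trial(design, cov, K, known_fixed=True)
            extra = design.plots.copy()
            t = rng.choice(design.trials)
            g = K.ids[int(rng.integers(6))]
            extra.loc[len(extra)] = {"trial": t, "plot": 99, "genotype": g}
            bigger = type(design)(design.trials, extra, design.candidates)
            more = cd_trial(bigger, cov, K, known_fixed=True)
            assert np.all(more >= base - 1e-9)

    def test_zero_variance_genotype_is_named(self, worked_example):
        K = KinshipMatrix(["1", "2"], [[1.0, 0.0], [0.0, 0.0]])
        d = make_design([(1, 1, "1")], trials=("trial1",), candidates=("1", "2"))
        cov = TrialCovariances([[1.0]], [[1.0]])
        with pytest.raises(ValueError, match="'2'"):
            cd_trial(d, cov, K)
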