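"""Covariance assembly, the M projector, and structure handling."""

import numpy as np
import pytest

from metcd import (
    KinshipMatrix,
    TrialCovariances,
    assemble_G,
    assemble_R,
    compute_M,
    exchangeable_covariances,
    structure_covariances,
)
from metcd.met_model import METDesign

from conftest import make_design


def kron_oracle(A, B):
    n, m = A.shape[0], B.shape[0]
    out = np.zeros((n * m, n * m))
    for t in range(n):
        for tp in range(n):
            for i in range(m):
                for k in range(m):
                    out[t * m + i, tp * m + k] = A[t, tp] * B[i, k]
    return out


class TestAssembleG:
    def test_cross_trial_cross_genotype_element(self, worked_example):
        G = assemble_G(worked_example["cov"].omega_G, worked_example["K"])
        # cov(g_{geno2,trial1}, g_{geno3,trial2}) = 0.7 * 0.5
        assert G[0 * 3 + 1, 1 * 3 + 2] == pytest.approx(0.35)

    def test_identity_between_trials_gives_block_diagonal(self, worked_example):
        K = worked_example["K"]
        G = assemble_G(np.eye(2), K)
        assert np.allclose(G[:3, :3], K.K)
        assert np.allclose(G[3:, 3:], K.K)
        assert np.allclose(G[:3, 3:], 0)

    def test_matches_four_index_loop(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(2, 2))
        A = A @ A.T
        B = rng.normal(size=(3, 3))
        B = B @ B.T
        assert np.allclose(assemble_G(A, B), kron_oracle(A, B), atol=1e-12)

    def test_psd_preserved(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            A = rng.normal(size=(2, 2))
            A = A @ A.T
            B = rng.normal(size=(4, 4))
            B = B @ B.T
            w = np.linalg.eigvalsh(assemble_G(A, B))
            assert w.min() >= -1e-8

    def test_genotype_permutation_conjugates_blocks(self, worked_example):
        K = worked_example["K"]
        omega = worked_example["cov"].omega_G
        perm = [2, 0, 1]
        Kp = KinshipMatrix([K.ids[i] for i in perm], K.K[np.ix_(perm, perm)])
        G = assemble_G(omega, K)
        Gp = assemble_G(omega, Kp)
        full = np.concatenate([np.array(perm), np.array(perm) + 3])
        assert np.allclose(Gp, G[np.ix_(full, full)], atol=1e-12)


class TestAssembleR:
    def test_worked_example_plot_variances(self, worked_example):
        d = worked_example["designs"]["A"]
        r = assemble_R(worked_example["cov"].omega_E, d)
        assert np.allclose(r, [1, 1, 2, 2])

    def test_single_trial_scalar(self):
        d = make_design([(1, p, "1") for p in range(1, 4)], trials=("trial1",))
        assert np.allclose(assemble_R(np.array([[4.0]]), d), [4, 4, 4])

    def test_unequal_plot_counts(self):
        d = make_design([(1, 1, "1"), (1, 2, "2"), (1, 3, "3"), (2, 1, "1")])
        r = assemble_R(np.diag([1.0, 3.0]), d)
        assert np.allclose(r, [1, 1, 1, 3])

    def test_nonpositive_error_variance_rejected(self, worked_example):
        with pytest.raises(ValueError, match="positive"):
            assemble_R(np.diag([1.0, 0.0]), worked_example["designs"]["A"])


class TestComputeM:
    def test_known_fixed_is_plain_inverse(self):
        assert np.allclose(compute_M(2 * np.eye(2), known_fixed=True), 0.5 * np.eye(2))

    def test_projector_annihilates_fixed_effects_and_is_sigma_idempotent(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            A = rng.normal(size=(6, 6))
            Sigma = A @ A.T + 6 * np.eye(6)
            X = np.kron(np.eye(2), np.ones((3, 1)))
            M = compute_M(Sigma, X)
            assert np.allclose(M @ X, 0, atol=1e-10)
            assert np.allclose(M @ Sigma @ M, M, atol=1e-10)

    def test_agrees_with_direct_formula(self):
        rng = np.random.default_rng(4)
        A = rng.normal(size=(6, 6))
        Sigma = A @ A.T + 6 * np.eye(6)
        X = np.kron(np.eye(2), np.ones((3, 1)))
        Si = np.linalg.inv(Sigma)
        direct = Si - Si @ X @ np.linalg.inv(X.T @ Si @ X) @ X.T @ Si
        assert np.allclose(compute_M(Sigma, X), direct, atol=1e-10)

    def test_rank_deficient_fixed_effects_named(self):
        Sigma = np.eye(4)
        X = np.zeros((4, 2))
        X[:, 0] = 1.0  # second column empty -> collinear/rank deficient
        with pytest.raises(np.linalg.LinAlgError, match="rank deficient"):
            compute_M(Sigma, X)


class TestStructures:
    def test_standard_structure_is_compound_with_full_correlation(self):
        cov = structure_covariances("S", [1.0, 1.0], T=2)
        assert np.allclose(cov.omega_G, np.ones((2, 2)))
        assert np.allclose(cov.omega_E, np.eye(2))
        assert np.allclose(cov.rho(), 1.0)

    def test_within_trial_structure_is_diagonal(self):
        cov = structure_covariances("W", [1.0, 2.0, 0.5, 0.5], T=2)
        assert np.allclose(cov.omega_G, np.diag([1.0, 2.0]))

    def test_unstructured_from_exchangeable_rho(self):
        cov = exchangeable_covariances(3, 1.0, sigma2_E=1.0, rho=0.5)
        off = cov.omega_G[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 0.5)

    @pytest.mark.parametrize(
        "structure,n_params", [("S", 2), ("W", 4), ("M", 5)]
    )
    def test_parameter_counts_enforced(self, structure, n_params):
        with pytest.raises(ValueError, match="parameters"):
            structure_covariances(structure, [1.0] * (n_params + 1), T=2)

    def test_non_psd_omega_rejected(self):
        with pytest.raises(ValueError, match="semidefinite"):
            TrialCovariances([[1, 2], [2, 1]], np.eye(2))

    def test_heritability_and_correlation_derivations(self):
        cov = exchangeable_covariances(2, [1.0, 2.0], rho=0.5, h2=[0.2, 0.8])
        assert np.allclose(cov.h2(), [0.2, 0.8])
        assert cov.rho()[0, 1] == pytest.approx(0.5)
        assert np.allclose(cov.sigma2_E, [4.0, 0.5])

    def test_restrict_matches_structure_invariants(self, worked_example):
        cov = worked_example["cov"]
        s = cov.restrict("S")
        assert len(np.unique(s.omega_G)) == 1
        w = cov.restrict("W")
        assert np.allclose(w.omega_G, np.diag(np.diag(cov.omega_G)))
        assert np.allclose(cov.restrict("M").omega_G, cov.omega_G)


class TestMETDesign:
    def test_duplicate_plot_ids_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            make_design([(1, 1, "1"), (1, 1, "2")])

    def test_unknown_genotype_rejected(self):
        with pytest.raises(ValueError, match="unknown genotypes"):
            make_design([(1, 1, "zz")])

    def test_incidence_marks_trial_major_entries(self, worked_example):
        d = worked_example["designs"]["D"]
        Z = d.incidence()
        # plots: t1(g1), t1(g2), t2(g1), t2(g3); columns t*3+i
        assert Z[0, 0] == 1 and Z[1, 1] == 1 and Z[2, 3] == 1 and Z[3, 5] == 1
        assert Z.sum() == 4
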