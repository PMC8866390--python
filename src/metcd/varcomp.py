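"""Variance-component estimation for the MET model.

Two estimation routes share one contract:

* ``method="gibbs"`` — a conjugate Gibbs sampler over (mu | rest),
  (g | rest), (Omega_G | rest) and (sigma2_E | rest).  Priors are weakly
  informative: an inverse-Wishart(T + 2, I) on an unstructured Omega_G,
  scaled-inverse-chi-square (df 3, scale anchored on the per-trial sample
  variance) on error variances and on per-trial genetic variances under the
  S / W structures.  Point estimates are posterior means of the retained
  draws (default chain: 10,000 iterations, 1,000 burn-in, thinning 5).
* ``method="reml"`` — direct restricted-maximum-likelihood maximization of
  the structure parameters (Cholesky-parameterized Omega_G, log error
  variances) by L-BFGS-B; deterministic and fast, used for cross-validation
  sweeps where chain-length costs would dominate.

Under structure ``S`` a single genetic effect per genotype is shared by all
trials; under ``W`` the trials are independent univariate GBLUPs estimated
jointly; ``M`` is the full unstructured model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._linalg import chol_psd, inv_psd, project_psd
from .met_model import METDesign, TrialCovariances, check_structure
from .relate import KinshipMatrix

__all__ = ["FittedMET", "fit_met", "structure_to_model", "read_phenotypes", "write_phenotypes"]


@dataclass
class FittedMET:
    """Fitted trial means and covariances with (optionally) posterior draws."""

    structure: str
    trials: Sequence[str]
    mu: np.ndarray
    cov: TrialCovariances
    samples: dict[str, np.ndarray] | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        if self.mu.shape != (len(self.trials),):
            raise ValueError("mu length must equal the number of trials")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python")
    df = df.rename(columns={"trial_id": "trial", "genotype_id": "genotype", "plot_id": "plot"})
    for col in ("genotype", "trial", "value"):
        if col not in df.columns:
            raise ValueError(f"phenotype file lacks column {col!r}")
    return df


def write_phenotypes(pheno: pd.DataFrame, path: str | Path) -> None:
    df = pheno.rename(columns={"trial": "trial_id", "genotype": "genotype_id", "plot": "plot_id"})
    df.to_csv(path, index=False)


def structure_to_model(structure: str, T: int = 2) -> dict[str, Any]:
    """Free-parameter layout and prior family for a structure tag."""
    check_structure(structure)
    if structure == "S":
        return {
            "structure": "S",
            "n_genetic_params": 1,
            "n_error_params": 1,
            "genetic_prior": "scaled-inv-chi2(df=3)",
            "error_prior": "scaled-inv-chi2(df=3)",
        }
    if structure == "W":
        return {
            "structure": "W",
            "n_genetic_params": T,
            "n_error_params": T,
            "genetic_prior": "scaled-inv-chi2(df=3) per trial",
            "error_prior": "scaled-inv-chi2(df=3) per trial",
        }
    return {
        "structure": "M",
        "n_genetic_params": T * (T + 1) // 2,
        "n_error_params": T,
        "genetic_prior": f"inverse-Wishart(df={T + 2}, scale=I)",
        "error_prior": "scaled-inv-chi2(df=3) per trial",
    }


# ---------------------------------------------------------------------------


@dataclass
class _Problem:
    """Phenotypes aligned to the observed-genotype submatrix of K."""

    trials: list[str]
    obs_ids: list[str]
    y: np.ndarray
    ti: np.ndarray  # trial index per plot
    gi: np.ndarray  # observed-genotype index per plot
    K: np.ndarray
    Kinv: np.ndarray

    @property
    def T(self) -> int:
        return len(self.trials)

    @property
    def n(self) -> int:
        return len(self.obs_ids)

    @property
    def counts(self) -> np.ndarray:
        c = np.zeros((self.T, self.n))
        np.add.at(c, (self.ti, self.gi), 1.0)
        return c


def _prepare(pheno: pd.DataFrame, K: KinshipMatrix, design: METDesign | None) -> _Problem:
    df = pheno.rename(columns={"trial_id": "trial", "genotype_id": "genotype"})
    df = df.dropna(subset=["value"])
    trials = list(design.trials) if design is not None else list(dict.fromkeys(df["trial"].astype(str)))
    obs_ids = list(dict.fromkeys(df["genotype"].astype(str)))
    counts = df.groupby(df["trial"].astype(str)).size()
    for t in trials:
        if counts.get(t, 0) < 2:
            raise ValueError(f"trial {t!r} has fewer than 2 observations")
    tpos = {t: k for k, t in enumerate(trials)}
    gpos = {g: i for i, g in enumerate(obs_ids)}
    ti = np.array([tpos[str(t)] for t in df["trial"]])
    gi = np.array([gpos[str(g)] for g in df["genotype"]])
    y = df["value"].to_numpy(dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("phenotypes must be finite")
    Ksub = K.subset(obs_ids)
    return _Problem(trials, obs_ids, y, ti, gi, Ksub.K, inv_psd(Ksub.K))


def fit_met(
    pheno: pd.DataFrame,
    K: KinshipMatrix,
    design: METDesign | None = None,
    structure: str = "M",
    *,
    method: str = "gibbs",
    iterations: int = 10_000,
    burn_in: int = 1_000,
    thinning: int = 5,
    seed: int | np.random.Generator | None = None,
) -> FittedMET:
    """Estimate trial means and (co)variances under a model structure.

    ``design`` is optional: the phenotype table itself carries the
    allocation; when given it fixes the trial ordering.
    """
    check_structure(structure)
    prob = _prepare(pheno, K, design)
    if method == "reml":
        return _fit_reml(prob, structure)
    if method != "gibbs":
        raise ValueError(f"unknown method {method!r}; expected 'gibbs' or 'reml'")
    if min(iterations, thinning) < 1 or burn_in < 0 or burn_in >= iterations:
        raise ValueError("chain configuration must satisfy 0 <= burn_in < iterations, thinning >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _fit_gibbs(prob, structure, iterations, burn_in, thinning, rng)


# ---------------------------------------------------------------------------
# Gibbs sampler


def _trial_sample_var(prob: _Problem) -> np.ndarray:
    v = np.empty(prob.T)
    for t in range(prob.T):
        v[t] = np.var(prob.y[prob.ti == t], ddof=1)
    return np.maximum(v, 1e-8)


def _draw_mvn_prec(C: np.ndarray, rhs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw from N(C^-1 rhs, C^-1) given the precision matrix C."""
    from scipy import linalg as sla

    L = chol_psd(C)  # lower
    mean = sla.cho_solve((L, True), rhs)
    z = rng.standard_normal(len(rhs))
    return mean + sla.solve_triangular(L, z, trans="T", lower=True)


def _fit_gibbs(
    prob: _Problem,
    structure: str,
    iterations: int,
    burn_in: int,
    thinning: int,
    rng: np.random.Generator,
) -> FittedMET:
    T, n = prob.T, prob.n
    y, ti, gi = prob.y, prob.ti, prob.gi
    counts = prob.counts
    P_t = counts.sum(axis=1)
    vary = _trial_sample_var(prob)

    # priors
    nu_e, s0_e = 3.0, vary.copy()
    nu_g, s0_g = 3.0, vary / 2.0
    nu_w = T + 2  # inverse-Wishart df for structure M

    # state
    mu = np.array([y[ti == t].mean() for t in range(T)])
    s2e = vary / 2.0
    gmat = np.zeros((n, T))
    omega = np.diag(vary / 2.0)
    s2g_scalar = float(np.mean(vary)) / 2.0

    n_keep = (iterations - burn_in) // thinning
    keep_mu = np.empty((n_keep, T))
    keep_og = np.empty((n_keep, T, T))
    keep_oe = np.empty((n_keep, T))
    k = 0

    for it in range(iterations):
        # --- trial means
        resid_mu = y - gmat[gi, ti]
        for t in range(T):
            m = resid_mu[ti == t].mean()
            mu[t] = m + rng.standard_normal() * np.sqrt(s2e[t] / P_t[t])
        r = y - mu[ti]

        # --- genetic values
        if structure == "S":
            rhs = np.zeros(n)
            np.add.at(rhs, gi, r / s2e[ti])
            prec_diag = np.zeros(n)
            np.add.at(prec_diag, gi, 1.0 / s2e[ti])
            C = np.diag(prec_diag) + prob.Kinv / s2g_scalar
            a = _draw_mvn_prec(C, rhs, rng)
            gmat = np.repeat(a[:, None], T, axis=1)
        else:
            og_use = np.diag(np.diag(omega)) if structure == "W" else omega
            prior = np.kron(inv_psd(og_use), prob.Kinv)
            flat = ti * n + gi
            rhs = np.zeros(n * T)
            np.add.at(rhs, flat, r / s2e[ti])
            prec_diag = np.zeros(n * T)
            np.add.at(prec_diag, flat, 1.0 / s2e[ti])
            C = prior + np.diag(prec_diag)
            gflat = _draw_mvn_prec(C, rhs, rng)
            gmat = gflat.reshape(T, n).T

        # --- genetic covariance
        if structure == "S":
            a = gmat[:, 0]
            sc = nu_g * float(np.mean(s0_g)) + float(a @ prob.Kinv @ a)
            s2g_scalar = sc / rng.chisquare(nu_g + n)
            omega = np.full((T, T), s2g_scalar)
        elif structure == "W":
            d = np.empty(T)
            for t in range(T):
                gt = gmat[:, t]
                sc = nu_g * s0_g[t] + float(gt @ prob.Kinv @ gt)
                d[t] = sc / rng.chisquare(nu_g + n)
            omega = np.diag(d)
        else:
            Sg = gmat.T @ prob.Kinv @ gmat
            omega = stats.invwishart.rvs(df=nu_w + n, scale=np.eye(T) + Sg, random_state=rng)
            omega = np.atleast_2d(omega)

        # --- error variances
        e = r - gmat[gi, ti]
        if structure == "S":
            sse = float(e @ e)
            s2e[:] = (nu_e * float(np.mean(s0_e)) + sse) / rng.chisquare(nu_e + len(y))
        else:
            for t in range(T):
                et = e[ti == t]
                s2e[t] = (nu_e * s0_e[t] + float(et @ et)) / rng.chisquare(nu_e + P_t[t])

        if not (np.isfinite(mu).all() and np.isfinite(omega).all() and np.isfinite(s2e).all()):
            raise FloatingPointError(f"divergent chain: non-finite draw at iteration {it}")

        if it >= burn_in and (it - burn_in) % thinning == 0 and k < n_keep:
            keep_mu[k] = mu
            keep_og[k] = omega
            keep_oe[k] = s2e
            k += 1

    og_mean = project_psd(keep_og[:k].mean(axis=0))
    cov = TrialCovariances(og_mean, np.diag(keep_oe[:k].mean(axis=0)))
    return FittedMET(
        structure=structure,
        trials=prob.trials,
        mu=keep_mu[:k].mean(axis=0),
        cov=cov,
        samples={"mu": keep_mu[:k], "omega_G": keep_og[:k], "omega_E": keep_oe[:k]},
        meta={
            "method": "gibbs",
            "iterations": iterations,
            "burn_in": burn_in,
            "thinning": thinning,
            "n_samples": int(k),
        },
    )


# ---------------------------------------------------------------------------
# REML fast path


def _sigma_obs(prob: _Problem, omega_G: np.ndarray, s2e: np.ndarray) -> np.ndarray:
    Kp = prob.K[np.ix_(prob.gi, prob.gi)]
    Sigma = omega_G[np.ix_(prob.ti, prob.ti)] * Kp
    Sigma[np.diag_indices_from(Sigma)] += s2e[prob.ti]
    return Sigma


def _unpack_theta(theta: np.ndarray, structure: str, T: int) -> tuple[np.ndarray, np.ndarray]:
    if structure == "S":
        s2g, s2e = np.exp(theta)
        return np.full((T, T), s2g), np.full(T, s2e)
    if structure == "W":
        return np.diag(np.exp(theta[:T])), np.exp(theta[T:])
    n_tri = T * (T + 1) // 2
    L = np.zeros((T, T))
    idx = np.tril_indices(T)
    L[idx] = theta[:n_tri]
    L[np.diag_indices(T)] = np.exp(np.diag(L))
    return L @ L.T, np.exp(theta[n_tri:])


def _neg_reml(theta: np.ndarray, prob: _Problem, structure: str) -> float:
    from scipy import linalg as sla

    omega_G, s2e = _unpack_theta(theta, structure, prob.T)
    if np.any(~np.isfinite(omega_G)) or np.any(~np.isfinite(s2e)):
        return 1e30
    Sigma = _sigma_obs(prob, omega_G, s2e)
    try:
        L = sla.cholesky(Sigma, lower=True)
    except sla.LinAlgError:
        return 1e30
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    X = np.zeros((len(prob.y), prob.T))
    X[np.arange(len(prob.y)), prob.ti] = 1.0
    SiX = sla.cho_solve((L, True), X)
    Siy = sla.cho_solve((L, True), prob.y)
    A = X.T @ SiX
    sign, logdetA = np.linalg.slogdet(A)
    if sign <= 0:
        return 1e30
    beta = np.linalg.solve(A, X.T @ Siy)
    quad = float(prob.y @ Siy - (X.T @ Siy) @ beta)
    return 0.5 * (logdet + logdetA + quad)


def _init_theta(prob: _Problem, structure: str) -> np.ndarray:
    vary = _trial_sample_var(prob)
    if structure == "S":
        return np.log([float(np.mean(vary)) / 2.0, float(np.mean(vary)) / 2.0])
    if structure == "W":
        return np.concatenate([np.log(vary / 2.0), np.log(vary / 2.0)])
    T = prob.T
    s = np.sqrt(vary / 2.0)
    omega0 = 0.3 * np.outer(s, s)
    np.fill_diagonal(omega0, vary / 2.0)
    L = np.linalg.cholesky(omega0)
    L[np.diag_indices(T)] = np.log(np.diag(L))
    return np.concatenate([L[np.tril_indices(T)], np.log(vary / 2.0)])


def _fit_reml(prob: _Problem, structure: str) -> FittedMET:
    theta0 = _init_theta(prob, structure)
    res = optimize.minimize(
        _neg_reml,
        theta0,
        args=(prob, structure),
        method="L-BFGS-B",
        options={"maxiter": 300, "ftol": 1e-10},
    )
    omega_G, s2e = _unpack_theta(res.x, structure, prob.T)
    # GLS trial means at the optimum
    Sigma = _sigma_obs(prob, omega_G, s2e)
    X = np.zeros((len(prob.y), prob.T))
    X[np.arange(len(prob.y)), prob.ti] = 1.0
    from scipy import linalg as sla

    L = chol_psd(Sigma)
    SiX = sla.cho_solve((L, True), X)
    mu = np.linalg.solve(X.T @ SiX, SiX.T @ prob.y)
    cov = TrialCovariances(project_psd(omega_G), np.diag(s2e))
    return FittedMET(
        structure=structure,
        trials=prob.trials,
        mu=mu,
        cov=cov,
        samples=None,
        meta={"method": "reml", "converged": bool(res.success), "neg_reml": float(res.fun)},
    )
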