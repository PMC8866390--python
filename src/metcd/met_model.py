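"""Multi-environment-trial (MET) mixed model: data structures and covariances.

The model for a trait observed in T trials is

    y = X beta + Z g + e,      g ~ N(0, G),   e ~ N(0, R),

with y the plot phenotypes stacked trial by trial, beta = (mu_1, ..., mu_T)
the fixed trial means, and g the stacked trial-specific genetic values.  The
genetic covariance factorizes as a Kronecker product ``G = Omega_G (x) K``
over a T x T between-trial genetic covariance Omega_G and the N x N genomic
relationship matrix K; the error covariance is diagonal with trial-specific
variances (``R = Omega_E (x) I_P`` when every trial has the same number of
plots P, and the obvious per-plot generalization otherwise).

Stacking convention: **trial-major** — entry (t, i) of g sits at flat index
``t * N + i``, matching Omega_G on the left of the Kronecker product.

Three named structures of (Omega_G, Omega_E) correspond to the classical
GBLUP variants for METs:

* ``S`` (standard GBLUP): one genetic variance shared by all trials and a
  between-trial genetic correlation of 1; a single error variance.
* ``W`` (within-trial GBLUP): trial-specific variances, zero genetic
  correlation between trials — equivalent to fitting each trial alone.
* ``M`` (multi-trial GBLUP): unstructured Omega_G, trial-specific error
  variances — the full genotype-by-environment model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._linalg import inv_psd, project_psd
from .relate import KinshipMatrix

__all__ = [
    "METDesign",
    "TrialCovariances",
    "ModelStructure",
    "ModelMatrices",
    "assemble_G",
    "assemble_R",
    "compute_M",
    "structure_covariances",
    "exchangeable_covariances",
    "read_design",
    "write_design",
    "VALID_STRUCTURES",
]

VALID_STRUCTURES = ("S", "W", "M")
ModelStructure = str  # one of VALID_STRUCTURES


def check_structure(structure: str) -> str:
    if structure not in VALID_STRUCTURES:
        raise ValueError(f"unknown model structure {structure!r}; expected one of {VALID_STRUCTURES}")
    return structure


@dataclass
class METDesign:
    """Allocation of genotypes to plots within T trials.

    ``plots`` has one row per observed plot with columns ``trial``, ``plot``
    and ``genotype``.  ``candidates`` is the full genotype universe
    (a superset of the allocated ids); predictions and CDs are computed for
    every candidate, observed or not.
    """

    trials: Sequence[str]
    plots: pd.DataFrame
    candidates: Sequence[str]

    def __post_init__(self) -> None:
        self.trials = [str(t) for t in self.trials]
        if len(set(self.trials)) != len(self.trials):
            raise ValueError("duplicate trial ids")
        if len(self.trials) < 1:
            raise ValueError("at least one trial is required")
        self.candidates = [str(g) for g in self.candidates]
        if len(set(self.candidates)) != len(self.candidates):
            raise ValueError("duplicate candidate ids")
        df = pd.DataFrame(self.plots)
        for col in ("trial", "plot", "genotype"):
            if col not in df.columns:
                raise ValueError(f"plot table lacks column {col!r}")
        df = df[["trial", "plot", "genotype"]].copy()
        df["trial"] = df["trial"].astype(str)
        df["genotype"] = df["genotype"].astype(str)
        unknown_t = sorted(set(df["trial"]) - set(self.trials))
        if unknown_t:
            raise ValueError(f"plots reference unknown trials: {unknown_t}")
        unknown_g = sorted(set(df["genotype"]) - set(self.candidates))
        if unknown_g:
            raise ValueError(f"plots reference unknown genotypes: {unknown_g[:5]}")
        if df.duplicated(["trial", "plot"]).any():
            raise ValueError("plot indices must be unique within a trial")
        # canonical plot order: trial-major, then plot index
        order = {t: k for k, t in enumerate(self.trials)}
        df = df.sort_values(["trial", "plot"], key=lambda s: s.map(order) if s.name == "trial" else s)
        self.plots = df.reset_index(drop=True)

    @property
    def T(self) -> int:
        return len(self.trials)

    @property
    def n_plots(self) -> int:
        return len(self.plots)

    def plot_counts(self) -> np.ndarray:
        """Observed plots per trial, in trial order (zeros allowed)."""
        c = self.plots["trial"].value_counts()
        return np.array([int(c.get(t, 0)) for t in self.trials])

    def plot_entries(self, ids: Sequence[str] | None = None) -> np.ndarray:
        """For each plot (canonical order) the flat index t*N+i of its genetic value."""
        ids = self.candidates if ids is None else [str(g) for g in ids]
        gpos = {g: i for i, g in enumerate(ids)}
        tpos = {t: k for k, t in enumerate(self.trials)}
        n = len(ids)
        try:
            return np.array(
                [tpos[t] * n + gpos[g] for t, g in zip(self.plots["trial"], self.plots["genotype"])],
                dtype=int,
            )
        except KeyError as e:  # pragma: no cover - guarded in __post_init__
            raise KeyError(f"genotype/trial not in index: {e}") from None

    def incidence(self, ids: Sequence[str] | None = None) -> np.ndarray:
        """Incidence matrix Z (plots x N*T) linking plots to genetic values."""
        ids = self.candidates if ids is None else list(ids)
        entries = self.plot_entries(ids)
        Z = np.zeros((self.n_plots, len(ids) * self.T))
        Z[np.arange(self.n_plots), entries] = 1.0
        return Z

    def fixed_effects(self) -> np.ndarray:
        """Design matrix X of trial intercepts (plots x T)."""
        tpos = {t: k for k, t in enumerate(self.trials)}
        X = np.zeros((self.n_plots, self.T))
        X[np.arange(self.n_plots), [tpos[t] for t in self.plots["trial"]]] = 1.0
        return X

    def observed_ids(self) -> list[str]:
        seen = dict.fromkeys(self.plots["genotype"])
        return list(seen)

    def fingerprint(self) -> str:
        """Stable identifier of the allocation (order-insensitive within trials)."""
        items = sorted(zip(self.plots["trial"], self.plots["plot"], self.plots["genotype"]))
        return f"{hash(tuple(items)) & 0xFFFFFFFF:08x}"


@dataclass
class TrialCovariances:
    """Between-trial genetic covariance Omega_G and diagonal error covariance Omega_E."""

    omega_G: np.ndarray
    omega_E: np.ndarray

    def __post_init__(self) -> None:
        self.omega_G = np.atleast_2d(np.asarray(self.omega_G, dtype=float))
        omega_E = np.asarray(self.omega_E, dtype=float)
        if omega_E.ndim == 1:
            omega_E = np.diag(omega_E)
        self.omega_E = omega_E
        T = self.omega_G.shape[0]
        if self.omega_G.shape != (T, T) or self.omega_E.shape != (T, T):
            raise ValueError("omega_G and omega_E must be square with equal dimension")
        if np.max(np.abs(self.omega_G - self.omega_G.T)) > 1e-8 * max(1.0, np.max(np.abs(self.omega_G))):
            raise ValueError("omega_G must be symmetric")
        if np.any(np.abs(self.omega_E - np.diag(np.diag(self.omega_E))) > 0):
            raise ValueError("omega_E must be diagonal")
        if np.any(np.diag(self.omega_E) <= 0):
            raise ValueError("error variances must be strictly positive")
        w = np.linalg.eigvalsh(0.5 * (self.omega_G + self.omega_G.T))
        if w.min() < -1e-8 * max(1.0, w.max()):
            raise ValueError("omega_G must be positive semidefinite")

    @property
    def T(self) -> int:
        return self.omega_G.shape[0]

    @property
    def sigma2_G(self) -> np.ndarray:
        return np.diag(self.omega_G).copy()

    @property
    def sigma2_E(self) -> np.ndarray:
        return np.diag(self.omega_E).copy()

    def rho(self) -> np.ndarray:
        """Between-trial genetic correlation matrix."""
        s = np.sqrt(self.sigma2_G)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = self.omega_G / np.outer(s, s)
        return r

    def h2(self) -> np.ndarray:
        """Per-plot heritability sigma2_G / (sigma2_G + sigma2_E), per trial."""
        g, e = self.sigma2_G, self.sigma2_E
        return g / (g + e)

    def restrict(self, structure: str) -> "TrialCovariances":
        """Reshape to a named structure (S: pooled variances, rho=1; W: rho=0; M: as-is)."""
        check_structure(structure)
        if structure == "M":
            return TrialCovariances(self.omega_G.copy(), self.omega_E.copy())
        if structure == "W":
            return TrialCovariances(np.diag(self.sigma2_G), self.omega_E.copy())
        s2g = float(np.mean(self.sigma2_G))
        s2e = float(np.mean(self.sigma2_E))
        return TrialCovariances(np.full((self.T, self.T), s2g), s2e * np.eye(self.T))


def exchangeable_covariances(
    T: int,
    sigma2_G: float | Sequence[float],
    sigma2_E: float | Sequence[float] | None = None,
    rho: float = 0.0,
    h2: float | Sequence[float] | None = None,
) -> TrialCovariances:
    """Covariances with a common genetic correlation ``rho`` between all trial pairs.

    Either ``sigma2_E`` or per-trial heritabilities ``h2`` (from which
    sigma2_E = (1 - h2) / h2 * sigma2_G) must be given.
    """
    s2g = np.broadcast_to(np.asarray(sigma2_G, dtype=float), (T,)).copy()
    if (sigma2_E is None) == (h2 is None):
        raise ValueError("give exactly one of sigma2_E or h2")
    if h2 is not None:
        h = np.broadcast_to(np.asarray(h2, dtype=float), (T,))
        if np.any((h <= 0) | (h >= 1)):
            raise ValueError("h2 must lie in (0, 1)")
        s2e = (1.0 - h) / h * s2g
    else:
        s2e = np.broadcast_to(np.asarray(sigma2_E, dtype=float), (T,)).copy()
    s = np.sqrt(s2g)
    omega_G = rho * np.outer(s, s)
    np.fill_diagonal(omega_G, s2g)
    return TrialCovariances(omega_G, np.diag(s2e))


def structure_covariances(structure: str, params: Sequence[float], T: int) -> TrialCovariances:
    """Build TrialCovariances from a flat parameter vector under a structure.

    Parameter layout: ``S``: (sigma2_G, sigma2_E); ``W``: (sigma2_G_1..T,
    sigma2_E_1..T); ``M``: lower triangle of Omega_G row by row
    (T(T+1)/2 values) followed by the T error variances.
    """
    check_structure(structure)
    params = np.asarray(params, dtype=float)
    if structure == "S":
        if params.shape != (2,):
            raise ValueError("structure S takes exactly 2 parameters")
        return TrialCovariances(np.full((T, T), params[0]), params[1] * np.eye(T))
    if structure == "W":
        if params.shape != (2 * T,):
            raise ValueError(f"structure W takes exactly {2 * T} parameters")
        return TrialCovariances(np.diag(params[:T]), np.diag(params[T:]))
    n_tri = T * (T + 1) // 2
    if params.shape != (n_tri + T,):
        raise ValueError(f"structure M takes exactly {n_tri + T} parameters")
    omega_G = np.zeros((T, T))
    omega_G[np.tril_indices(T)] = params[:n_tri]
    omega_G = omega_G + np.tril(omega_G, -1).T
    return TrialCovariances(omega_G, np.diag(params[n_tri:]))


# ---------------------------------------------------------------------------
# covariance assembly


def assemble_G(omega_G: np.ndarray, K: KinshipMatrix | np.ndarray) -> np.ndarray:
    """NT x NT genetic covariance ``Omega_G (x) K`` in trial-major block order."""
    Km = K.K if isinstance(K, KinshipMatrix) else np.asarray(K, dtype=float)
    omega_G = np.atleast_2d(np.asarray(omega_G, dtype=float))
    if omega_G.shape[0] != omega_G.shape[1] or Km.shape[0] != Km.shape[1]:
        raise ValueError("omega_G and K must both be square")
    return np.kron(omega_G, Km)


def assemble_R(omega_E: np.ndarray, design: METDesign) -> np.ndarray:
    """Per-plot error variances (diagonal of R) in canonical plot order.

    Each plot of trial t receives sigma2_E_t; with equal plot counts this is
    the Kronecker form ``Omega_E (x) I_P``, and it generalizes naturally to
    unbalanced designs.
    """
    omega_E = np.asarray(omega_E, dtype=float)
    if omega_E.ndim == 2:
        omega_E = np.diag(omega_E)
    if omega_E.shape != (design.T,):
        raise ValueError("omega_E dimension does not match the number of trials")
    if np.any(omega_E <= 0):
        raise ValueError("error variances must be strictly positive")
    tpos = {t: k for k, t in enumerate(design.trials)}
    return omega_E[[tpos[t] for t in design.plots["trial"]]]


def compute_M(Sigma: np.ndarray, X: np.ndarray | None = None, known_fixed: bool = False) -> np.ndarray:
    """The projector M of the BLUP and CD formulas.

    With known fixed effects M = Sigma^-1; otherwise
    M = Sigma^-1 - Sigma^-1 X (X' Sigma^-1 X)^-1 X' Sigma^-1, which satisfies
    M Sigma M = M and M X = 0.
    """
    Si = inv_psd(np.asarray(Sigma, dtype=float))
    if known_fixed:
        return Si
    if X is None:
        raise ValueError("X is required when fixed effects are estimated")
    X = np.asarray(X, dtype=float)
    XtSi = X.T @ Si
    A = XtSi @ X
    rank = np.linalg.matrix_rank(A)
    if rank < X.shape[1]:
        empty = [j for j in range(X.shape[1]) if not np.any(X[:, j])]
        detail = f" (columns with no observations: {empty})" if empty else ""
        raise np.linalg.LinAlgError(
            f"X' Sigma^-1 X is rank deficient ({rank} < {X.shape[1]}){detail}"
        )
    return Si - XtSi.T @ np.linalg.solve(A, XtSi)


@dataclass
class ModelMatrices:
    """All dense matrices of the MET model for one design + covariance pair."""

    G: np.ndarray = field(repr=False)
    R: np.ndarray = field(repr=False)  # diagonal entries, length = n_plots
    Z: np.ndarray = field(repr=False)
    X: np.ndarray = field(repr=False)
    Sigma: np.ndarray = field(repr=False)
    M: np.ndarray = field(repr=False)
    known_fixed: bool = False

    @classmethod
    def build(
        cls,
        cov: TrialCovariances,
        K: KinshipMatrix,
        design: METDesign,
        known_fixed: bool = False,
    ) -> "ModelMatrices":
        if cov.T != design.T:
            raise ValueError("covariance and design disagree on the number of trials")
        Ksub = K.subset(design.candidates)
        G = assemble_G(cov.omega_G, Ksub)
        r = assemble_R(cov.omega_E, design)
        Z = design.incidence()
        X = design.fixed_effects()
        Sigma = Z @ G @ Z.T + np.diag(r)
        M = compute_M(Sigma, X, known_fixed=known_fixed)
        return cls(G=G, R=r, Z=Z, X=X, Sigma=Sigma, M=M, known_fixed=known_fixed)


def posterior_mean_covariances(omega_G: np.ndarray, omega_E: np.ndarray) -> TrialCovariances:
    """Project an averaged Omega_G onto the PSD cone and package it."""
    return TrialCovariances(project_psd(omega_G), np.diag(np.diag(omega_E)))


# ---------------------------------------------------------------------------
# design file plumbing


def read_design(path: str | Path, candidates: Sequence[str] | None = None) -> METDesign:
    """Read a design table (columns trial_id/plot_id/genotype_id or trial/plot/genotype)."""
    df = pd.read_csv(path, sep=None, engine="python")
    df = df.rename(
        columns={"trial_id": "trial", "plot_id": "plot", "genotype_id": "genotype"}
    )
    trials = list(dict.fromkeys(df["trial"].astype(str)))
    geno = list(dict.fromkeys(df["genotype"].astype(str)))
    if candidates is None:
        candidates = geno
    return METDesign(trials, df, candidates)


def write_design(design: METDesign, path: str | Path) -> None:
    out = design.plots.rename(
        columns={"trial": "trial_id", "plot": "plot_id", "genotype": "genotype_id"}
    )
    out.to_csv(path, index=False)
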