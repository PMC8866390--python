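"""BLUPs of trial-specific genetic values and mean performance.

Two numerically equivalent routes are provided:

* the phenotype-covariance route ``g_hat = G Z' M y`` (dimension = number of
  plots), and
* Henderson's mixed-model equations (dimension = N*T genetic values plus T
  trial means), preferable when the design has more plots than there are
  genetic values to predict.

Predictions are returned for the complete candidate universe of the design,
including genotypes never observed in any trial — those are predicted purely
through their relatedness to observed genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._linalg import inv_psd, solve_psd
from .met_model import METDesign, ModelMatrices, TrialCovariances, assemble_R
from .relate import KinshipMatrix

__all__ = ["GeneticValues", "blup", "blup_mme", "predicted_performance", "write_genetic_values"]


@dataclass
class GeneticValues:
    """N x T matrix of trial-specific genetic values (deviations from trial means)."""

    ids: Sequence[str]
    trials: Sequence[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.ids = [str(g) for g in self.ids]
        self.trials = [str(t) for t in self.trials]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids), len(self.trials)):
            raise ValueError(
                f"values must be {len(self.ids)}x{len(self.trials)}, got {self.values.shape}"
            )

    @property
    def mean(self) -> np.ndarray:
        """Mean genetic value over trials, per genotype."""
        return self.values.mean(axis=1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=list(self.ids), columns=list(self.trials))
        df["mean"] = self.mean
        return df


def _phenotype_vector(pheno: pd.DataFrame, design: METDesign) -> np.ndarray:
    """Align a long phenotype table to the design's canonical plot order."""
    df = pheno.rename(columns={"trial_id": "trial", "genotype_id": "genotype", "plot_id": "plot"})
    y = np.empty(design.n_plots)
    if "plot" in df.columns and df["plot"].notna().all():
        key = {
            (str(t), str(p)): float(v)
            for t, p, v in zip(df["trial"], df["plot"], df["value"])
        }
        for k, (t, p) in enumerate(zip(design.plots["trial"], design.plots["plot"])):
            try:
                y[k] = key[(str(t), str(p))]
            except KeyError:
                raise ValueError(f"no phenotype for trial {t!r} plot {p!r}") from None
    else:
        # match by (trial, genotype); requires unique pairs
        if df.duplicated(["trial", "genotype"]).any():
            raise ValueError("phenotypes without plot ids must be unique per (trial, genotype)")
        key = {
            (str(t), str(g)): float(v)
            for t, g, v in zip(df["trial"], df["genotype"], df["value"])
        }
        for k, (t, g) in enumerate(zip(design.plots["trial"], design.plots["genotype"])):
            try:
                y[k] = key[(str(t), str(g))]
            except KeyError:
                raise ValueError(f"no phenotype for trial {t!r} genotype {g!r}") from None
    if not np.isfinite(y).all():
        raise ValueError("phenotypes must be finite")
    return y


def _unpack_fit(fitted) -> tuple[TrialCovariances, np.ndarray | None]:
    if isinstance(fitted, TrialCovariances):
        return fitted, None
    return fitted.cov, np.asarray(fitted.mu, dtype=float)


def blup(
    pheno: pd.DataFrame,
    fitted,
    K: KinshipMatrix,
    design: METDesign,
    known_fixed: bool = False,
) -> GeneticValues:
    """BLUPs ``g_hat = G Z' M y`` for all candidates in all trials.

    ``fitted`` is a FittedMET (supplies covariances and trial means) or a
    TrialCovariances.  With ``known_fixed`` the trial means must be available
    and M = Sigma^-1 is applied to the mean-centered phenotypes; otherwise
    the projector M absorbs the estimation of trial means.
    """
    cov, mu = _unpack_fit(fitted)
    mm = ModelMatrices.build(cov, K, design, known_fixed=known_fixed)
    y = _phenotype_vector(pheno, design)
    if known_fixed:
        if mu is None:
            raise ValueError("known_fixed requires trial means (pass a FittedMET)")
        y = y - mm.X @ mu
    g = mm.G @ mm.Z.T @ (mm.M @ y)
    values = g.reshape(design.T, len(design.candidates)).T
    return GeneticValues(design.candidates, design.trials, values)


def _psd_eigenbasis(a: np.ndarray, what: str) -> tuple[np.ndarray, np.ndarray]:
    """Positive eigencomponents of a PSD matrix (null space removed).

    Rank-deficient factors — the S structure's all-ones Omega_G, or a
    kinship matrix with duplicated lines — are handled by rotating the
    genetic effects into the span of the factor: with Omega_G = Q_g W_g Q_g'
    and K = Q_k W_k Q_k', the stacked values are g = (Q_g (x) Q_k) b with
    independent prior variances W_g (x) W_k, which keeps the mixed-model
    coefficient matrix well conditioned and the solution exact.
    """
    w, Q = np.linalg.eigh(0.5 * (a + a.T))
    keep = w > 1e-10 * max(w.max(), 1.0)
    if not keep.any():
        raise ValueError(f"{what} has no positive eigenvalue")
    return w[keep], Q[:, keep]


def mme_solve(
    cov: TrialCovariances,
    K: KinshipMatrix,
    design: METDesign,
    y: np.ndarray | None = None,
    known_fixed: bool = False,
    want_pev: bool = False,
) -> tuple[np.ndarray | None, np.ndarray | None]:
    """Henderson mixed-model equations in the eigenbasis of Omega_G.

    Returns ``(g_hat, Cgg)`` where ``g_hat`` (length N*T, trial-major) is
    None when no phenotype vector is given, and ``Cgg`` is the full N*T
    prediction error covariance Var(g_hat - g) when ``want_pev``.
    ``y`` must already have known fixed effects subtracted when
    ``known_fixed`` is set.
    """
    Ksub = K.subset(design.candidates)
    n, T = Ksub.n, design.T
    wg, Qg = _psd_eigenbasis(cov.omega_G, "omega_G")
    wk, Qk = _psd_eigenbasis(Ksub.K, "kinship")
    prior = np.diag(1.0 / np.kron(wg, wk))
    r = assemble_R(cov.omega_E, design)
    Z = design.incidence()
    rot = np.kron(Qg, Qk)  # (T*N) x (rank_g*rank_k)
    Zb = Z @ rot
    ZtRi = Zb.T / r
    if known_fixed:
        C = ZtRi @ Zb + prior
        if want_pev:
            Cbb = inv_psd(C)
            g = rot @ (Cbb @ (ZtRi @ y)) if y is not None else None
            return g, rot @ Cbb @ rot.T
        g = rot @ solve_psd(C, ZtRi @ y) if y is not None else None
        return g, None
    X = design.fixed_effects()
    XtRi = X.T / r
    C = np.block([[XtRi @ X, XtRi @ Zb], [ZtRi @ X, ZtRi @ Zb + prior]])
    if want_pev:
        Cinv = inv_psd(C)
        g = None
        if y is not None:
            sol = Cinv @ np.concatenate([XtRi @ y, ZtRi @ y])
            g = rot @ sol[T:]
        return g, rot @ Cinv[T:, T:] @ rot.T
    if y is None:
        return None, None
    sol = solve_psd(C, np.concatenate([XtRi @ y, ZtRi @ y]))
    return rot @ sol[T:], None


def blup_mme(
    pheno: pd.DataFrame,
    fitted,
    K: KinshipMatrix,
    design: METDesign,
    known_fixed: bool = False,
) -> GeneticValues:
    """BLUPs through Henderson's mixed-model equations (same contract as :func:`blup`)."""
    cov, mu = _unpack_fit(fitted)
    if cov.T != design.T:
        raise ValueError("covariance and design disagree on the number of trials")
    y = _phenotype_vector(pheno, design)
    if known_fixed:
        if mu is None:
            raise ValueError("known_fixed requires trial means (pass a FittedMET)")
        y = y - design.fixed_effects() @ mu
    g, _ = mme_solve(cov, K, design, y=y, known_fixed=known_fixed)
    values = g.reshape(design.T, len(design.candidates)).T
    return GeneticValues(design.candidates, design.trials, values)


def predicted_performance(gv: GeneticValues, mu: Sequence[float]) -> pd.DataFrame:
    """Predicted performance mu_t + g_hat_it per trial, plus the mean over trials."""
    mu = np.asarray(mu, dtype=float)
    if mu.shape != (len(gv.trials),):
        raise ValueError("mu length must equal the number of trials")
    perf = gv.values + mu
    df = pd.DataFrame(perf, index=list(gv.ids), columns=list(gv.trials))
    df["mean"] = perf.mean(axis=1)
    return df


def write_genetic_values(gv: GeneticValues, path: str | Path) -> None:
    """Long-format output: genotype_id, trial_id (or 'mean'), predicted_value."""
    long = (
        gv.to_frame()
        .reset_index(names="genotype_id")
        .melt(id_vars="genotype_id", var_name="trial_id", value_name="predicted_value")
    )
    long.to_csv(path, index=False)
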