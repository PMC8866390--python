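"""Coefficients of determination (CD) for MET genomic prediction.

The CD of a prediction is the model-based expectation of the squared
correlation between a genetic value and its BLUP — the *expected
reliability*, computable before any phenotype is collected.  For a genotype
i and a trial t,

    CD_it = [G Z' M Z G]_(it,it) / G_(it,it),

and for the mean genetic value of genotype i over all T trials,

    CD_i. = sum_{t,t'} [G Z' M Z G]_(it,it') / sum_{t,t'} G_(it,it').

Both are computed under a named covariance structure:

* ``S``: one variance, between-trial genetic correlation 1 — CD_it is then
  identical across trials and equals CD_i. (one number per genotype);
* ``W``: zero between-trial correlation — CD_i. is the plain average of the
  per-trial CD_it;
* ``M``: unstructured Omega_G — CD_i. exceeds the average of CD_it whenever
  some pair of trials is positively correlated, quantifying the gain in
  precision on mean performance contributed by between-trial covariance.

An alternative route evaluates the same quantities through the inverse of
Henderson's mixed-model-equation coefficient matrix (prediction error
variance), useful when the number of plots exceeds N*T.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .met_model import METDesign, ModelMatrices, TrialCovariances, check_structure
from .predict import mme_solve
from .relate import KinshipMatrix

__all__ = ["CDResult", "cd_trial", "cd_mean", "cd_with_structure", "cd_mme", "write_cd"]


@dataclass
class CDResult:
    """Per-trial CD_it (N x T) and mean-performance CD_i. (N) for one design."""

    ids: Sequence[str]
    trials: Sequence[str]
    per_trial: np.ndarray
    mean_perf: np.ndarray
    structure: str
    design_fingerprint: str = ""

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.per_trial, index=list(self.ids), columns=list(self.trials))
        df["mean"] = self.mean_perf
        return df


def _check_g_diag(cov: TrialCovariances, K: KinshipMatrix, design: METDesign) -> np.ndarray:
    Ksub = K.subset(design.candidates)
    d = np.outer(np.diag(Ksub.K), cov.sigma2_G)  # N x T variance of g_it
    if np.any(d <= 0):
        i, t = np.argwhere(d <= 0)[0]
        raise ValueError(
            f"zero genetic variance for genotype {design.candidates[i]!r} "
            f"in trial {design.trials[t]!r}"
        )
    return d


def _vw(mm: ModelMatrices) -> tuple[np.ndarray, np.ndarray]:
    V = mm.Z @ mm.G  # plots x NT, column (t,i) = cov(y, g_it)
    return V, mm.M @ V


def cd_trial(
    design: METDesign,
    cov: TrialCovariances,
    K: KinshipMatrix,
    known_fixed: bool = False,
) -> np.ndarray:
    """CD_it for every candidate x trial (N x T), zeros for unconnected genotypes."""
    gdiag = _check_g_diag(cov, K, design)
    mm = ModelMatrices.build(cov, K, design, known_fixed=known_fixed)
    n, T = len(design.candidates), design.T
    V, W = _vw(mm)
    num = np.einsum("pj,pj->j", V, W)  # diag of G Z' M Z G
    cd = num.reshape(T, n).T / gdiag
    return np.clip(cd, 0.0, 1.0)


def cd_mean(
    design: METDesign,
    cov: TrialCovariances,
    K: KinshipMatrix,
    known_fixed: bool = False,
) -> np.ndarray:
    """CD_i. for every candidate (length N)."""
    _check_g_diag(cov, K, design)
    Ksub = K.subset(design.candidates)
    denom = np.diag(Ksub.K) * float(cov.omega_G.sum())
    if np.any(denom <= 0):
        i = int(np.argwhere(denom <= 0)[0])
        raise ValueError(
            f"non-positive variance of the mean genetic value for genotype "
            f"{design.candidates[i]!r} (sum of omega_G = {cov.omega_G.sum():.3g})"
        )
    mm = ModelMatrices.build(cov, K, design, known_fixed=known_fixed)
    n, T = len(design.candidates), design.T
    V = mm.Z @ mm.G
    U = V.reshape(-1, T, n).sum(axis=1)  # plots x N, summed over trials
    num = np.einsum("pi,pi->i", U, mm.M @ U)
    return np.clip(num / denom, 0.0, 1.0)


def cd_with_structure(
    structure: str,
    design: METDesign,
    cov: TrialCovariances,
    K: KinshipMatrix,
    known_fixed: bool = False,
) -> CDResult:
    """CDResult under a named structure; ``cov`` is reshaped accordingly first."""
    check_structure(structure)
    rcov = cov.restrict(structure)
    per_trial = cd_trial(design, rcov, K, known_fixed=known_fixed)
    mean_perf = cd_mean(design, rcov, K, known_fixed=known_fixed)
    return CDResult(
        ids=list(design.candidates),
        trials=list(design.trials),
        per_trial=per_trial,
        mean_perf=mean_perf,
        structure=structure,
        design_fingerprint=design.fingerprint(),
    )


def cd_mme(
    design: METDesign,
    cov: TrialCovariances,
    K: KinshipMatrix,
    known_fixed: bool = False,
    structure: str = "M",
) -> CDResult:
    """CDs through the mixed-model-equation inverse (prediction error variances).

    With C the MME coefficient matrix, the genetic block of C^-1 is the
    prediction error covariance Var(g_hat - g) = G - G Z' M Z G, so
    CD_it = 1 - PEV_it / G_(it,it) and the mean-performance CD follows from
    the summed blocks.  Agrees with the covariance route to high precision.
    """
    check_structure(structure)
    rcov = cov.restrict(structure)
    gdiag = _check_g_diag(rcov, K, design)
    Ksub = K.subset(design.candidates)
    n, T = Ksub.n, design.T
    _, Cgg = mme_solve(rcov, K, design, known_fixed=known_fixed, want_pev=True)
    pev = np.diag(Cgg).reshape(T, n).T
    per_trial = np.clip(1.0 - pev / gdiag, 0.0, 1.0)
    denom = np.diag(Ksub.K) * float(rcov.omega_G.sum())
    if np.any(denom <= 0):
        i = int(np.argwhere(denom <= 0)[0])
        raise ValueError(
            f"non-positive variance of the mean genetic value for genotype "
            f"{design.candidates[i]!r}"
        )
    # sum of the T x T block of Cgg belonging to each genotype
    blocks = Cgg.reshape(T, n, T, n)
    pev_mean = np.einsum("tiui->i", blocks)
    mean_perf = np.clip(1.0 - pev_mean / denom, 0.0, 1.0)
    return CDResult(
        ids=list(design.candidates),
        trials=list(design.trials),
        per_trial=per_trial,
        mean_perf=mean_perf,
        structure=structure,
        design_fingerprint=design.fingerprint(),
    )


def write_cd(result: CDResult, path: str | Path) -> None:
    """Long-format CD report: genotype_id, trial_id (or 'mean'), cd_value, structure."""
    long = (
        result.to_frame()
        .reset_index(names="genotype_id")
        .melt(id_vars="genotype_id", var_name="trial_id", value_name="cd_value")
    )
    long["structure"] = result.structure
    long.to_csv(path, index=False)
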