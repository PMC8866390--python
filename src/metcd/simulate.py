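"""Synthetic genotypes, correlated genetic values, and MET phenotypes.

The trait simulator draws from the multi-trial GBLUP model itself
(infinitesimal architecture): stacked trial-specific genetic values are
``g = L z`` with ``L L' = Omega_G (x) K`` and ``z`` iid standard normal, and
plot phenotypes are ``y = mu_t + g_it + e`` with independent errors of
variance ``sigma2_E_t = (1 - h2_t) / h2_t * sigma2_G_t``.

Default trial parameters (means 20/10/50/30/40, genetic variances 1..5,
plot heritabilities 0.2/0.8/0.6/0.4/0.5 for up to five trials, common
between-trial genetic correlation rho in {0.2, 0.5, 0.8}) define the
simulation study conditions; a scenario with T trials uses the first T
columns.

The genotype simulator is a family-block founder model (Balding–Nichols
allele-frequency divergence between families) whose only purpose is to
induce a kinship matrix with substantial within-family relatedness
(off-diagonals above 0.2), as found in breeding populations with shared
pedigree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._linalg import chol_psd
from .met_model import METDesign, TrialCovariances, exchangeable_covariances
from .predict import GeneticValues
from .relate import GenotypeMatrix, KinshipMatrix

__all__ = [
    "TRIAL_MEANS",
    "TRIAL_GENETIC_VARIANCES",
    "TRIAL_HERITABILITIES",
    "SimScenario",
    "synthetic_genotypes",
    "simulate_genetic_values",
    "error_variance_from_h2",
    "simulate_phenotypes",
]

TRIAL_MEANS = (20.0, 10.0, 50.0, 30.0, 40.0)
TRIAL_GENETIC_VARIANCES = (1.0, 2.0, 3.0, 4.0, 5.0)
TRIAL_HERITABILITIES = (0.2, 0.8, 0.6, 0.4, 0.5)


def error_variance_from_h2(h2_t: float, sigma2_G_t: float) -> float:
    """Error variance giving plot heritability h2: (1 - h2) / h2 * sigma2_G."""
    if not 0.0 < h2_t < 1.0:
        raise ValueError(f"h2 must lie in (0, 1), got {h2_t}")
    return (1.0 - h2_t) / h2_t * sigma2_G_t


@dataclass
class SimScenario:
    """Study conditions for one simulated trait family.

    Defaults follow the standard T-trial parameter table (first T entries of
    the module constants) with a common pairwise genetic correlation.
    """

    T: int = 2
    rho: float = 0.5
    mu: tuple[float, ...] = ()
    sigma2_G: tuple[float, ...] = ()
    h2: tuple[float, ...] = ()
    n_reps: int = 30
    seed: int | None = None
    trials: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not 1 <= self.T <= len(TRIAL_MEANS) and not self.mu:
            raise ValueError(f"default parameters cover 1..{len(TRIAL_MEANS)} trials")
        if not self.mu:
            self.mu = TRIAL_MEANS[: self.T]
        if not self.sigma2_G:
            self.sigma2_G = TRIAL_GENETIC_VARIANCES[: self.T]
        if not self.h2:
            self.h2 = TRIAL_HERITABILITIES[: self.T]
        for name in ("mu", "sigma2_G", "h2"):
            v = tuple(float(x) for x in getattr(self, name))
            if len(v) != self.T:
                raise ValueError(f"{name} must have length T={self.T}")
            setattr(self, name, v)
        if not all(0.0 < h < 1.0 for h in self.h2):
            raise ValueError("all h2 must lie in (0, 1)")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("rho must lie in (-1, 1)")
        if not self.trials:
            self.trials = tuple(f"trial{t + 1}" for t in range(self.T))

    @property
    def sigma2_E(self) -> tuple[float, ...]:
        return tuple(error_variance_from_h2(h, g) for h, g in zip(self.h2, self.sigma2_G))

    def covariances(self) -> TrialCovariances:
        return exchangeable_covariances(self.T, self.sigma2_G, rho=self.rho, h2=self.h2)


def synthetic_genotypes(
    n: int,
    m: int,
    n_families: int,
    seed: int | np.random.Generator | None = None,
    fst: float = 0.35,
) -> GenotypeMatrix:
    """Family-structured biallelic dosages.

    Global allele frequencies are uniform on (0.1, 0.9); each family draws
    its own frequencies from a Balding–Nichols Beta around the global ones
    (divergence ``fst``), and individuals are binomial draws from their
    family frequencies.  Members of a family therefore share drifted allele
    frequencies and show VanRaden kinship well above the 0.2 relatedness
    threshold used for pruning.
    """
    if min(n, m, n_families) < 1:
        raise ValueError("n, m and n_families must be >= 1")
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.1, 0.9, size=m)
    c = (1.0 - fst) / fst
    sizes = np.full(n_families, n // n_families)
    sizes[: n % n_families] += 1
    rows = []
    for fam in range(n_families):
        q = rng.beta(p * c, (1.0 - p) * c)
        rows.append(rng.binomial(2, q, size=(int(sizes[fam]), m)).astype(float))
    dosages = np.vstack(rows)
    ids = [f"g{i + 1:04d}" for i in range(n)]
    return GenotypeMatrix(ids, dosages)


def simulate_genetic_values(
    scenario: SimScenario,
    K: KinshipMatrix,
    seed: int | np.random.Generator | None = None,
) -> GeneticValues:
    """Draw stacked genetic values g = L z with L L' = Omega_G (x) K.

    The Cholesky factor is taken as chol(Omega_G) (x) chol(K) (with the
    package jitter policy), so a single N(0,1) vector of length N*T yields
    the exact joint distribution.  Values are deviations; add mu_t for
    trial-level performance.
    """
    rng = np.random.default_rng(seed)
    cov = scenario.covariances()
    Lg = chol_psd(cov.omega_G)
    Lk = chol_psd(K.K)
    # matrix-normal draw: cov of the trial-major stack is Omega_G (x) K
    z = rng.standard_normal((K.n, scenario.T))
    values = Lk @ z @ Lg.T
    return GeneticValues(list(K.ids), list(scenario.trials), values)


def simulate_phenotypes(
    gv: GeneticValues,
    design: METDesign,
    scenario: SimScenario,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Plot phenotypes y = mu_t + g_it + e for every plot of the design.

    Errors are independent N(0, sigma2_E_t) draws, fresh for every call, so
    repeated calls with advancing generators emulate replicate phenotyping
    of the same genetic values.
    """
    rng = np.random.default_rng(seed)
    if list(design.trials) != list(gv.trials):
        raise ValueError("design and genetic values disagree on trials")
    missing = set(design.plots["genotype"]) - set(gv.ids)
    if missing:
        raise ValueError(f"design genotypes without genetic values: {sorted(missing)[:5]}")
    gpos = {g: i for i, g in enumerate(gv.ids)}
    tpos = {t: k for k, t in enumerate(design.trials)}
    ti = np.array([tpos[t] for t in design.plots["trial"]])
    gi = np.array([gpos[g] for g in design.plots["genotype"]])
    s2e = np.asarray(scenario.sigma2_E)
    mu = np.asarray(scenario.mu)
    e = rng.standard_normal(design.n_plots) * np.sqrt(s2e[ti])
    y = mu[ti] + gv.values[gi, ti] + e
    out = design.plots.copy()
    out["value"] = y
    return out.rename(columns={"trial": "trial", "plot": "plot", "genotype": "genotype"})
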