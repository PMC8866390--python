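"""Shared fixtures: the three-genotype worked example and small synthetic pools."""

import numpy as np
import pandas as pd
import pytest

from metcd import (
    KinshipMatrix,
    METDesign,
    TrialCovariances,
    vanraden_kinship,
)
from metcd.simulate import synthetic_genotypes


def make_design(plots, trials=("trial1", "trial2"), candidates=("1", "2", "3")):
    """Build a METDesign from (trial_index_1based, plot, genotype) triples."""
    rows = [
        {"trial": f"trial{t}", "plot": p, "genotype": str(g)} for t, p, g in plots
    ]
    return METDesign(list(trials), pd.DataFrame(rows), list(candidates))


@pytest.fixture(scope="session")
def worked_example():
    """Three genotypes, two trials: kinship, covariances, designs A-D, printed CDs.

    Only genotypes 2 and 3 are related (kinship 0.5); trial genetic variances
    1 and 2 with covariance 0.7 (correlation ~0.5); error variances 1 and 2,
    so both trials have plot heritability 0.5.  Expected values are the
    published two-decimal CDs for each design, with known trial means.
    """
    K = KinshipMatrix(["1", "2", "3"], [[1, 0, 0], [0, 1, 0.5], [0, 0.5, 1]])
    cov = TrialCovariances([[1, 0.7], [0.7, 2]], [[1, 0], [0, 2]])
    designs = {
        "A": make_design([(1, 1, "1"), (1, 2, "1"), (2, 1, "1"), (2, 2, "1")]),
        "B": make_design([(1, 1, "2"), (1, 2, "2"), (2, 1, "2"), (2, 2, "2")]),
        "C": make_design([(1, 1, "1"), (1, 2, "2"), (2, 1, "1"), (2, 2, "1")]),
        "D": make_design([(1, 1, "1"), (1, 2, "2"), (2, 1, "1"), (2, 2, "3")]),
    }
    # rows: genotype -> (CD_i1, CD_i2, CD_i.)
    expected = {
        "A": {"1": (0.69, 0.69, 0.75), "2": (0.00, 0.00, 0.00), "3": (0.00, 0.00, 0.00)},
        "B": {"1": (0.00, 0.00, 0.00), "2": (0.69, 0.69, 0.75), "3": (0.17, 0.17, 0.19)},
        "C": {"1": (0.54, 0.68, 0.69), "2": (0.50, 0.12, 0.33), "3": (0.13, 0.03, 0.08)},
        "D": {"1": (0.53, 0.53, 0.60), "2": (0.51, 0.22, 0.39), "3": (0.22, 0.51, 0.46)},
    }
    return {"K": K, "cov": cov, "designs": designs, "expected": expected}


@pytest.fixture(scope="session")
def family_pool():
    """120 genotypes in 12 families with their VanRaden kinship (session-cached)."""
    geno = synthetic_genotypes(120, 600, 12, seed=41)
    return geno, vanraden_kinship(geno)


def random_instance(rng, n=6, T=2, n_fam=2, plots_per_trial=None, h2=0.5, rho=0.4):
    """Small random MET instance: well-conditioned K, PSD covariances, design, phenotypes."""
    geno = synthetic_genotypes(n, 200, n_fam, seed=rng)
    K = vanraden_kinship(geno)
    # jitter the diagonal so K is comfortably full rank
    K = KinshipMatrix(K.ids, K.K + 0.05 * np.eye(n))
    s2g = rng.uniform(0.5, 2.0, size=T)
    s = np.sqrt(s2g)
    omega_G = rho * np.outer(s, s)
    np.fill_diagonal(omega_G, s2g)
    s2e = s2g * (1 - h2) / h2
    cov = TrialCovariances(omega_G, np.diag(s2e))
    P = plots_per_trial or max(2, n // 2)
    trials = [f"trial{t+1}" for t in range(T)]
    rows = []
    for t in trials:
        picks = rng.choice(n, size=P, replace=False)
        for p, gi in enumerate(picks):
            rows.append({"trial": t, "plot": p + 1, "genotype": K.ids[gi]})
    design = METDesign(trials, pd.DataFrame(rows), list(K.ids))
    pheno = design.plots.copy()
    pheno["value"] = rng.normal(size=len(pheno))
    return K, cov, design, pheno
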