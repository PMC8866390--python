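"""Validation machinery: observed reliability, CD calibration, cross-validation.

*Observed reliability* R^2_G is the squared Pearson correlation between true
and predicted genetic values over a set of genotypes (for real traits the
same statistic against reference phenotypes gives the phenotype-based
R^2_Y).  Because the CD is the model-expected R^2_G, plotting observed
reliability of groups of predictions with similar CD against the CD value
calibrates the criterion: genotypes are pooled into sliding CD windows
[x - 0.05, x + 0.05] for x in {0.05, ..., 0.95}, each window is pruned so no
two members have kinship above 0.2 (correlated predictions inflate the
correlation estimate), windows with too few members are discarded, and the
window R^2_G is compared to its center.

Cross-validation follows the simulated-trait protocol: a training set
observed once per trial, fresh phenotypes per replicate (new errors on the
same or new genetic values), models fitted per structure and scored on the
held-out test set per trial and for mean performance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .met_model import METDesign
from .predict import GeneticValues, blup
from .relate import KinshipMatrix
from .simulate import SimScenario, simulate_genetic_values, simulate_phenotypes
from .varcomp import fit_met
from .design_opt import OptimizerConfig, make_design, optimize_design

__all__ = [
    "ReliabilityBin",
    "CVSplit",
    "reliability",
    "prune_related",
    "cd_calibration",
    "cross_validate",
    "compare_designs",
]


def reliability(
    true_g: GeneticValues | np.ndarray,
    pred_g: GeneticValues | np.ndarray,
    ids: Sequence[str] | None = None,
    target: str | int = "mean",
) -> float:
    """Squared Pearson correlation between true and predicted values.

    ``target`` selects a trial (name or index) or ``"mean"`` for the mean
    performance over trials.  Invariant to affine rescaling of either input.
    """

    def pick(gv, other_trials=None):
        if isinstance(gv, GeneticValues):
            v = gv.mean if target == "mean" else gv.values[:, _trial_index(gv, target)]
            if ids is not None:
                pos = {g: i for i, g in enumerate(gv.ids)}
                v = v[[pos[str(g)] for g in ids]]
            return np.asarray(v, dtype=float)
        return np.asarray(gv, dtype=float)

    x, y = pick(true_g), pick(pred_g)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("true and predicted vectors must be 1-D and aligned")
    if len(x) < 3:
        raise ValueError("at least 3 genotypes are required")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in true or predicted values")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _trial_index(gv: GeneticValues, target: str | int) -> int:
    if isinstance(target, int):
        return target
    try:
        return list(gv.trials).index(str(target))
    except ValueError:
        raise KeyError(f"unknown trial {target!r}") from None


def prune_related(ids: Sequence[str], K: KinshipMatrix, threshold: float = 0.2) -> list[str]:
    """Iteratively drop genotypes until all pairwise kinship <= threshold.

    Deterministic rule: repeatedly take the offending pair that comes
    earliest in the current id order and discard its second member.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    kept = [str(g) for g in ids]
    while True:
        idx = K.index(kept)
        sub = K.K[np.ix_(idx, idx)]
        offending = None
        m = len(kept)
        for a in range(m):
            for b in range(a + 1, m):
                if sub[a, b] > threshold:
                    offending = b
                    break
            if offending is not None:
                break
        if offending is None:
            return kept
        del kept[offending]


@dataclass
class ReliabilityBin:
    """One sliding CD window with its pruned membership and observed reliability."""

    center: float
    ids: list[str]
    r2: float
    n: int


def cd_calibration(
    cd_values: np.ndarray,
    true_g: np.ndarray,
    pred_g: np.ndarray,
    K: KinshipMatrix,
    ids: Sequence[str],
    *,
    half_width: float = 0.05,
    centers: Sequence[float] | None = None,
    min_count: int = 50,
    kinship_threshold: float = 0.2,
) -> list[ReliabilityBin]:
    """Observed reliability per sliding CD window (see module docstring).

    Windows may overlap; each is pruned for relatedness and scored
    independently; windows with fewer than ``min_count`` members after
    pruning are discarded.  Returns possibly empty list.
    """
    ids = [str(g) for g in ids]
    cd_values = np.asarray(cd_values, dtype=float)
    true_g = np.asarray(true_g, dtype=float)
    pred_g = np.asarray(pred_g, dtype=float)
    if not (len(ids) == len(cd_values) == len(true_g) == len(pred_g)):
        raise ValueError("cd_values, true_g, pred_g and ids must be aligned")
    if centers is None:
        centers = np.round(np.arange(0.05, 1.0, 0.05), 2)
    out: list[ReliabilityBin] = []
    for x in centers:
        inside = np.flatnonzero((cd_values >= x - half_width) & (cd_values <= x + half_width))
        if len(inside) < 2:
            continue
        members = prune_related([ids[i] for i in inside], K, threshold=kinship_threshold)
        if len(members) < min_count:
            continue
        pos = {g: i for i, g in enumerate(ids)}
        sel = [pos[g] for g in members]
        x_t, x_p = true_g[sel], pred_g[sel]
        if np.std(x_t) == 0 or np.std(x_p) == 0:
            continue
        r = float(np.corrcoef(x_t, x_p)[0, 1] ** 2)
        out.append(ReliabilityBin(center=float(x), ids=members, r2=r, n=len(members)))
    return out


@dataclass
class CVSplit:
    """Training / test partition of the candidate universe for one replicate."""

    training: list[str]
    test: list[str]
    replicate: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if set(self.training) & set(self.test):
            raise ValueError("training and test sets overlap")


def _split(ids: Sequence[str], trs_size: int, rng: np.random.Generator, rep: int) -> CVSplit:
    ids = [str(g) for g in ids]
    if trs_size >= len(ids):
        raise ValueError("training-set size must leave a non-empty test set")
    chosen = rng.choice(len(ids), size=trs_size, replace=False)
    mask = np.zeros(len(ids), dtype=bool)
    mask[chosen] = True
    return CVSplit([ids[i] for i in np.flatnonzero(mask)], [ids[i] for i in np.flatnonzero(~mask)], rep)


def cross_validate(
    K: KinshipMatrix,
    scenario: SimScenario,
    structures: Sequence[str] = ("S", "W", "M"),
    n_replicates: int = 30,
    trs_size: int = 500,
    seed: int | None = None,
    *,
    method: str = "reml",
    resimulate_genetics: bool = False,
    chain: dict | None = None,
) -> pd.DataFrame:
    """Simulated-trait cross-validation of the model structures.

    Each replicate draws a fresh training split and fresh phenotypes
    (new errors; new genetic values too when ``resimulate_genetics``),
    observes the training set once in every trial, fits each structure and
    scores the test-set reliability per trial and for mean performance.
    Returns a long table (structure, target, replicate, r2); summarize with
    ``df.groupby(["structure", "target"])["r2"].agg(["mean", "sem"])``.
    """
    rng = np.random.default_rng(seed)
    ids = list(K.ids)
    gv = simulate_genetic_values(scenario, K, rng)
    records = []
    chain = chain or {}
    for rep in range(n_replicates):
        if resimulate_genetics and rep > 0:
            gv = simulate_genetic_values(scenario, K, rng)
        split = _split(ids, trs_size, rng, rep)
        rows = [
            {"trial": t, "plot": g, "genotype": g}
            for t in scenario.trials
            for g in split.training
        ]
        design = METDesign(list(scenario.trials), pd.DataFrame(rows), ids)
        pheno = simulate_phenotypes(gv, design, scenario, rng)
        for structure in structures:
            try:
                fitted = fit_met(
                    pheno, K, design, structure, method=method,
                    seed=rng if method == "gibbs" else None, **chain,
                )
                pred = blup(pheno, fitted, K, design)
            except (ValueError, FloatingPointError) as err:
                records.append(
                    {"structure": structure, "target": "error", "replicate": rep,
                     "r2": np.nan, "note": str(err)}
                )
                continue
            for t in scenario.trials:
                records.append(
                    {"structure": structure, "target": t, "replicate": rep,
                     "r2": reliability(gv, pred, split.test, target=t), "note": ""}
                )
            records.append(
                {"structure": structure, "target": "mean", "replicate": rep,
                 "r2": reliability(gv, pred, split.test, target="mean"), "note": ""}
            )
    return pd.DataFrame.from_records(records)


def compare_designs(
    K: KinshipMatrix,
    scenario: SimScenario,
    families: Sequence[str] = ("C2", "C1", "I", "Opt"),
    plots_per_trial: int = 50,
    test_size: int = 50,
    n_replicates: int = 10,
    seed: int | None = None,
    *,
    use_true_covariances: bool = True,
    method: str = "reml",
    optimizer: OptimizerConfig | None = None,
) -> pd.DataFrame:
    """Observed test-set reliability of standard vs optimized designs.

    Per replicate: a test set is held out, the remaining genotypes form the
    candidate pool; one design per family is built at the common plot budget
    (``Opt`` by CD optimization over the candidates, conservative mode:
    the test set is excluded from the optimization criterion); phenotypes
    are simulated and the test set predicted with the multi-trial model.
    With ``use_true_covariances`` the simulation parameters are used for
    prediction (isolating the design effect); otherwise the model is
    refitted per design.
    """
    rng = np.random.default_rng(seed)
    ids = list(K.ids)
    records = []
    for rep in range(n_replicates):
        split = _split(ids, len(ids) - test_size, rng, rep)
        pool = split.training  # candidates for the design
        gv = simulate_genetic_values(scenario, K, rng)
        for family in families:
            if family == "Opt":
                cfg = optimizer or OptimizerConfig(
                    ga_iterations=60, population=40, elites=8, saa_iterations=5
                )
                cfg = OptimizerConfig(
                    **{**cfg.__dict__, "seed": int(rng.integers(2**31 - 1))}
                )
                design, _ = optimize_design(
                    pool, plots_per_trial, scenario.T, K, cfg,
                    eval_set=pool, trials=scenario.trials,
                )
                design = METDesign(list(scenario.trials), design.plots, ids)
            else:
                design = make_design(
                    family, pool, plots_per_trial, scenario.T,
                    seed=rng, trials=scenario.trials,
                )
                design = METDesign(list(scenario.trials), design.plots, ids)
            pheno = simulate_phenotypes(gv, design, scenario, rng)
            if use_true_covariances:
                pred = blup(pheno, scenario.covariances(), K, design)
            else:
                fitted = fit_met(pheno, K, design, "M", method=method)
                pred = blup(pheno, fitted, K, design)
            for t in scenario.trials:
                records.append(
                    {"family": family, "target": t, "replicate": rep,
                     "r2": reliability(gv, pred, split.test, target=t)}
                )
            records.append(
                {"family": family, "target": "mean", "replicate": rep,
                 "r2": reliability(gv, pred, split.test, target="mean")}
            )
    return pd.DataFrame.from_records(records)
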