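"""Construction and CD-based optimization of MET experimental designs.

Standard design families:

* ``I`` — incomplete and unreplicated: each allocated genotype is observed
  exactly once in the whole experiment (one plot of one trial);
* ``Ck`` — complete with k replicates: each allocated genotype is observed
  k times in every trial;
* ``Opt`` — optimized allocation: no within-trial replication, replication
  across trials allowed.

The optimizer maximizes the mean CD (per-trial CD_it over genotypes x
trials, or mean-performance CD_i. over genotypes) across an evaluation set
of candidates, using a hybrid of a genetic algorithm (GA) and simulated
annealing (SAA): each GA generation builds a population of designs by
uniform plot-level crossover between elite parents plus random plot-level
mutations, keeps the best designs as the next elite set, and polishes every
elite with a few Metropolis single-plot moves under a geometrically cooled
temperature.  Defaults: 2,000 GA generations, population 200, 20 elites,
10 SAA moves per elite per generation.

CDs for the objective use a deliberately simple parameter configuration
(unit genetic and error variances for all trials; between-trial genetic
correlation 1, 0 or 0.5 for configurations S, W and M) — the ranking of
designs is insensitive to the precise variances, so prior knowledge of the
trait is not required.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .met_model import METDesign, TrialCovariances, check_structure, compute_M, exchangeable_covariances
from .relate import KinshipMatrix

__all__ = [
    "OptimizerConfig",
    "configuration_covariances",
    "make_design",
    "objective",
    "optimize_design",
    "exhaustive_search",
    "enumerate_allocations",
]

_CONFIG_RHO = {"S": 1.0, "W": 0.0, "M": 0.5}


def configuration_covariances(configuration: str, T: int) -> TrialCovariances:
    """Unit-variance covariances with rho = 1 / 0 / 0.5 for configuration S / W / M."""
    check_structure(configuration)
    return exchangeable_covariances(T, 1.0, sigma2_E=1.0, rho=_CONFIG_RHO[configuration])


@dataclass
class OptimizerConfig:
    """Knobs of the GA + SAA design optimizer."""

    ga_iterations: int = 2_000
    population: int = 200
    elites: int = 20
    saa_iterations: int = 10
    mutation_rate: float = 0.05
    objective: str = "trial"  # "trial" (mean CD_it) or "mean" (mean CD_i.)
    configuration: str = "M"
    cov: TrialCovariances | None = None
    known_fixed: bool = False
    cooling: float = 0.9
    initial_temperature: float | None = None
    polish_passes: int = 2
    polish_candidates: int = 30
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.elites > self.population:
            raise ValueError("elite count cannot exceed population size")
        if min(self.ga_iterations, self.population, self.elites, self.saa_iterations) < 1:
            raise ValueError("all optimizer counts must be positive")
        if self.objective not in ("trial", "mean"):
            raise ValueError("objective must be 'trial' or 'mean'")
        check_structure(self.configuration)
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation rate must lie in [0, 1]")

    def covariances(self, T: int) -> TrialCovariances:
        if self.cov is not None:
            if self.cov.T != T:
                raise ValueError("configured covariances disagree with the number of trials")
            return self.cov
        return configuration_covariances(self.configuration, T)


# ---------------------------------------------------------------------------
# standard design families


def _parse_family(family: str) -> tuple[str, int]:
    if family == "I":
        return "I", 0
    if family == "Opt":
        return "Opt", 0
    m = re.fullmatch(r"C(\d+)", family)
    if not m or int(m.group(1)) < 1:
        raise ValueError(f"unknown design family {family!r}; expected 'I', 'Ck' or 'Opt'")
    return "C", int(m.group(1))


def _assign_to_design(
    assign: np.ndarray,
    candidates: Sequence[str],
    trials: Sequence[str],
) -> METDesign:
    rows = []
    for t, trial in enumerate(trials):
        for p, gi in enumerate(assign[t]):
            rows.append({"trial": trial, "plot": p + 1, "genotype": candidates[int(gi)]})
    return METDesign(list(trials), pd.DataFrame(rows), list(candidates))


def make_design(
    family: str,
    candidates: Sequence[str],
    plots_per_trial: int,
    T: int,
    seed: int | np.random.Generator | None = None,
    trials: Sequence[str] | None = None,
) -> METDesign:
    """Random allocation from a standard family (seed-reproducible).

    ``I`` draws T * plots_per_trial distinct genotypes, one plot each;
    ``Ck`` draws plots_per_trial / k genotypes and replicates each k times
    in every trial.
    """
    kind, k = _parse_family(family)
    if kind == "Opt":
        raise ValueError("Opt designs come from optimize_design(), not make_design()")
    candidates = [str(g) for g in candidates]
    trials = [f"trial{t + 1}" for t in range(T)] if trials is None else [str(t) for t in trials]
    if len(trials) != T:
        raise ValueError("trial name count must equal T")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if kind == "I":
        need = T * plots_per_trial
        if need > len(candidates):
            raise ValueError(
                f"design I with {T} trials x {plots_per_trial} plots needs "
                f"{need} candidates, got {len(candidates)}"
            )
        chosen = rng.choice(len(candidates), size=need, replace=False)
        assign = chosen.reshape(T, plots_per_trial)
    else:
        if plots_per_trial % k:
            raise ValueError(f"plots_per_trial={plots_per_trial} is not divisible by k={k}")
        n_geno = plots_per_trial // k
        if n_geno > len(candidates):
            raise ValueError(f"design C{k} needs {n_geno} candidates, got {len(candidates)}")
        chosen = rng.choice(len(candidates), size=n_geno, replace=False)
        assign = np.tile(np.repeat(chosen, k), (T, 1))
    return _assign_to_design(assign, candidates, trials)


# ---------------------------------------------------------------------------
# fast CD objective on index arrays


class _CDObjective:
    """Mean CD over an evaluation set, evaluated directly from index arrays.

    Avoids assembling the full N*T x N*T genetic covariance: only the plot
    covariance (P*T square) and the cross-covariance columns of the
    evaluation set are formed per design.
    """

    def __init__(
        self,
        cov: TrialCovariances,
        K: KinshipMatrix,
        candidates: Sequence[str],
        eval_ids: Sequence[str],
        objective: str = "trial",
        known_fixed: bool = False,
    ) -> None:
        self.candidates = [str(g) for g in candidates]
        self.K = K.subset(self.candidates).K
        self.omega_G = cov.omega_G
        self.s2e = cov.sigma2_E
        self.T = cov.T
        pos = {g: i for i, g in enumerate(self.candidates)}
        self.eval_idx = np.array([pos[str(g)] for g in eval_ids], dtype=int)
        self.objective = objective
        self.known_fixed = known_fixed
        self.kdiag_eval = np.diag(self.K)[self.eval_idx]
        if np.any(self.kdiag_eval * np.diag(self.omega_G).max() <= 0):
            raise ValueError("zero genetic variance in the evaluation set")

    def __call__(self, assign: np.ndarray) -> float:
        assign = np.asarray(assign, dtype=int)
        if assign.size == 0:
            return 0.0
        T, P = assign.shape
        return self.score(np.repeat(np.arange(T), P), assign.reshape(-1))

    def score(self, ti: np.ndarray, gi: np.ndarray) -> float:
        """Objective from per-plot trial and genotype index arrays."""
        if len(ti) == 0:
            return 0.0
        T = self.T
        Sigma = self.omega_G[np.ix_(ti, ti)] * self.K[np.ix_(gi, gi)]
        Sigma[np.diag_indices_from(Sigma)] += self.s2e[ti]
        n_plots = len(ti)
        if self.known_fixed:
            M = compute_M(Sigma, known_fixed=True)
        else:
            X = np.zeros((n_plots, T))
            X[np.arange(n_plots), ti] = 1.0
            M = compute_M(Sigma, X)
        # V[p, t, i] = cov(y_p, g_{eval_i, t})
        V = self.omega_G[ti][:, :, None] * self.K[gi][:, None, self.eval_idx]
        n_eval = len(self.eval_idx)
        flat = V.reshape(n_plots, T * n_eval)
        W = M @ flat
        if self.objective == "trial":
            num = np.einsum("pj,pj->j", flat, W).reshape(T, n_eval)
            den = np.outer(np.diag(self.omega_G), self.kdiag_eval)
            return float(np.mean(np.clip(num / den, 0.0, 1.0)))
        U = V.sum(axis=1)  # n_plots x n_eval
        num = np.einsum("pi,pi->i", U, M @ U)
        den = self.kdiag_eval * float(self.omega_G.sum())
        return float(np.mean(np.clip(num / den, 0.0, 1.0)))


def objective(
    design: METDesign,
    config: OptimizerConfig,
    K: KinshipMatrix,
    eval_set: Sequence[str] | None = None,
) -> float:
    """Mean CD of a design over the evaluation set under the configured parameters."""
    eval_ids = list(design.candidates) if eval_set is None else [str(g) for g in eval_set]
    cov = config.covariances(design.T)
    fn = _CDObjective(
        cov, K, design.candidates, eval_ids, objective=config.objective, known_fixed=config.known_fixed
    )
    if design.n_plots == 0:
        return 0.0
    pos = {g: i for i, g in enumerate(design.candidates)}
    tpos = {t: k for k, t in enumerate(design.trials)}
    ti = np.array([tpos[t] for t in design.plots["trial"]], dtype=int)
    gi = np.array([pos[g] for g in design.plots["genotype"]], dtype=int)
    return fn.score(ti, gi)


# ---------------------------------------------------------------------------
# GA + SAA optimizer


def _random_assign(rng: np.random.Generator, n_cand: int, T: int, P: int) -> np.ndarray:
    return np.stack([rng.choice(n_cand, size=P, replace=False) for _ in range(T)])


def _repair_row(row: np.ndarray, n_cand: int, rng: np.random.Generator) -> None:
    """Replace duplicate entries within a trial with fresh random candidates."""
    seen: set[int] = set()
    dup_pos = []
    for j, g in enumerate(row):
        if g in seen:
            dup_pos.append(j)
        else:
            seen.add(int(g))
    if dup_pos:
        pool = np.setdiff1d(np.arange(n_cand), row, assume_unique=False)
        repl = rng.choice(pool, size=len(dup_pos), replace=False)
        row[dup_pos] = repl


def _crossover(a: np.ndarray, b: np.ndarray, rng: np.random.Generator, n_cand: int) -> np.ndarray:
    mask = rng.random(a.shape) < 0.5
    child = np.where(mask, a, b)
    for row in child:
        _repair_row(row, n_cand, rng)
    return child


def _mutate(assign: np.ndarray, rate: float, rng: np.random.Generator, n_cand: int) -> None:
    T, P = assign.shape
    for t in range(T):
        for p in range(P):
            if rng.random() < rate:
                pool = np.setdiff1d(np.arange(n_cand), assign[t])
                if len(pool):
                    assign[t, p] = rng.choice(pool)


def optimize_design(
    candidates: Sequence[str],
    plots_per_trial: int,
    T: int,
    K: KinshipMatrix,
    config: OptimizerConfig,
    eval_set: Sequence[str] | None = None,
    trials: Sequence[str] | None = None,
) -> tuple[METDesign, np.ndarray]:
    """Best design found by GA + SAA, plus the per-generation best-objective trace.

    Within-trial replication is a hard constraint (proposals are repaired,
    never penalized); replication of a genotype across trials is allowed.
    The trace is non-decreasing because elites survive generations.
    """
    candidates = [str(g) for g in candidates]
    trials = [f"trial{t + 1}" for t in range(T)] if trials is None else [str(t) for t in trials]
    n_cand = len(candidates)
    if plots_per_trial > n_cand:
        raise ValueError(
            f"{plots_per_trial} plots per trial without within-trial replication "
            f"needs at least {plots_per_trial} candidates, got {n_cand}"
        )
    eval_ids = candidates if eval_set is None else [str(g) for g in eval_set]
    cov = config.covariances(T)
    fn = _CDObjective(
        cov, K, candidates, eval_ids, objective=config.objective, known_fixed=config.known_fixed
    )
    rng = np.random.default_rng(config.seed)

    pop = [_random_assign(rng, n_cand, T, plots_per_trial) for _ in range(config.population)]
    scores = np.array([fn(a) for a in pop])
    order = np.argsort(scores)[::-1]
    elites = [pop[i].copy() for i in order[: config.elites]]
    elite_scores = scores[order[: config.elites]].copy()

    t0 = config.initial_temperature
    if t0 is None:
        t0 = 0.1 * max(float(elite_scores[0]), 1e-8)
    trace = np.empty(config.ga_iterations)

    for it in range(config.ga_iterations):
        temp = max(t0 * config.cooling**it, 1e-12)
        children = []
        for _ in range(config.population):
            i, j = rng.integers(0, len(elites), size=2)
            child = _crossover(elites[i], elites[j], rng, n_cand)
            _mutate(child, config.mutation_rate, rng, n_cand)
            children.append(child)
        child_scores = np.array([fn(a) for a in children])
        merged = elites + children
        merged_scores = np.concatenate([elite_scores, child_scores])
        order = np.argsort(merged_scores)[::-1]
        elites = [merged[i].copy() for i in order[: config.elites]]
        elite_scores = merged_scores[order[: config.elites]].copy()

        # simulated-annealing polish of each elite
        for e in range(len(elites)):
            cur, cur_s = elites[e], float(elite_scores[e])
            for _ in range(config.saa_iterations):
                prop = cur.copy()
                t = int(rng.integers(T))
                p = int(rng.integers(plots_per_trial))
                pool = np.setdiff1d(np.arange(n_cand), prop[t])
                if not len(pool):
                    continue
                prop[t, p] = rng.choice(pool)
                s = fn(prop)
                delta = s - cur_s
                if delta >= 0 or rng.random() < np.exp(delta / temp):
                    cur, cur_s = prop, s
            # keep the polish only if it did not lose ground
            if cur_s >= float(elite_scores[e]):
                elites[e], elite_scores[e] = cur, cur_s
        order = np.argsort(elite_scores)[::-1]
        elites = [elites[i] for i in order]
        elite_scores = elite_scores[order]
        trace[it] = float(elite_scores[0])

    # zero-temperature finishing sweeps: steepest-ascent single-plot moves
    best_assign, best_score = _greedy_polish(
        elites[0].copy(), float(elite_scores[0]), fn, rng, n_cand,
        passes=config.polish_passes, max_candidates=config.polish_candidates,
    )
    trace[-1] = max(trace[-1], best_score)
    best = _assign_to_design(best_assign, candidates, trials)
    return best, trace


def _greedy_polish(
    assign: np.ndarray,
    score: float,
    fn: "_CDObjective",
    rng: np.random.Generator,
    n_cand: int,
    passes: int,
    max_candidates: int,
) -> tuple[np.ndarray, float]:
    """Best-improvement single-plot sweeps over (a sample of) replacement genotypes."""
    T, P = assign.shape
    for _ in range(passes):
        improved = False
        for t in range(T):
            for p in range(P):
                pool = np.setdiff1d(np.arange(n_cand), assign[t])
                if len(pool) > max_candidates:
                    pool = rng.choice(pool, size=max_candidates, replace=False)
                keep = assign[t, p]
                for g in pool:
                    assign[t, p] = g
                    s = fn(assign)
                    if s > score + 1e-12:
                        score, keep = s, g
                        improved = True
                assign[t, p] = keep
        if not improved:
            break
    return assign, score


# ---------------------------------------------------------------------------
# exhaustive reference for small instances


def enumerate_allocations(n_cand: int, plots_per_trial: int, T: int) -> Iterator[np.ndarray]:
    """All designs without within-trial replication (unordered plots within trials)."""
    per_trial = list(itertools.combinations(range(n_cand), plots_per_trial))
    for combo in itertools.product(per_trial, repeat=T):
        yield np.array(combo, dtype=int)


def exhaustive_search(
    candidates: Sequence[str],
    plots_per_trial: int,
    T: int,
    K: KinshipMatrix,
    config: OptimizerConfig,
    eval_set: Sequence[str] | None = None,
    trials: Sequence[str] | None = None,
) -> tuple[METDesign, float]:
    """Global optimum by enumeration (use only for tiny instances)."""
    candidates = [str(g) for g in candidates]
    trials = [f"trial{t + 1}" for t in range(T)] if trials is None else [str(t) for t in trials]
    eval_ids = candidates if eval_set is None else [str(g) for g in eval_set]
    cov = config.covariances(T)
    fn = _CDObjective(
        cov, K, candidates, eval_ids, objective=config.objective, known_fixed=config.known_fixed
    )
    best_assign, best_score = None, -np.inf
    for assign in enumerate_allocations(len(candidates), plots_per_trial, T):
        s = fn(assign)
        if s > best_score:
            best_assign, best_score = assign, s
    assert best_assign is not None
    return _assign_to_design(best_assign, candidates, trials), float(best_score)
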