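"""Optimize which lines go in which trial by maximizing the mean CD.

A pool of 60 candidate lines (6 families) must fill 2 trials x 10 plots.
The optimizer (genetic algorithm + simulated annealing over plot-level
moves, no within-trial replication) maximizes the average per-trial CD over
all candidates, using the neutral parameter configuration M (unit variances,
between-trial genetic correlation 0.5).  We compare against random
unreplicated (I) and fully replicated (C2) allocations at the same budget.
"""

import numpy as np

from metcd import (
    OptimizerConfig,
    make_design,
    objective,
    optimize_design,
    synthetic_genotypes,
    vanraden_kinship,
)

rng = np.random.default_rng(11)
K = vanraden_kinship(synthetic_genotypes(60, 600, 6, seed=rng))

config = OptimizerConfig(ga_iterations=80, population=60, elites=10,
                         saa_iterations=8, mutation_rate=0.1,
                         configuration="M", objective="trial", seed=3)
best, trace = optimize_design(list(K.ids), 10, 2, K, config)

print(f"optimized design: mean CD_it = {trace[-1]:.3f} "
      f"(start {trace[0]:.3f}, {len(trace)} GA generations)")
for family in ("I", "C2"):
    scores = [objective(make_design(family, list(K.ids), 10, 2, seed=s), config, K)
              for s in range(20)]
    print(f"random {family} designs: mean CD_it = {np.mean(scores):.3f} "
          f"(best of 20: {np.max(scores):.3f})")

n_distinct = best.plots["genotype"].nunique()
print(f"\nthe optimized design observes {n_distinct} distinct lines in 20 plots")
print(
    "Higher mean CD means higher expected prediction reliability for the\n"
    "whole candidate pool.  The optimizer spreads plots over many families\n"
    "(replicating alleles, not genotypes), which is why it beats C2 by a\n"
    "wide margin and random unreplicated allocation by a consistent one."
)
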