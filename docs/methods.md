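# Methods

## Model

`metcd` works with the multivariate (multi-trial) GBLUP model for a trait
observed in T trials:

    y = X β + Z g + e,   g ~ N(0, G),   e ~ N(0, R),
    G = Ω_G ⊗ K,         R diagonal with trial-specific variances σ²_Et.

The stacked vector g holds trial-specific genetic values in **trial-major**
order (all genotypes of trial 1, then trial 2, …), matching Ω_G on the left
of the Kronecker product; entry (t, i) sits at flat index `t*N + i`. X is
one intercept per trial (β = trial means) unless the user declares the
means known. R is assembled per plot — each plot of trial t gets σ²_Et —
which reduces to the Kronecker form Ω_E ⊗ I_P only when plot counts are
equal across trials; unbalanced designs are first-class.

Assumptions: genotypes are inbred lines represented by a single genomic
relationship matrix K; errors are independent across plots with
trial-specific variance (no spatial or row-column structure — spatial
adjustment is assumed done upstream); g and e are independent Gaussians
(infinitesimal architecture).

Three structures of (Ω_G, Ω_E) name the classical GBLUP variants:
**S** — σ²_G constant everywhere in Ω_G (genetic correlation 1) and one
σ²_E; **W** — diagonal Ω_G (correlation 0; separate per-trial fits);
**M** — unstructured Ω_G. `TrialCovariances.restrict` maps any covariance
to a structure; for S the pooled variance is the mean of the per-trial
variances (a convention needed only when restricting a heterogeneous
covariance, as the S configuration is normally used with equal variances).

## Kinship

`vanraden_kinship` computes K = WWᵀ / (2 Σ p_j(1−p_j)) with W the dosage
matrix centered at 2p_j, allele frequencies estimated from the sample,
missing dosages mean-imputed per marker, then rescales K ← K·N/trace(K) so
the mean diagonal is exactly 1. Monomorphic markers contribute nothing to
either numerator or denominator. Two consequences of sample-estimated
frequencies worth knowing: an input consisting only of identical lines has
a zero centered matrix (rejected with a "zero denominator" error), and
relatedness is always *relative to the sample* — within-family kinship is
high only against a background of other families. K is not forced positive
definite here; downstream code handles rank deficiency (below).

## Numerical policy for (near-)singular matrices

Family-structured or duplicated lines make K rank-deficient. Every
symmetric factorization goes through one jitter ladder: Cholesky is
attempted exactly, then with a diagonal ridge of 1e-10, 1e-8, 1e-6 times the
mean diagonal, and only then fails. The mixed-model-equation route never
inverts Ω_G or K directly: both factors are eigendecomposed, null
components (eigenvalue ≤ 1e-10 of the maximum) are dropped, and the
equations are solved in the reduced basis g = (Q_g ⊗ Q_k) b. This keeps the
MME route exact for the rank-1 Ω_G of structure S and for singular K, and
it is why the Σ-inverse route and the MME route agree to machine precision
even on degenerate inputs. CD values are clipped to [0, 1] (excursions are
at rounding level); zero genetic variance for a requested genotype raises an
error naming it rather than returning NaN.

## CD criteria

CD_it = [G Zᵀ M Z G]/(G diag) and CD_i· = (summed T×T block)/(summed prior
block) are evaluated without forming the NT×NT product: with V = ZG
(plots × NT), the needed diagonals are `einsum` contractions of V and MV.
The MME route instead reads prediction error variances from the inverse
coefficient matrix (PEV = G − GZᵀMZG) and reports CD = 1 − PEV/var; both
routes are tested to agree to 1e-8 on random instances and on the worked
example.

Identities used as test oracles: under S, CD_it is constant over t and
equals CD_i·; under W with equal genetic variances, CD_i· is the plain mean
of CD_it (with heterogeneous variances it is the σ²_Gt-weighted mean — an
algebraic fact the unit tests pin down); under M with positive between-trial
covariance, CD_i· strictly exceeds the per-trial average for every genotype
with non-zero CD.

For the published three-genotype table the package uses known trial means
(M = Σ⁻¹), as that table does; the public default estimates means, which is
what any real cross-validation does. Printed-value comparisons use a
half-up two-decimal band (±0.005 plus an epsilon for exact boundary values
such as 0.125).

## Estimation

`fit_met` offers two routes behind one contract.

**Gibbs** (default, chain 10,000 / burn-in 1,000 / thinning 5; point
estimates are posterior means of retained draws). Conjugate updates: trial
means from their Gaussian conditional (flat prior); genetic values jointly
from the Gaussian conditional with precision ZᵀR⁻¹Z + Ω_G⁻¹ ⊗ K⁻¹ restricted
to observed genotypes; Ω_G from an inverse-Wishart (prior df T+2, scale I);
error variances from scaled-inverse-χ² (prior df 3, scale the per-trial
sample variance; genetic variances under S/W use df 3, scale half of it).
These priors are weakly informative conveniences chosen for conjugacy, not
substantive claims; what is validated is parameter recovery, not the prior.
All draws flow from one `numpy.random.Generator`; identical seeds give
identical chains, and any non-finite draw aborts with the iteration index.

**REML** (`method="reml"`): direct maximization of the restricted
log-likelihood by L-BFGS-B over log error variances and a
Cholesky-parameterized Ω_G (log diagonal, free off-diagonal), with GLS trial
means at the optimum. It is deterministic and ~20× faster than a full
chain, so cross-validation sweeps use it. A maximum-likelihood route was
preferred over an EM iteration because with T ≤ 5 the parameter count is
tiny and a quasi-Newton on the 600-plot profile likelihood converges in a
few hundred evaluations, with nothing structure-specific to derive.

Identifiability caveat: with a few hundred lines and strong family
structure, the genetic correlation is weakly identified for a single trait;
REML estimates can sit on the ρ = 1 boundary where the Gibbs posterior mean
is pulled interior by the prior. Recovery is therefore assessed as a median
over replicate traits (median |ρ̂ − ρ| ≤ 0.15 at N = 300).

## Simulator

The trait simulator draws from the model itself: g stacked trial-major is
L z with L = chol(Ω_G) ⊗ chol(K) (matrix-normal form, never materializing
NT×NT), phenotypes add μ_t and independent N(0, σ²_Et) plot errors with
σ²_Et = (1−h²_t)/h²_t · σ²_Gt. Default trial parameters — means 20/10/50/
30/40, genetic variances 1–5, plot heritabilities 0.2/0.8/0.6/0.4/0.5, a
common pairwise genetic correlation ρ ∈ {0.2, 0.5, 0.8} — define the
simulation study conditions; a T-trial scenario uses the first T columns.

The genotype simulator is a family-block founder model: global allele
frequencies uniform on (0.1, 0.9), per-family frequencies drawn from a
Balding–Nichols Beta (divergence 0.35), individuals binomial. It exists to
induce realistic relatedness (within-family VanRaden kinship well above the
0.2 pruning threshold) — it has no linkage, no LD, no QTL. Consequently
passing tests demonstrate the statistical machinery under the infinitesimal
model; they say nothing about trait architectures with major genes, about
marker-QTL ascertainment error, or about real spatial field effects, which
is exactly the gap between model-expected CD and realized reliability on
real data.

## Design optimization

Families: **I** (each allocated genotype once in the whole experiment),
**Ck** (each allocated genotype k times in every trial), **Opt** (no
within-trial replication; across-trial replication allowed). The optimizer
maximizes mean CD_it (or CD_i·) over an evaluation set of candidates —
conservative mode excludes the prediction targets from the criterion. CDs
for the objective use neutral unit-variance configurations with ρ = 1, 0,
0.5 for S, W, M; the default is M with mean CD_it.

The search combines a genetic algorithm with simulated annealing, defaults
2,000 generations × population 200 × 20 elites × 10 annealing moves:
uniform plot-level crossover between two random elites, per-plot mutation to
a random non-conflicting candidate (rate 0.05), within-trial duplicates
repaired at proposal time (hard constraint, never penalized); each elite
then takes Metropolis single-plot moves under geometric cooling (T₀ = 0.1 ×
the initial best objective, factor 0.9 per generation), keeping the polished
elite only if it did not lose ground. After the last generation the best
design gets zero-temperature steepest-ascent sweeps over (a bounded sample
of) single-plot replacements — cheap local optimality that closes the last
fraction of a percent the stochastic phase occasionally leaves. The trace
of best objectives is non-decreasing by construction; replicate runs differ
in the design but plateau at near-identical objectives, so correctness is
tested against exhaustive enumeration on small instances (global optimum
found in ≥ 95% of seeded runs) rather than by design identity.

## Validation machinery

Observed reliability is the squared Pearson correlation between true and
predicted genetic values over a genotype set (against reference phenotypes
it is the phenotype-based analogue). Calibration groups predictions into
sliding CD windows [x−0.05, x+0.05], x ∈ {0.05, …, 0.95}; windows are pruned
so no two members have kinship > 0.2 — iteratively removing the
second member of the earliest offending pair in id order, a deterministic
tie-break chosen for reproducibility — and windows below a minimum count
(default 50, configurable because desk-scale populations are far smaller
than the datasets the default was written for) are discarded. Each window
is scored independently; windows overlap by construction.

`cross_validate` runs the simulated-trait protocol: per replicate a fresh
training split observed once per trial, fresh plot errors (optionally fresh
genetic values), one fit per structure, test-set reliability per trial and
for mean performance. `compare_designs` holds out a test set, builds one
design per family from the remaining candidates at a common plot budget and
scores test-set reliability; by default it predicts with the true
simulation covariances, isolating the design effect from estimation noise
(set `use_true_covariances=False` to refit per design).

## Problem sizes used by the shipped checks

The test suite and `scripts/acceptance.py` run everything at desk scale,
chosen so the full suite completes in minutes on one CPU: the
three-genotype worked example exactly as published; path equivalence on 50
random instances with N ≤ 10, T ≤ 3; calibration with N = 120 lines in 12
families, 2 trials, ρ = 0.5, 500 simulated traits; structure ranking with
a 400-line pool, training sets of 300, 10 cross-validation replicates (REML
route); design-family comparison with a 200-line pool, 30 plots/trial, 10
replicates; optimizer-vs-enumeration on 8-candidate instances, 20 seeded
runs; Gibbs recovery at N = 300 with chains of 2,000 (burn-in 200,
thinning 5), 10 replicate traits.

## Known limitations

- Ω_G is unstructured; no factor-analytic reduction, so T beyond ~10 makes
  estimation fragile and slow.
- No spatial modeling within trials, no heterogeneous error within a trial,
  no non-Gaussian traits.
- The MME/PEV route materializes dense matrices; populations beyond a few
  thousand lines need sparse or low-rank refactoring.
- CD conditions on known variance parameters; uncertainty in Ω_G, Ω_E is
  not propagated into the forecast (the calibration experiments quantify
  how much that matters under the model).
- Generalized CDs for contrasts between genetic values are out of scope.
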