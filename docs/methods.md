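# Methods

This note documents the models, algorithms, defaults and numerical
choices behind `hblup`, and what the simulation-based validation does and
does not demonstrate.

## Relationship matrices

**NRM.** The numerator relationship matrix A is built with the tabular
recursion: founders get diagonal 1; an individual's relationship to an
earlier individual is the mean of its parents' relationships; its
diagonal is `1 + a(sire, dam)/2`.  Unknown parents contribute nothing and
are treated as unrelated, non-inbred base animals; the missing-parent
code defaults to `"0"` (configurable).  Parents referenced but never
listed are inserted as founders, since real pedigree files routinely omit
base animals.  The implementation is dense O(n²) — exact inbreeding, no
sparse-inverse machinery — which is comfortable up to a few times 10⁴
individuals and keeps the code auditable.  Genetic groups, metafounders
and sparse A⁻¹ assembly are out of scope.

**GRM.** `G_ij = (1/d) Σ_k z_ik z_jk w_k` with `z = x − 2p` and weights
`w = [2p(1−p)]^(2α)`.  Allele frequencies default to in-sample estimates
from the genotyped individuals; any base-population adjustment is the job
of the tuning step, though supplied frequencies are accepted.  The
normaliser `d` is the empirical mean of the weighted squared centred
genotypes (so `trace(G)/n = 1` exactly, for every α); the theoretical
Hardy–Weinberg sum `Σ_k [2p(1−p)]^(1+2α)` is available for equivalence
with the PLINK/GCTA convention at α = −0.5 and VanRaden method 1 at
α = 0.  Monomorphic markers are dropped (their weight is degenerate for
negative α) with a logged count; missing genotypes are mean-imputed to
`2p`, which makes them contribution-free after centring.  α is accepted
as any real in [−1.5, 1.5].

**Blending and tuning.**  Blending is the convex combination
`θG + (1−θ)A22`.  Tuning is the affine map `βG + ωJ`; method 2 fixes
β = 1 and matches the overall mean to `A22`, method 1 solves the
two-moment system (overall mean and diagonal mean), i.e.
`β = (mean(diag A22) − mean(A22)) / (mean(diag G) − mean(G))`,
`ω = mean(A22) − β·mean(G)`.  Both moment identities are enforced by
tests.  The default order applies tuning to the blended matrix; the
reverse order is supported and genuinely differs.  Defaults are θ = 1 and
no tuning — the package never adjusts silently, because the whole point
is that these knobs must be optimised per dataset.

**H assembly.**  The genotyped block of H is the adjusted G verbatim
(asserted bit-for-bit in tests); the non-genotyped blocks propagate the
difference `G* − A22` through `A22⁻¹` (Cholesky).  No positive-definite
repair is applied: the REML solver works on the phenotypic covariance
and only requires `V = Hσ²g + Iσ²e` to be positive definite, so an
indefinite H is acceptable; a warning is emitted for small matrices where
the check is cheap (n ≤ 500).

## REML, BLUP, AIC

The univariate animal model `y = Xb + g + e` is fitted by restricted
maximum likelihood with Average Information updates on (σ²g, σ²e), EM
fallback, and step-halving whenever a proposed step leaves the feasible
region or would reduce the restricted likelihood by more than the
tolerance.  One spectral decomposition `K = UΛU'` per fit makes each
iteration O(n·p²): in the rotated basis V is diagonal, so determinants,
traces and the REML projection come from elementwise arithmetic.
Negative eigenvalues of K are tolerated as long as every
`σ²g λ_i + σ²e` stays positive; infeasible starting points shrink σ²g
until feasible.

Defaults: intercept-only fixed effects (arbitrary covariates accepted),
starting values σ²g = σ²e = var(y)/2, convergence |Δ logL| < 1e-6,
at most 100 iterations, components floored at 1e-8·var(y) with a
boundary flag.  Non-convergence returns a flagged fit, not an exception.
`AIC = 2P − 2 lnL` with P = 2 (the variance components); only AIC
differences within a dataset are ever interpreted, so the convention for
P cancels.

BLUP for unphenotyped individuals uses the conditional mean
`ĝ_t = σ̂²g K[t, obs] V⁻¹(y − Xb̂)`; the fitted model stores
`V⁻¹(y − Xb̂)` so prediction is a single matrix-vector product.

**Precision.**  Everything runs in float64 by default.  Inside
cross-validated sweeps the spectral factorisation optionally runs in
float32 (`precision="single"`, the default for `run_cv`): it is about
twice as fast and reconstructs the kernel to ~1e-6 relative error, three
orders of magnitude below the accuracy contrasts the grid search
compares.  All likelihood arithmetic remains float64 either way; oracle
comparisons in the tests (likelihood grid, mixed-model equations) run
strict double precision.

## Simulator

The simulator emulates a livestock/human-style two-phase history:

* **Historical phase** — two-sex Wright–Fisher random union of gametes at
  constant size Ne (default 100) for 100 generations, markers initialised
  at frequency 0.5 independently per locus.  Drift generates the MAF
  spectrum and LD.  Reproduction draws each offspring's sire and dam
  independently, so the variance effective size equals the census size;
  the neutral decay of gene diversity, `H_t = 0.5 (1 − 1/(2Ne))^t`, is
  verified against Monte-Carlo replicates.  Scenario 1 (and 3) grow the
  census linearly from Ne to 1,000 over the last five historical
  generations; any monotone profile would do, the design only needs
  enough final-generation animals to draw founders.
* **Recent phase** — five pedigreed generations.  Scenario 1: 50 sires ×
  10 dams × 2 offspring (paternal half-sib families of 20, 1,000
  offspring/generation; founders 550).  Scenarios 2–3: 500 monogamous
  pairs × 2 offspring (full-sib design).  Scenario 2 uses Ne = 1,000
  throughout with no expansion.  Sexes are assigned exactly balanced in
  random order rather than Bernoulli(0.5) per individual, so the stated
  mating designs are feasible every generation by construction.
* **Meiosis** — Haldane model: Poisson(1) crossovers per 100 cM placed
  uniformly, random start phase; symmetric allele-flip mutation at
  2.8e-8 per locus per meiosis (negligible but present).  Genome default:
  30 chromosomes × 300 markers × 100 cM (9,000 markers), uniform random
  marker positions.
* **Phenotypes** — 1,000 causal markers drawn from the panel (they stay
  in the panel for GRM building; an exclusion option exists), raw effects
  N(0, 1) scaled by `[2p(1−p)]^α_true`, genetic values standardised to
  variance h², residuals N(0, 1 − h²).  The generative `alpha_true` and
  the GRM's `alpha` are deliberately separate concepts.

What the simulator does **not** reproduce: selection (mating and
retention are random by design), marker ascertainment (no MAF floor —
markers drift freely and monomorphic ones are dropped at GRM time),
genotyping error, pedigree error, and real-data fixed-effect structure.
Passing tests therefore demonstrate internal consistency of the method
and its estimators under a neutral polygenic architecture, not
performance on any particular livestock population.

## Evaluation protocol

Targets are the genotyped offspring of the last two generations, split
into k = 5 disjoint folds; per fold, the targets' phenotypes are masked
(the individuals remain in H), variance components are re-estimated on
the discovery set (all other phenotyped individuals, founders included),
and targets get BLUP genetic values.  Accuracy is the Pearson R between
observed phenotypes and predicted genetic values — no division by h, to
keep it a phenotypic prediction accuracy; RMSE is computed against
`b̂ + ĝ` so the error is on the phenotype scale.  Reported means are
unweighted over folds; folds that fail to converge are dropped with a
warning.

The full grid is tune ∈ {0, 1, 2} × θ ∈ {0→1 step 0.1} ∪ {0.9→1 step
0.02} × α ∈ {−1→1 step 0.1} (945 configurations after deduplication); a
coarse grid (tune {0, 1}, θ {0.5, 0.9, 1.0}, α {−1, −0.5, 0, 0.5, 1}) is
the default for desk-scale work.  Best = maximum mean fold R; exact ties
break toward parsimony (smaller |α|, then larger θ, then smaller tuning
index).  An AIC profile over the same grid reports ΔAIC relative to the
best-fitting configuration.

## Problem sizes and statistical power

The validation experiments run at deliberately reduced sizes, chosen
once:

* grid-search experiments: scenario 1 with 18 sires/generation
  (198 founders + 5 × 360 offspring = 1,998 individuals, 720 genotyped,
  folds of 144), full 9,000-marker genome;
* heritability recovery: full 1,000-offspring generations, 3,000
  markers, phenotypes and GRM on the 1,000 last-generation offspring;
* sensitivity/contrast replicates: 6 sires/generation, 3,000 markers.

A caveat the replicated experiments make explicit: the mean
cross-validated accuracy curve over α peaks at the generative value, but
the curvature near the peak is shallow — neighbouring grid values
(|Δα| = 0.5) differ by ~1e-3 in mean R while the dataset-to-dataset
noise of that contrast is of the same order.  Selection of the exact
generative α from a single reduced dataset is therefore a stochastic
outcome (correct more often than any competitor, but not guaranteed),
and the same holds for the near-tied θ ∈ {0.9, 1.0} contrast.  This
mirrors the flatness of the accuracy surface that motivates explicit
hyper-parameter optimisation in the first place.

The degradation away from the peak is strongly asymmetric.  Using a
scale factor a full unit *below* the generative value (over-weighting
rare variants, whose genotype scores are the noisiest) collapses
accuracy by ~0.3 and loses in every replicate; a full unit *above*
(over-weighting common variants) costs under 0.01 on average, and
because each replicate draws a fresh causal architecture, roughly a
quarter of realizations genuinely favour the higher α.  Replicate-level
win rates for the positive offset therefore plateau around 70–75%
regardless of population size — a property of the generative model, not
of estimator noise.

## Known limitations

Single trait, single genetic variance component, dense linear algebra
throughout (no sparse MME route, no APY); no LD-based marker weighting;
no genetic groups; no bias/dispersion validation statistics beyond R and
RMSE.  The GCTA-format GRM export uses float32, as the format dictates.
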