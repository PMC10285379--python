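# hblup

Single-step genetic evaluation (HBLUP) with explicit hyper-parameters:
blending weight θ, tuning method, and GRM scale factor α.

## The problem

Livestock genetic evaluations routinely hold phenotypes for many animals
that were never genotyped.  Single-step evaluation harmonises the
pedigree numerator relationship matrix **A** (which covers everyone) with
the genomic relationship matrix **G** (genotyped animals only) into one
matrix **H**, so that every phenotyped animal contributes to genomic
prediction.  With the genotyped block written `A22`,

```
H = | A11 + A12 A22⁻¹ (G* − A22) A22⁻¹ A21    A12 A22⁻¹ G* |
    | G* A22⁻¹ A21                            G*           |
```

where `G*` is the genomic matrix after two standard adjustments and one
less standard one:

* **blending** `G_blended = θ G + (1 − θ) A22`, θ ∈ [0, 1] — shrinks
  genomic toward pedigree relationships (and can repair an indefinite G);
* **tuning** `G_tuned = β G_blended + ω J` — matches the mean (method 2,
  β = 1) or both mean and mean diagonal (method 1) of the GRM to `A22`,
  compensating for unobserved base-population allele frequencies;
* **scale factor** α — the GRM itself is parameterised as

  `G_ij = (1/d) Σ_k (x_ik − 2p_k)(x_jk − 2p_k) [2p_k(1 − p_k)]^(2α)`,

  encoding the assumption that per-allele effect sizes are proportional
  to `[2p(1 − p)]^α`.  α = −0.5 is the PLINK/GCTA standardised GRM,
  α = 0 is VanRaden method 1; neither is optimal for every trait.

Variance components `y = Xb + g + e`, `g ~ N(0, H σ²g)`, `e ~ N(0, I σ²e)`
are estimated with the direct Average Information REML algorithm (which
tolerates an indefinite H), genetic values are predicted by BLUP, model
fit is compared by `AIC = 2P − 2 lnL`, and the three hyper-parameters are
optimised by an exhaustive grid search under k-fold cross-validation.
A forward-in-time simulator (neutral historical phase, then half-sib or
full-sib pedigreed designs) provides calibrated test populations.

## Worked example

```python
from hblup import (ScenarioConfig, GenomeSpec, PhenotypeSimConfig,
                   simulate_scenario, simulate_phenotypes, EvalDataset,
                   CVDesign, GridSpec, grid_search)

cfg = ScenarioConfig(scenario=1, n_sires=8, dams_per_sire=10)
pop = simulate_scenario(cfg, GenomeSpec(n_chromosomes=10), seed=21)
phe = simulate_phenotypes(pop, PhenotypeSimConfig(
    n_causal=500, h2=0.8, alpha_true=-0.5, seed=22))
ds = EvalDataset.from_population(pop, phe)

grid = GridSpec(tune=(0, 1), theta=(0.9, 1.0), alpha=(-1.0, -0.5, 0.0, 0.5))
result = grid_search(ds, grid, CVDesign(ds.genotyped_ids, k=5, seed=23),
                     with_aic=False)
print(result.best[["tune", "theta", "alpha", "mean_r"]])
```

Running `python examples/04_grid_search.py` (the same experiment) prints

```
 tune  theta  alpha   mean_r  mean_rmse
    1    1.0    0.0 0.702822   0.681845
    1    1.0    0.5 0.701663   0.683109
    0    1.0    0.0 0.700440   0.686782
    1    1.0   -0.5 0.700336   0.683324
    ...
    1    1.0   -1.0 0.627894   0.748418

selected: tune=1, theta=1.0, alpha=0.0 (mean fold R = 0.7028)
```

`mean_r` is the Pearson correlation between observed phenotypes and BLUP
genetic values of held-out genotyped offspring, averaged over five folds.
The output shows the two sides of the accuracy surface: a badly wrong
scale factor (α = −1.0, a full unit below the generative −0.5) costs
about 0.07 in accuracy, while configurations within half a unit of the
truth are separated only in the third decimal — on a small single
dataset the argmax can land on a neighbour of the generative value, as
here.  θ = 1 (no blending) wins, and tuning helps slightly.  This
flatness near the optimum, against steep losses farther away, is exactly
why the hyper-parameters deserve explicit optimisation rather than
convention.  The other scripts in `examples/` walk through pedigree/NRM
construction, GRM scale factors, and a full single-step REML + BLUP fit.

A thin CLI mirrors the library:

```
hblup simulate --scenario 1 --alpha-true -0.5 --h2 0.8 --seed 7 --out data/
hblup grm --genotypes data/genotypes.raw --alpha -0.5 --out out/grm
hblup reml --pedigree data/pedigree.csv --genotypes data/genotypes.raw \
           --phenotypes data/phenotypes.tsv --alpha -0.5 --out out/reml
hblup gridsearch --pedigree data/pedigree.csv --genotypes data/genotypes.raw \
           --phenotypes data/phenotypes.tsv --out out/grid
```

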