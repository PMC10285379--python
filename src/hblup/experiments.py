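"""Prepackaged validation experiments at desk scale.

These functions bundle the simulation designs and evaluation protocols the
package uses to validate itself end to end: a scenario-1 dataset with a
known generative scale factor, the coarse hyper-parameter grid search
under 5-fold cross-validation, heritability-recovery replicates, and the
blending contrast (theta = 1 vs theta = 0.9).

Problem sizes are deliberately reduced relative to a full livestock
evaluation so each experiment runs in minutes on a single core: the
scenario-1 design keeps its family structure (10 dams per sire, 2
offspring per dam, 5 pedigreed generations, genotypes on the last two)
but uses 18 sires per generation (360 offspring per generation, 1,980
individuals, 720 genotyped) instead of 50, and the full 9,000-marker
genome.  Heritability-recovery replicates keep the full 1,000-offspring
generations but use a 3,000-marker genome, since marker count does not
enter the recovery property.
"""

from __future__ import annotations

import numpy as np

from .evaluation import CVDesign, EvalDataset, GridResult, coarse_grid, grid_search, pearson_r, run_cv
from .grm import compute_grm
from .mixed_model import fit_reml, predict_blup
from .simulator import (
    GenomeSpec,
    PhenotypeSimConfig,
    ScenarioConfig,
    simulate_phenotypes,
    simulate_scenario,
)

__all__ = [
    "desk_scenario1_dataset",
    "scenario1_grid_selection",
    "h2_recovery_replicates",
    "blending_contrast_replicates",
]

DESK_N_SIRES = 18


def desk_scenario1_dataset(
    alpha_true: float,
    seed: int,
    h2: float = 0.8,
    n_sires: int = DESK_N_SIRES,
    n_chromosomes: int = 30,
    n_causal: int = 1000,
) -> EvalDataset:
    """Scenario-1 dataset (reduced census, full marker genome)."""
    cfg = ScenarioConfig(scenario=1, n_sires=n_sires, dams_per_sire=10)
    genome = GenomeSpec(n_chromosomes=n_chromosomes)
    pop = simulate_scenario(cfg, genome, seed=seed)
    phe = simulate_phenotypes(pop, PhenotypeSimConfig(
        n_causal=n_causal, h2=h2, alpha_true=alpha_true, seed=seed + 10_000))
    return EvalDataset.from_population(pop, phe)


def scenario1_grid_selection(
    alpha_true: float,
    seed: int,
    grid=None,
    k: int = 5,
    **dataset_kwargs,
) -> GridResult:
    """Coarse grid search under k-fold CV on one scenario-1 dataset.

    Targets are the genotyped offspring of the last two generations; the
    discovery set per fold is every other phenotyped individual.
    """
    ds = desk_scenario1_dataset(alpha_true, seed, **dataset_kwargs)
    design = CVDesign(target_pool=ds.genotyped_ids, k=k, seed=seed + 20_000)
    return grid_search(ds, grid or coarse_grid(), design, with_aic=False)


def h2_recovery_replicates(
    n_replicates: int,
    seed: int,
    h2: float = 0.8,
    alpha_true: float = 0.0,
    n_chromosomes: int = 10,
) -> np.ndarray:
    """REML heritability estimates across simulation replicates.

    Each replicate simulates the full scenario-1 design, phenotypes the
    1,000 offspring of the last generation, and fits the genomic
    relationship matrix built with the matching scale factor.
    """
    genome = GenomeSpec(n_chromosomes=n_chromosomes)
    estimates = np.empty(n_replicates)
    for rep in range(n_replicates):
        rep_seed = seed + 1000 * rep
        cfg = ScenarioConfig(scenario=1, seed=rep_seed)
        pop = simulate_scenario(cfg, genome)
        phe = simulate_phenotypes(pop, PhenotypeSimConfig(
            n_causal=1000, h2=h2, alpha_true=alpha_true, seed=rep_seed + 1))
        ids = pop.ids_of_generations([int(pop.generation.max())])
        K = compute_grm(pop.genotypes(ids), alpha=alpha_true).values
        pos = {ident: i for i, ident in enumerate(pop.ids)}
        y = phe["trait"].to_numpy()[[pos[i] for i in ids]]
        fit = fit_reml(y, None, K, compute_blup=False)
        estimates[rep] = fit.h2
    return estimates


def blending_contrast_replicates(
    n_replicates: int,
    seed: int,
    thetas: tuple[float, float] = (1.0, 0.9),
    alpha: float = -0.5,
    tune_method: int = 1,
    h2: float = 0.8,
    n_sires: int = 6,
    n_chromosomes: int = 10,
    holdout_fraction: float = 0.2,
) -> np.ndarray:
    """Per-replicate accuracy difference R(theta_a) - R(theta_b).

    Each replicate simulates a reduced scenario-1 dataset (generative
    scale factor equal to ``alpha``), holds out a random fraction of the
    genotyped offspring as targets, and evaluates HBLUP accuracy at the
    two blending weights with everything else fixed.
    """
    diffs = np.empty(n_replicates)
    for rep in range(n_replicates):
        rep_seed = seed + 1000 * rep
        ds = desk_scenario1_dataset(alpha, rep_seed, h2=h2, n_sires=n_sires,
                                    n_chromosomes=n_chromosomes)
        rng = np.random.default_rng(rep_seed + 5)
        pool = ds.genotyped_ids
        targets = list(rng.choice(pool, int(len(pool) * holdout_fraction),
                                  replace=False))
        r = {}
        for theta in thetas:
            H = ds.build_h(alpha, theta, tune_method)
            hpos = {ident: i for i, ident in enumerate(H.ids)}
            obs = [i for i in ds.phenotyped_ids if i not in set(targets)]
            oi = np.array([hpos[i] for i in obs])
            fit = fit_reml(ds.phenotypes[obs].to_numpy(), None,
                           H.values[np.ix_(oi, oi)], ids=obs,
                           compute_blup=False)
            pred = predict_blup(fit, H.values, H.ids, obs, targets)
            r[theta] = pearson_r(ds.phenotypes[targets].to_numpy(), pred)
        diffs[rep] = r[thetas[0]] - r[thetas[1]]
    return diffs
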