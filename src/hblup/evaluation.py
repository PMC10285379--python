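"""Cross-validated prediction accuracy and hyper-parameter grid search.

The evaluation protocol mirrors a routine genetic-evaluation validation:
the genotyped offspring of the most recent generations form a target pool
that is split into ``k`` disjoint folds.  For each fold the targets'
phenotypes are masked (the individuals stay inside the H matrix), variance
components are re-estimated on the discovery set by REML, targets receive
BLUP genetic values, and accuracy is summarised as the Pearson correlation
(R) between observed phenotypes and predicted genetic values plus the
RMSE of the calibrated predictions.

The grid search evaluates every combination of the three HBLUP
hyper-parameters — tuning method (0/1/2), blending weight theta, and GRM
scale factor alpha — and selects the configuration with the highest mean
fold R.  Exact ties are broken toward parsimony: smaller ``|alpha|``,
larger theta, smaller tuning index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .grm import GenotypeMatrix, compute_grm
from .hmatrix import HMatrix, adjust_grm, assemble_h
from .mixed_model import ModelFit, fit_reml, predict_blup
from .pedigree import Pedigree, build_nrm, partition_nrm

__all__ = [
    "pearson_r",
    "rmse",
    "CVDesign",
    "GridSpec",
    "GridResult",
    "EvalDataset",
    "run_cv",
    "grid_search",
    "aic_profile",
    "paper_grid",
    "coarse_grid",
]

logger = logging.getLogger(__name__)


def pearson_r(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation; errors on degenerate input."""
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if a.size != b.size or a.size < 3:
        raise ValueError("vectors must have equal length >= 3")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("correlation undefined for a zero-variance vector")
    return float(np.corrcoef(a, b)[0, 1])


def rmse(a: np.ndarray, b: np.ndarray) -> float:
    """Root mean squared difference."""
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if a.size != b.size:
        raise ValueError("vectors must have equal length")
    return float(np.sqrt(np.mean((a - b) ** 2)))


@dataclass
class CVDesign:
    """k disjoint folds covering a target pool, drawn from a seed."""

    target_pool: list[str]
    k: int = 5
    seed: int = 0
    folds: list[list[str]] = field(init=False)

    def __post_init__(self) -> None:
        if self.k < 2 or self.k > len(self.target_pool):
            raise ValueError("k must be in [2, |target pool|]")
        rng = np.random.default_rng(self.seed)
        order = rng.permutation(len(self.target_pool))
        self.folds = [
            [self.target_pool[j] for j in chunk]
            for chunk in np.array_split(order, self.k)
        ]


@dataclass
class GridSpec:
    """Hyper-parameter grids (deduplicated, sorted)."""

    tune: tuple[int, ...] = (0, 1, 2)
    theta: tuple[float, ...] = ()
    alpha: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        self.tune = tuple(sorted(set(int(t) for t in self.tune)))
        self.theta = tuple(sorted({round(float(t), 10) for t in self.theta}))
        self.alpha = tuple(sorted({round(float(a), 10) for a in self.alpha}))

    def configurations(self):
        for t in self.tune:
            for th in self.theta:
                for al in self.alpha:
                    yield t, th, al

    def __len__(self) -> int:
        return len(self.tune) * len(self.theta) * len(self.alpha)


def paper_grid() -> GridSpec:
    """The full published grid: 3 tune x 15 theta x 21 alpha = 945 cells."""
    theta = np.concatenate([np.arange(0.0, 1.0001, 0.1),
                            np.arange(0.9, 1.0001, 0.02)])
    alpha = np.arange(-1.0, 1.0001, 0.1)
    return GridSpec(tune=(0, 1, 2), theta=tuple(theta), alpha=tuple(alpha))


def coarse_grid() -> GridSpec:
    """Desk-scale grid for quick searches."""
    return GridSpec(tune=(0, 1), theta=(0.5, 0.9, 1.0),
                    alpha=(-1.0, -0.5, 0.0, 0.5, 1.0))


@dataclass
class EvalDataset:
    """Pedigree + genotypes + phenotypes, with cached relationship pieces."""

    pedigree: Pedigree
    genotypes: GenotypeMatrix
    phenotypes: pd.Series  # indexed by individual id; NaN = missing
    _cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        missing = [i for i in self.genotypes.ids if i not in self.pedigree.index]
        if missing:
            raise KeyError(f"genotyped ids not in pedigree: {missing[:10]}")
        self.phenotypes = self.phenotypes.astype(float)

    @classmethod
    def from_population(cls, pop, phenotypes: pd.DataFrame,
                        genotyped_generations: int = 2) -> "EvalDataset":
        geno_ids = pop.last_generations(genotyped_generations)
        phe = pd.Series(
            phenotypes["trait"].to_numpy(), index=phenotypes["id"].astype(str)
        )
        return cls(pop.pedigree(), pop.genotypes(geno_ids), phe)

    @property
    def genotyped_ids(self) -> list[str]:
        return list(self.genotypes.ids)

    @property
    def phenotyped_ids(self) -> list[str]:
        return [i for i in self.phenotypes.index if np.isfinite(self.phenotypes[i])]

    def nrm_blocks(self):
        if "blocks" not in self._cache:
            A = build_nrm(self.pedigree)
            self._cache["A_ids"] = A.ids
            self._cache["blocks"] = partition_nrm(A, self.genotyped_ids)
        return self._cache["blocks"]

    def grm(self, alpha: float):
        key = ("grm", round(float(alpha), 10))
        if key not in self._cache:
            self._cache[key] = compute_grm(self.genotypes, alpha=alpha)
        return self._cache[key]

    def build_h(self, alpha: float, theta: float = 1.0, tune_method: int = 0,
                order: str = "blend_then_tune") -> HMatrix:
        A11, A12, A21, A22 = self.nrm_blocks()
        G = self.grm(alpha).values
        G_adj = adjust_grm(G, A22, theta=theta, tune_method=tune_method,
                           order=order)
        nongeno = [i for i in self._cache["A_ids"] if i not in set(self.genotyped_ids)]
        return assemble_h(A11, A12, A21, A22, G_adj,
                          ids_nongenotyped=nongeno,
                          ids_genotyped=self.genotyped_ids,
                          alpha=alpha, theta=theta, tune_method=tune_method)


def run_cv(
    dataset: EvalDataset,
    tune_method: int,
    theta: float,
    alpha: float,
    design: CVDesign,
    tol: float = 1e-6,
    max_iter: int = 100,
    order: str = "blend_then_tune",
    precision: str = "single",
) -> pd.DataFrame:
    """Per-fold HBLUP accuracy for one hyper-parameter configuration.

    Returns a DataFrame with one row per fold (r, rmse, h2, logL,
    converged).  Folds whose REML fit fails to converge are flagged;
    summaries downstream average over converged folds only.  The per-fold
    REML runs its spectral factorisation in single precision by default
    (see :func:`hblup.mixed_model.fit_reml`); pass ``precision="double"``
    for strict double precision.
    """
    H = dataset.build_h(alpha, theta, tune_method, order)
    hpos = {ident: i for i, ident in enumerate(H.ids)}
    phen = dataset.phenotypes
    phen_ids = dataset.phenotyped_ids

    rows = []
    for f, fold in enumerate(design.folds):
        fold_set = set(fold)
        obs_ids = [i for i in phen_ids if i not in fold_set]
        oi = np.array([hpos[i] for i in obs_ids])
        K_obs = H.values[np.ix_(oi, oi)]
        y_obs = phen[obs_ids].to_numpy()
        fit = fit_reml(y_obs, None, K_obs, ids=obs_ids, tol=tol,
                       max_iter=max_iter, compute_blup=False,
                       precision=precision)
        pred_g = predict_blup(fit, H.values, H.ids, obs_ids, fold)
        y_t = phen[fold].to_numpy()
        intercept = float(fit.fixed_effects[0])
        rows.append({
            "fold": f,
            "n_target": len(fold),
            "r": pearson_r(y_t, pred_g),
            "rmse": rmse(y_t, intercept + pred_g),
            "h2": fit.h2,
            "logL": fit.logL,
            "converged": fit.converged,
        })
        if not fit.converged:
            logger.warning("fold %d REML did not converge (tune=%s theta=%s "
                           "alpha=%s)", f, tune_method, theta, alpha)
    return pd.DataFrame(rows)


@dataclass
class GridResult:
    table: pd.DataFrame         # one row per configuration
    folds: pd.DataFrame         # one row per configuration x fold
    best: pd.Series             # the selected configuration

    @property
    def best_alpha(self) -> float:
        return float(self.best["alpha"])

    @property
    def best_theta(self) -> float:
        return float(self.best["theta"])

    @property
    def best_tune(self) -> int:
        return int(self.best["tune"])


def _select_best(table: pd.DataFrame) -> pd.Series:
    # max mean R; exact ties resolved toward parsimony
    ranked = table.sort_values(
        by=["mean_r", "abs_alpha", "theta", "tune"],
        ascending=[False, True, False, True],
        kind="mergesort",
    )
    return ranked.iloc[0]


def grid_search(
    dataset: EvalDataset,
    grid: GridSpec,
    design: CVDesign,
    with_aic: bool = True,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> GridResult:
    """Exhaustive CV evaluation of every grid configuration."""
    cfg_rows = []
    fold_rows = []
    for tune_m, theta, alpha in grid.configurations():
        folds = run_cv(dataset, tune_m, theta, alpha, design,
                       tol=tol, max_iter=max_iter)
        folds.insert(0, "tune", tune_m)
        folds.insert(1, "theta", theta)
        folds.insert(2, "alpha", alpha)
        fold_rows.append(folds)
        ok = folds[folds["converged"]]
        if len(ok) < len(folds):
            logger.warning("configuration (tune=%s, theta=%s, alpha=%s): "
                           "%d/%d folds converged", tune_m, theta, alpha,
                           len(ok), len(folds))
        row = {
            "tune": tune_m,
            "theta": theta,
            "alpha": alpha,
            "abs_alpha": abs(alpha),
            "mean_r": ok["r"].mean() if len(ok) else np.nan,
            "sd_r": ok["r"].std(ddof=1) if len(ok) > 1 else np.nan,
            "mean_rmse": ok["rmse"].mean() if len(ok) else np.nan,
            "sd_rmse": ok["rmse"].std(ddof=1) if len(ok) > 1 else np.nan,
            "n_folds_converged": len(ok),
        }
        if with_aic:
            fit = _full_data_fit(dataset, tune_m, theta, alpha, tol, max_iter)
            row["aic"] = fit.aic
            row["h2_full"] = fit.h2
        cfg_rows.append(row)

    table = pd.DataFrame(cfg_rows)
    best = _select_best(table)
    return GridResult(table=table.drop(columns=["abs_alpha"]),
                      folds=pd.concat(fold_rows, ignore_index=True),
                      best=best)


def _full_data_fit(dataset: EvalDataset, tune_m: int, theta: float,
                   alpha: float, tol: float, max_iter: int) -> ModelFit:
    H = dataset.build_h(alpha, theta, tune_m)
    hpos = {ident: i for i, ident in enumerate(H.ids)}
    ids = dataset.phenotyped_ids
    idx = np.array([hpos[i] for i in ids])
    K = H.values[np.ix_(idx, idx)]
    y = dataset.phenotypes[ids].to_numpy()
    return fit_reml(y, None, K, ids=ids, tol=tol, max_iter=max_iter,
                    compute_blup=False)


def aic_profile(
    dataset: EvalDataset,
    grid: GridSpec,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> pd.DataFrame:
    """Full-data REML AIC for every configuration, with delta-AIC column.

    ``delta_aic`` is relative to the best (minimum-AIC) configuration, so
    the optimum row is exactly zero.
    """
    rows = []
    for tune_m, theta, alpha in grid.configurations():
        fit = _full_data_fit(dataset, tune_m, theta, alpha, tol, max_iter)
        rows.append({
            "tune": tune_m, "theta": theta, "alpha": alpha,
            "aic": fit.aic, "logL": fit.logL, "h2": fit.h2,
            "converged": fit.converged,
        })
    df = pd.DataFrame(rows)
    df["delta_aic"] = df["aic"] - df["aic"].min()
    return df
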