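"""AI-REML and BLUP against independent likelihood-grid and MME oracles."""

import numpy as np
import pytest

import hblup as hb
from hblup.mixed_model import (
    ModelFit,
    VarianceComponents,
    aic,
    fit_reml,
    predict_blup,
    reml_loglik,
)
from conftest import random_pedigree
from hblup.pedigree import build_nrm


def _simulate(rng, K, sg2, se2, n=None):
    n = n or K.shape[0]
    L = np.linalg.cholesky(K + 1e-10 * np.eye(n))
    g = L @ rng.standard_normal(n) * np.sqrt(sg2)
    return 3.0 + g + rng.standard_normal(n) * np.sqrt(se2)


# --- AIC ---------------------------------------------------------------------

@pytest.mark.parametrize("logL, P, expected", [(-100.0, 2, 204.0), (0.0, 3, 6.0)])
def test_aic_formula(logL, P, expected):
    assert aic(logL, P) == expected


def test_aic_requires_positive_params():
    with pytest.raises(ValueError):
        aic(0.0, 0)


# --- REML vs likelihood grid -------------------------------------------------

def test_reml_beats_brute_force_likelihood_grid(rng):
    """AI-REML optimum dominates a 200x200 grid evaluated through the
    dense-factorisation likelihood (an independent code path)."""
    n = 40
    ped = random_pedigree(n, rng)
    K = build_nrm(ped).values
    y = _simulate(rng, K, 0.6, 0.4)
    X = np.ones((n, 1))
    fit = fit_reml(y, X, K)
    assert fit.converged
    vy = y.var()
    grid = np.linspace(0.01, 2.5, 200) * vy / 2
    best_grid = max(
        reml_loglik(y, X, sg * K + se * np.eye(n))
        for sg in grid for se in grid
    )
    assert fit.logL >= best_grid - 1e-4


def test_reml_loglik_agrees_with_rotated_path(rng):
    n = 30
    ped = random_pedigree(n, rng)
    K = build_nrm(ped).values
    y = _simulate(rng, K, 0.5, 0.5)
    fit = fit_reml(y, None, K)
    dense = reml_loglik(y, np.ones((n, 1)),
                        fit.sigma_g2 * K + fit.sigma_e2 * np.eye(n))
    assert fit.logL == pytest.approx(dense, abs=1e-8)


def test_restricted_likelihood_translation_invariant(rng):
    n = 35
    ped = random_pedigree(n, rng)
    K = build_nrm(ped).values
    y = _simulate(rng, K, 0.5, 0.5)
    f1 = fit_reml(y, None, K)
    f2 = fit_reml(y + 100.0, None, K)
    assert f1.logL == pytest.approx(f2.logL, abs=1e-6)
    assert f1.h2 == pytest.approx(f2.h2, abs=1e-6)


def test_rank_deficient_design_rejected(rng):
    n = 20
    K = np.eye(n)
    X = np.ones((n, 2))  # duplicated intercept
    with pytest.raises(ValueError, match="rank deficient"):
        fit_reml(np.arange(n, dtype=float), X, K)


# --- BLUP vs hand-built mixed-model equations --------------------------------

def test_blup_matches_henderson_mme(rng):
    """5-individual pedigree; Henderson's MME solved directly."""
    from hblup.pedigree import Pedigree, PedigreeRecord
    ped = Pedigree([
        PedigreeRecord("1"), PedigreeRecord("2"),
        PedigreeRecord("3", "1", "2"), PedigreeRecord("4", "1", "0"),
        PedigreeRecord("5", "3", "4"),
    ])
    A = build_nrm(ped).values
    obs = [0, 1, 2]        # first three phenotyped
    tgt = [3, 4]
    y = np.array([1.2, -0.4, 0.7])
    sg2, se2 = 0.6, 0.4

    # Henderson MME for all 5 breeding values (X = intercept, Z selects obs)
    n, q = len(y), 5
    X = np.ones((n, 1))
    Z = np.zeros((n, q))
    Z[np.arange(n), obs] = 1.0
    lam = se2 / sg2
    Ainv = np.linalg.inv(A)
    lhs = np.block([
        [X.T @ X, X.T @ Z],
        [Z.T @ X, Z.T @ Z + lam * Ainv],
    ])
    rhs = np.concatenate([X.T @ y, Z.T @ y])
    sol = np.linalg.solve(lhs, rhs)
    g_mme = sol[1:]

    # package route: construct the fit at the same variances, then predict
    K_obs = A[np.ix_(obs, obs)]
    V = sg2 * K_obs + se2 * np.eye(n)
    beta = np.linalg.solve(X.T @ np.linalg.solve(V, X),
                           X.T @ np.linalg.solve(V, y)).item()
    fit = ModelFit(
        varcomp=VarianceComponents(sg2, se2), logL=0.0, n_params=2,
        fixed_effects=np.array([beta]), converged=True, n_iter=0,
        ids=["1", "2", "3"],
        vinv_resid=np.linalg.solve(V, y - beta),
    )
    pred = predict_blup(fit, A, ["1", "2", "3", "4", "5"],
                        ["1", "2", "3"], ["4", "5"])
    np.testing.assert_allclose(pred, g_mme[tgt], atol=1e-8)
    assert beta == pytest.approx(sol[0], abs=1e-8)


def test_blup_shrinks_to_zero_without_genetic_variance():
    fit = ModelFit(
        varcomp=VarianceComponents(0.0, 1.0), logL=0.0, n_params=2,
        fixed_effects=np.zeros(1), converged=True, n_iter=0,
        ids=["a", "b"], vinv_resid=np.array([0.3, -0.3]),
    )
    K = np.eye(3)
    pred = predict_blup(fit, K, ["a", "b", "c"], ["a", "b"], ["c"])
    np.testing.assert_array_equal(pred, [0.0])


def test_blup_interpolates_duplicate_individual_as_noise_vanishes(rng):
    """A target with a relationship row identical to an observed individual
    (K_tt = K_oo) recovers that individual's centred phenotype as
    sigma_e^2 -> 0."""
    n = 6
    a = rng.standard_normal((n, 2 * n))
    K_oo = a @ a.T / (2 * n) + 0.5 * np.eye(n)
    y = rng.standard_normal(n)
    sg2, se2 = 1.0, 1e-10
    V = sg2 * K_oo + se2 * np.eye(n)
    X = np.ones((n, 1))
    beta = np.linalg.solve(X.T @ np.linalg.solve(V, X),
                           X.T @ np.linalg.solve(V, y)).item()
    obs_ids = [f"o{i}" for i in range(n)]
    fit = ModelFit(
        varcomp=VarianceComponents(sg2, se2), logL=0.0, n_params=2,
        fixed_effects=np.array([beta]), converged=True, n_iter=0,
        ids=obs_ids, vinv_resid=np.linalg.solve(V, y - beta),
    )
    K_full = np.zeros((n + 1, n + 1))
    K_full[:n, :n] = K_oo
    K_full[n, :n] = K_oo[0]       # duplicate of observed individual 0
    K_full[:n, n] = K_oo[0]
    K_full[n, n] = K_oo[0, 0]
    pred = predict_blup(fit, K_full, obs_ids + ["t"], obs_ids, ["t"])
    assert pred[0] == pytest.approx(y[0] - beta, abs=1e-6)


def test_predict_rejects_overlap_and_unknown_ids():
    fit = ModelFit(
        varcomp=VarianceComponents(1.0, 1.0), logL=0.0, n_params=2,
        fixed_effects=np.zeros(1), converged=True, n_iter=0,
        ids=["a"], vinv_resid=np.array([1.0]),
    )
    with pytest.raises(ValueError, match="overlap"):
        predict_blup(fit, np.eye(2), ["a", "b"], ["a"], ["a"])
    with pytest.raises(KeyError):
        predict_blup(fit, np.eye(2), ["a", "b"], ["a"], ["zz"])


# --- recovery properties -----------------------------------------------------

def test_null_heritability_hits_boundary(small_population):
    """Pure-noise phenotypes: h2 estimates collapse toward zero."""
    pop = small_population
    ids = pop.last_generations(3)[:500]
    K = hb.compute_grm(pop.genotypes(ids), alpha=0.0).values
    from scipy.linalg import eigh
    eig = eigh(K, driver="evd")
    rng = np.random.default_rng(123)
    hits = 0
    reps = 50
    for _ in range(reps):
        y = rng.standard_normal(len(ids))
        fit = fit_reml(y, None, K, eig=eig, compute_blup=False)
        hits += fit.h2 < 0.05
    assert hits >= 0.9 * reps


@pytest.mark.parametrize("h2_true", [0.2, 0.5])
def test_h2_recovery_mean_is_unbiased(small_population, h2_true):
    """GRM-based REML recovers the simulated heritability on average
    (reduced replicate count; the h2=0.8 case runs at full strength in the
    acceptance suite)."""
    pop = small_population
    ids = pop.last_generations(3)
    gm = pop.genotypes(ids)
    K = hb.compute_grm(gm, alpha=0.0).values
    from scipy.linalg import eigh
    eig = eigh(K, driver="evd")
    pos = {ident: i for i, ident in enumerate(pop.ids)}
    idx = [pos[i] for i in ids]
    ests = []
    for rep in range(25):
        phe = hb.simulate_phenotypes(
            pop, hb.PhenotypeSimConfig(n_causal=300, h2=h2_true,
                                       alpha_true=0.0, seed=1000 + rep))
        y = phe["trait"].to_numpy()[idx]
        fit = fit_reml(y, None, K, eig=eig, compute_blup=False)
        ests.append(fit.h2)
    assert np.mean(ests) == pytest.approx(h2_true, abs=0.06)
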