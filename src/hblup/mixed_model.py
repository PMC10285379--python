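"""REML variance components and BLUP under a genomic/pedigree covariance.

The model is the standard animal model

    y = X b + g + e,   g ~ N(0, K sigma_g^2),   e ~ N(0, I sigma_e^2)

with ``K`` a relationship matrix (NRM, GRM or H).  Variance components are
estimated by restricted maximum likelihood using the Average Information
(AI) algorithm operating directly on the phenotypic covariance
``V = K sigma_g^2 + I sigma_e^2`` — the "direct" AI variant, which never
inverts ``K`` and therefore tolerates an indefinite relationship matrix as
long as ``V`` itself stays positive definite along the search path.

A single eigendecomposition ``K = U L U'`` turns every AI iteration into
O(n p^2) work: in the rotated basis ``V`` is diagonal, so determinants,
traces and the projection ``P = V^-1 - V^-1 X (X'V^-1X)^-1 X'V^-1`` come
from elementwise operations.  AI steps that would leave the feasible
region or decrease the restricted likelihood are halved and, if necessary,
replaced by an EM-REML step (slow but safe).

Prediction of unphenotyped individuals uses the conditional-mean (BLUP)
identity g_t = sigma_g^2 K[t, obs] V^-1 (y - X b_hat).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import eigh

__all__ = ["ModelFit", "VarianceComponents", "fit_reml", "predict_blup", "aic", "reml_loglik"]

logger = logging.getLogger(__name__)


@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_e2: float

    @property
    def h2(self) -> float:
        tot = self.sigma_g2 + self.sigma_e2
        return self.sigma_g2 / tot if tot > 0 else float("nan")


@dataclass
class ModelFit:
    """REML solution with everything needed for downstream BLUP."""

    varcomp: VarianceComponents
    logL: float
    n_params: int
    fixed_effects: np.ndarray
    converged: bool
    n_iter: int
    ids: list[str] | None = None
    blup: np.ndarray | None = None
    boundary: bool = False
    # V^-1 (y - X b_hat) on the original (unrotated) scale; the only state
    # BLUP prediction needs besides sigma_g2.
    vinv_resid: np.ndarray | None = field(default=None, repr=False)

    @property
    def sigma_g2(self) -> float:
        return self.varcomp.sigma_g2

    @property
    def sigma_e2(self) -> float:
        return self.varcomp.sigma_e2

    @property
    def h2(self) -> float:
        return self.varcomp.h2

    @property
    def aic(self) -> float:
        return aic(self.logL, self.n_params)


def aic(logL: float, n_params: int) -> float:
    """Akaike information criterion, 2P - 2 lnL."""
    if n_params < 1:
        raise ValueError("n_params must be >= 1")
    return 2.0 * n_params - 2.0 * logL


def reml_loglik(y: np.ndarray, X: np.ndarray, V: np.ndarray) -> float:
    """Restricted log-likelihood evaluated by dense factorisation.

    Independent of the eigen-rotated iteration path; used as a reference
    route and for small problems.
    """
    n, p = X.shape
    sign, logdetV = np.linalg.slogdet(V)
    if sign <= 0:
        return -np.inf
    Vi_y = np.linalg.solve(V, y)
    Vi_X = np.linalg.solve(V, X)
    B = X.T @ Vi_X
    signB, logdetB = np.linalg.slogdet(B)
    if signB <= 0:
        return -np.inf
    beta = np.linalg.solve(B, X.T @ Vi_y)
    r = y - X @ beta
    yPy = float(r @ np.linalg.solve(V, r))
    return -0.5 * (logdetV + logdetB + yPy + (n - p) * np.log(2.0 * np.pi))


class _RotatedREML:
    """All per-iteration REML quantities in the eigenbasis of K."""

    def __init__(self, y, X, lam, Uty, UtX):
        self.y = y
        self.lam = lam
        self.yt = Uty
        self.Xt = UtX
        self.n, self.p = UtX.shape

    def quantities(self, sg2: float, se2: float):
        d = sg2 * self.lam + se2
        if np.any(d <= 0):
            return None
        dinv = 1.0 / d
        Xd = self.Xt * dinv[:, None]
        B = self.Xt.T @ Xd
        try:
            Bc = np.linalg.cholesky(B)
        except np.linalg.LinAlgError:
            return None
        beta = _chol_solve(Bc, Xd.T @ self.yt)
        r = self.yt - self.Xt @ beta
        Py = r * dinv
        yPy = float(r @ Py)
        logdetB = 2.0 * float(np.sum(np.log(np.diag(Bc))))
        logL = -0.5 * (
            float(np.sum(np.log(d))) + logdetB + yPy
            + (self.n - self.p) * np.log(2.0 * np.pi)
        )
        return {"d": d, "dinv": dinv, "Bc": Bc, "beta": beta, "Py": Py,
                "yPy": yPy, "logL": logL}

    def apply_P(self, v, q):
        dinv, Bc = q["dinv"], q["Bc"]
        vd = v * dinv
        return vd - (self.Xt * dinv[:, None]) @ _chol_solve(Bc, self.Xt.T @ vd)

    def trace_P(self, q, weights):
        """tr(P diag-rotated(V_i)) where rotated V_i = diag(weights)."""
        dinv, Bc = q["dinv"], q["Bc"]
        t1 = float(np.sum(weights * dinv))
        M = self.Xt.T @ (self.Xt * (weights * dinv**2)[:, None])
        t2 = float(np.trace(_chol_solve(Bc, M)))
        return t1 - t2


def _chol_solve(L: np.ndarray, b: np.ndarray) -> np.ndarray:
    from scipy.linalg import solve_triangular

    z = solve_triangular(L, b, lower=True)
    return solve_triangular(L.T, z, lower=False)


def fit_reml(
    y: np.ndarray,
    X: np.ndarray | None,
    K: np.ndarray,
    ids: Sequence[str] | None = None,
    tol: float = 1e-6,
    max_iter: int = 100,
    eig: tuple[np.ndarray, np.ndarray] | None = None,
    compute_blup: bool = True,
    precision: str = "double",
) -> ModelFit:
    """AI-REML fit of (sigma_g^2, sigma_e^2) for ``y ~ N(Xb, K sg2 + I se2)``.

    Parameters
    ----------
    y : phenotypes for the individuals indexing ``K`` (no missing values;
        drop those rows and the matching K rows/columns beforehand).
    X : fixed-effect design; ``None`` means intercept only.
    K : relationship matrix over the phenotyped individuals (may be
        indefinite).
    ids : optional identifiers matching K's order, carried into the fit.
    eig : optional precomputed ``(eigenvalues, eigenvectors)`` of K, for
        reuse across fits on the same individuals.
    precision : "double" (default) or "single"; with "single" the spectral
        factorisation of K runs in float32 (about twice as fast, kernel
        reconstruction error ~1e-6) while all likelihood arithmetic stays
        in float64.  Intended for large cross-validation sweeps.
    """
    y = np.asarray(y, float).ravel()
    n = y.size
    if X is None:
        X = np.ones((n, 1))
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != n or K.shape != (n, n):
        raise ValueError("y, X and K dimensions disagree")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect design X is rank deficient")
    if np.any(~np.isfinite(y)):
        raise ValueError("y contains missing/non-finite values; drop them first")

    if eig is None:
        if precision == "single":
            lam, U = eigh(np.asarray(K, np.float32), driver="evd",
                          check_finite=False)
            lam, U = lam.astype(float), U.astype(float)
        else:
            lam, U = eigh(np.asarray(K, float), driver="evd",
                          check_finite=False)
    else:
        lam, U = eig
    rot = _RotatedREML(y, X, lam, U.T @ y, U.T @ X)

    vy = float(np.var(y))
    if vy <= 0:
        raise ValueError("phenotype has zero variance")
    floor = 1e-8 * vy
    sg2 = se2 = vy / 2.0

    q = rot.quantities(sg2, se2)
    if q is None:
        # shrink toward pure residual until feasible (indefinite K)
        for _ in range(60):
            sg2 *= 0.5
            q = rot.quantities(sg2, se2)
            if q is not None:
                break
        if q is None:
            raise np.linalg.LinAlgError("could not find a feasible starting point")

    converged = False
    boundary = False
    it = 0
    for it in range(1, max_iter + 1):
        Py = q["Py"]
        lamPy = rot.lam * Py
        # scores: dl/dsg2, dl/dse2
        s_g = -0.5 * (rot.trace_P(q, rot.lam) - float(Py @ lamPy))
        s_e = -0.5 * (rot.trace_P(q, np.ones(n)) - float(Py @ Py))
        PlamPy = rot.apply_P(lamPy, q)
        PPy = rot.apply_P(Py, q)
        AI = 0.5 * np.array(
            [
                [float(lamPy @ PlamPy), float(lamPy @ PPy)],
                [float(Py @ PlamPy), float(Py @ PPy)],
            ]
        )
        score = np.array([s_g, s_e])
        try:
            delta = np.linalg.solve(AI, score)
        except np.linalg.LinAlgError:
            delta = score / max(np.abs(AI).max(), 1.0)

        accepted = None
        for _ in range(12):  # halve until feasible and non-decreasing
            cand = np.maximum([sg2 + delta[0], se2 + delta[1]], floor)
            qc = rot.quantities(cand[0], cand[1])
            if qc is not None and qc["logL"] >= q["logL"] - tol:
                accepted = (cand, qc)
                break
            delta = delta / 2.0
        if accepted is None:
            # EM-REML fallback: guaranteed-feasible, slow but monotone
            em_g = sg2 + sg2**2 * (float(Py @ lamPy) - rot.trace_P(q, rot.lam)) / n
            em_e = se2 + se2**2 * (float(Py @ Py) - rot.trace_P(q, np.ones(n))) / n
            cand = np.maximum([em_g, em_e], floor)
            qc = rot.quantities(cand[0], cand[1])
            if qc is None:
                logger.warning("EM fallback infeasible; stopping at iteration %d", it)
                break
            accepted = (cand, qc)

        (sg2, se2), q_new = accepted
        dlog = q_new["logL"] - q["logL"]
        q = q_new
        if abs(dlog) < tol:
            converged = True
            break
    if sg2 <= floor * 1.001 or se2 <= floor * 1.001:
        boundary = True

    if not converged:
        logger.warning("AI-REML did not converge in %d iterations", max_iter)

    vinv_resid = U @ q["Py"]
    blup = sg2 * (K @ vinv_resid) if compute_blup else None
    fit = ModelFit(
        varcomp=VarianceComponents(float(sg2), float(se2)),
        logL=float(q["logL"]),
        n_params=2,
        fixed_effects=np.asarray(q["beta"], float).ravel(),
        converged=converged,
        n_iter=it,
        ids=list(ids) if ids is not None else None,
        blup=blup,
        boundary=boundary,
        vinv_resid=vinv_resid,
    )
    return fit


def predict_blup(
    fit: ModelFit,
    K_full: np.ndarray,
    full_ids: Sequence[str],
    observed_ids: Sequence[str],
    target_ids: Sequence[str],
) -> np.ndarray:
    """BLUP genetic values for ``target_ids`` given a fitted model.

    ``K_full`` is the relationship matrix over ``full_ids`` (e.g. the whole
    H matrix); ``observed_ids`` must match the individuals (and order) the
    model was fitted on.  Targets must be disjoint from the observed set.
    """
    if fit.vinv_resid is None:
        raise ValueError("fit carries no residual information")
    obs = list(observed_ids)
    tgt = list(target_ids)
    if set(obs) & set(tgt):
        raise ValueError("observed and target sets overlap")
    if fit.ids is not None and fit.ids != obs:
        raise ValueError("observed_ids must match the ids the model was fitted on")
    pos = {ident: i for i, ident in enumerate(full_ids)}
    missing = [i for i in obs + tgt if i not in pos]
    if missing:
        raise KeyError(f"ids absent from K_full: {missing[:10]}")
    oi = np.array([pos[i] for i in obs])
    ti = np.array([pos[i] for i in tgt])
    K_to = K_full[np.ix_(ti, oi)]
    return fit.sigma_g2 * (K_to @ fit.vinv_resid)
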