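"""Blending, tuning and assembly of the single-step H relationship matrix.

Single-step evaluation replaces the genotyped block of the pedigree NRM
with a (possibly adjusted) GRM and propagates the change to relatives
through the pedigree:

    H11 = A11 + A12 A22^-1 (G* - A22) A22^-1 A21
    H12 = A12 A22^-1 G*          H21 = H12'
    H22 = G*

Two standard adjustments of G precede assembly:

* blending — ``G_blended = theta * G + (1 - theta) * A22`` shrinks genomic
  toward pedigree relationships (and can repair mild indefiniteness);
* tuning — ``G_tuned = beta * G_blended + omega * J`` matches the GRM's
  mean relationships to the pedigree block, compensating for the unknown
  base-population allele frequencies.  Method 1 (Christensen-style) matches
  both the off-diagonal and diagonal means; method 2 (Vitezica-style) fixes
  ``beta = 1`` and matches only the overall mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = ["blend", "tune", "assemble_h", "adjust_grm", "HMatrix"]

logger = logging.getLogger(__name__)


@dataclass
class HMatrix:
    """Assembled H over all pedigree ids (non-genotyped block first)."""

    values: np.ndarray
    ids: list[str]
    n_nongenotyped: int
    alpha: float | None = None
    theta: float = 1.0
    tune_method: int = 0

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def genotyped_ids(self) -> list[str]:
        return self.ids[self.n_nongenotyped:]


def blend(G: np.ndarray, A22: np.ndarray, theta: float) -> np.ndarray:
    """Convex combination ``theta*G + (1-theta)*A22``."""
    if not 0.0 <= theta <= 1.0:
        raise ValueError(f"blending weight theta={theta} outside [0, 1]")
    G = np.asarray(G, float)
    A22 = np.asarray(A22, float)
    if G.shape != A22.shape:
        raise ValueError("G and A22 are not conformable")
    return theta * G + (1.0 - theta) * A22


def tune(
    Gb: np.ndarray, A22: np.ndarray, method: Literal[1, 2]
) -> tuple[np.ndarray, float, float]:
    """Affine adjustment ``beta*Gb + omega*J`` toward the pedigree block.

    Returns ``(G_tuned, omega, beta)``.  Method 1 solves the two moment
    conditions mean(G_tuned) = mean(A22) and mean(diag G_tuned) =
    mean(diag A22); method 2 keeps ``beta = 1`` and matches the overall
    mean only.
    """
    Gb = np.asarray(Gb, float)
    A22 = np.asarray(A22, float)
    if Gb.shape != A22.shape:
        raise ValueError("Gb and A22 are not conformable")
    mG, mA = float(Gb.mean()), float(A22.mean())
    if method == 2:
        beta = 1.0
        omega = mA - mG
    elif method == 1:
        dG, dA = float(np.diag(Gb).mean()), float(np.diag(A22).mean())
        denom = dG - mG
        if abs(denom) < 1e-12:
            raise ValueError(
                "tune method 1 degenerate: mean(diag Gb) == mean(Gb); "
                "use tune method 2"
            )
        beta = (dA - mA) / denom
        omega = mA - beta * mG
    else:
        raise ValueError(f"unknown tuning method {method!r}")
    return beta * Gb + omega, omega, beta


def adjust_grm(
    G: np.ndarray,
    A22: np.ndarray,
    theta: float = 1.0,
    tune_method: int = 0,
    order: Literal["blend_then_tune", "tune_then_blend"] = "blend_then_tune",
) -> np.ndarray:
    """Apply blending and (optionally) tuning in the requested order."""
    if tune_method not in (0, 1, 2):
        raise ValueError(f"tune_method must be 0, 1 or 2, got {tune_method!r}")
    if order == "blend_then_tune":
        out = blend(G, A22, theta)
        if tune_method:
            out, _, _ = tune(out, A22, tune_method)
    elif order == "tune_then_blend":
        out = G
        if tune_method:
            out, _, _ = tune(out, A22, tune_method)
        out = blend(out, A22, theta)
    else:
        raise ValueError(f"unknown order {order!r}")
    return out


def assemble_h(
    A11: np.ndarray,
    A12: np.ndarray,
    A21: np.ndarray,
    A22: np.ndarray,
    G_adj: np.ndarray,
    ids_nongenotyped: list[str] | None = None,
    ids_genotyped: list[str] | None = None,
    alpha: float | None = None,
    theta: float = 1.0,
    tune_method: int = 0,
) -> HMatrix:
    """Assemble H from the NRM blocks and the adjusted GRM.

    The genotyped block of the result is ``G_adj`` verbatim; when
    ``G_adj == A22`` the whole matrix collapses back to ``A``.  An
    indefinite result is allowed (the average-information REML solver
    tolerates it) but triggers a warning.
    """
    G_adj = np.asarray(G_adj, float)
    A22 = np.asarray(A22, float)
    if G_adj.shape != A22.shape:
        raise ValueError("G_adj and A22 are not conformable")
    n1 = A11.shape[0]
    n2 = A22.shape[0]
    if A12.shape != (n1, n2) or A21.shape != (n2, n1):
        raise ValueError("NRM blocks have inconsistent shapes")
    ids_ng = list(ids_nongenotyped) if ids_nongenotyped is not None else [
        f"ng{i}" for i in range(n1)
    ]
    ids_g = list(ids_genotyped) if ids_genotyped is not None else [
        f"g{i}" for i in range(n2)
    ]

    H = np.empty((n1 + n2, n1 + n2))
    if n1 == 0:
        H[:] = G_adj
    else:
        try:
            c, low = _cho(A22)
            A22inv_A21 = _cho_solve((c, low), A21)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"A22 factorisation failed ({exc}); invalid pedigree block"
            ) from exc
        # P = A22^-1 A21 (n2 x n1)
        GP = G_adj @ A22inv_A21            # n2 x n1
        H12 = GP.T                          # A12 A22^-1 G
        H11 = A11 + A22inv_A21.T @ (GP - A21)
        H[:n1, :n1] = (H11 + H11.T) / 2.0
        H[:n1, n1:] = H12
        H[n1:, :n1] = H12.T
        H[n1:, n1:] = G_adj

    eigmin = float(np.linalg.eigvalsh(H).min()) if H.shape[0] <= 500 else None
    if eigmin is not None and eigmin < -1e-8:
        logger.warning("assembled H is indefinite (min eigenvalue %.3g)", eigmin)
    return HMatrix(H, ids_ng + ids_g, n1, alpha=alpha, theta=theta,
                   tune_method=tune_method)


def _cho(a: np.ndarray):
    from scipy.linalg import cho_factor

    return cho_factor(a, lower=True)


def _cho_solve(c_and_low, b: np.ndarray) -> np.ndarray:
    from scipy.linalg import cho_solve

    return cho_solve(c_and_low, b)
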