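"""Genomic relationship matrix (GRM) with an allele-frequency scale factor.

The GRM entry between individuals ``i`` and ``j`` is

    G_ij = (1/d) * sum_k (x_ik - 2 p_k)(x_jk - 2 p_k) [2 p_k (1 - p_k)]^{2a}

where ``x`` is the additive genotype count in {0, 1, 2}, ``p_k`` the allele
frequency of SNP ``k``, and ``a`` (``alpha``) the scale factor relating
allele frequency to per-allele effect size: effects are taken proportional
to ``[2 p (1 - p)]^alpha``.  ``alpha = -0.5`` weights every SNP to an equal
expected variance contribution (the PLINK/GCTA convention); ``alpha = 0``
leaves effects frequency-independent (VanRaden method 1).

Two normalisations ``d`` are supported:

* ``"empirical"`` (default): ``d`` is the mean over individuals of the
  weighted squared centred genotypes, so ``trace(G)/n = 1`` exactly;
* ``"theoretical"``: ``d = sum_k [2 p_k (1 - p_k)]^{1 + 2 alpha}``, the
  Hardy–Weinberg expectation used by PLINK/GCTA (at ``alpha = -0.5`` this
  is just the SNP count).
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "GenomicRelationshipMatrix",
    "allele_frequencies",
    "compute_grm",
    "write_gcta_grm",
    "read_gcta_grm",
]

logger = logging.getLogger(__name__)


@dataclass
class GenotypeMatrix:
    """Additive genotype counts (individuals x SNPs) with a missing mask."""

    counts: np.ndarray  # float array; np.nan marks missing
    ids: list[str]
    snp_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.ids), len(self.snp_ids)):
            raise ValueError("genotype matrix shape does not match id lists")
        valid = np.isnan(self.counts) | np.isin(self.counts, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("genotype counts must be 0, 1, 2 or missing")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def subset(self, ids: Sequence[str]) -> "GenotypeMatrix":
        pos = {ident: i for i, ident in enumerate(self.ids)}
        idx = [pos[i] for i in ids]
        return GenotypeMatrix(self.counts[idx], list(ids), list(self.snp_ids))


@dataclass
class GenomicRelationshipMatrix:
    """Symmetric GRM over genotyped individuals, tagged with its provenance."""

    values: np.ndarray
    ids: list[str]
    alpha: float
    d: float
    freq_source: Literal["in-sample", "supplied"] = "in-sample"
    n_snps_used: int = 0
    freqs: np.ndarray | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return len(self.ids)


def allele_frequencies(gm: GenotypeMatrix) -> np.ndarray:
    """Per-SNP frequency of the counted allele over non-missing genotypes."""
    non_missing = np.sum(~np.isnan(gm.counts), axis=0)
    if np.any(non_missing == 0):
        bad = [gm.snp_ids[k] for k in np.flatnonzero(non_missing == 0)]
        raise ValueError(f"SNPs with all genotypes missing: {bad[:10]}")
    p = np.nansum(gm.counts, axis=0) / (2.0 * non_missing)
    return p


def monomorphic_mask(p: np.ndarray, tol: float = 0.0) -> np.ndarray:
    """True for SNPs fixed (or within ``tol`` of fixation) in the sample."""
    return (p <= tol) | (p >= 1.0 - tol)


def compute_grm(
    gm: GenotypeMatrix,
    alpha: float = -0.5,
    normalization: Literal["empirical", "theoretical"] = "empirical",
    freqs: np.ndarray | None = None,
) -> GenomicRelationshipMatrix:
    """Compute the alpha-scaled GRM.

    Monomorphic SNPs are dropped (their weight is degenerate for negative
    ``alpha``) with a logged count; missing genotypes are mean-imputed to
    ``2 p_k`` before centring, which leaves them without contribution.

    Parameters
    ----------
    gm : genotype counts for the genotyped individuals.
    alpha : scale factor; effects are proportional to ``[2p(1-p)]^alpha``.
    normalization : "empirical" (trace/n = 1) or "theoretical" (HWE sum).
    freqs : optional externally supplied allele frequencies (e.g. base
        population); defaults to in-sample estimates.
    """
    if gm.n < 2:
        raise ValueError("GRM needs at least two genotyped individuals")
    if freqs is None:
        p = allele_frequencies(gm)
        freq_source: Literal["in-sample", "supplied"] = "in-sample"
    else:
        p = np.asarray(freqs, dtype=float)
        if p.shape != (gm.n_snps,):
            raise ValueError("supplied frequency vector length mismatch")
        freq_source = "supplied"

    keep = ~monomorphic_mask(p)
    n_dropped = int(np.sum(~keep))
    if n_dropped:
        logger.info("dropping %d monomorphic SNPs before GRM", n_dropped)
    if not np.any(keep):
        raise ValueError("no polymorphic SNPs left; GRM undefined (d = 0)")

    X = gm.counts[:, keep]
    pk = p[keep]
    X = np.where(np.isnan(X), 2.0 * pk, X)
    Z = X - 2.0 * pk
    w = (2.0 * pk * (1.0 - pk)) ** (2.0 * alpha)

    Zw = Z * w
    G = Z @ Zw.T
    if normalization == "empirical":
        d = float(np.mean(np.sum(Z * Zw, axis=1)))
    elif normalization == "theoretical":
        d = float(np.sum((2.0 * pk * (1.0 - pk)) ** (1.0 + 2.0 * alpha)))
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    if d <= 0.0 or not np.isfinite(d):
        raise ValueError(f"degenerate GRM normalisation d = {d}")
    G /= d
    G = (G + G.T) / 2.0  # exact symmetry against roundoff
    return GenomicRelationshipMatrix(
        G, list(gm.ids), alpha=float(alpha), d=d,
        freq_source=freq_source, n_snps_used=int(np.sum(keep)),
        freqs=pk,
    )


# ---------------------------------------------------------------------------
# GCTA GRM dialect: lower triangle of float32 in .grm.bin, ids in .grm.id,
# per-pair SNP counts in .grm.N.bin.

def write_gcta_grm(grm: GenomicRelationshipMatrix, prefix: str | Path) -> None:
    prefix = str(prefix)
    n = grm.n
    tri = grm.values[np.tril_indices(n)]
    tri.astype("<f4").tofile(prefix + ".grm.bin")
    counts = np.full(tri.shape, grm.n_snps_used, dtype="<f4")
    counts.tofile(prefix + ".grm.N.bin")
    with open(prefix + ".grm.id", "w") as fh:
        for ident in grm.ids:
            fh.write(f"{ident}\t{ident}\n")


def read_gcta_grm(prefix: str | Path) -> tuple[np.ndarray, list[str]]:
    prefix = str(prefix)
    ids = [line.split()[1] for line in open(prefix + ".grm.id")]
    n = len(ids)
    tri = np.fromfile(prefix + ".grm.bin", dtype="<f4")
    if tri.size != n * (n + 1) // 2:
        raise ValueError("GRM binary size inconsistent with id count")
    G = np.zeros((n, n))
    il = np.tril_indices(n)
    G[il] = tri
    G = G + np.tril(G, -1).T
    return G, ids


def grm_to_tsv(grm: GenomicRelationshipMatrix, path: str | Path) -> None:
    pd.DataFrame(grm.values, index=grm.ids, columns=grm.ids).to_csv(path, sep="\t")
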