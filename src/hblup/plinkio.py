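"""Reading and writing PLINK genotype formats.

Two dialects are supported, enough to round-trip the additive genotype
matrices this package works with:

* ``.raw`` — the text export of ``plink --recode A``: a header line
  ``FID IID PAT MAT SEX PHENOTYPE`` followed by one column per SNP
  (named ``<snp>_<counted allele>``), additive counts 0/1/2 with ``NA``
  for missing;
* ``.bed/.bim/.fam`` — the binary format, SNP-major, magic bytes
  ``0x6c 0x1b 0x01``, two bits per genotype (00 = two copies of A1,
  10 = heterozygote, 11 = zero copies, 01 = missing).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .grm import GenotypeMatrix

__all__ = ["read_raw", "write_raw", "read_bed", "write_bed"]

_MAGIC = bytes([0x6C, 0x1B, 0x01])

# additive count -> 2-bit code (A1 counted): 2->00, missing->01, 1->10, 0->11
_COUNT_TO_CODE = {2: 0b00, 1: 0b10, 0: 0b11}
_CODE_TO_COUNT = np.array([2.0, np.nan, 1.0, 0.0])


def write_raw(gm: GenotypeMatrix, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        snp_cols = " ".join(f"{s}_A" for s in gm.snp_ids)
        fh.write(f"FID IID PAT MAT SEX PHENOTYPE {snp_cols}\n")
        for i, ident in enumerate(gm.ids):
            row = gm.counts[i]
            vals = " ".join("NA" if np.isnan(v) else str(int(v)) for v in row)
            fh.write(f"{ident} {ident} 0 0 0 -9 {vals}\n")


def read_raw(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep=r"\s+", na_values=["NA"])
    meta_cols = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    missing_meta = [c for c in meta_cols if c not in df.columns]
    if missing_meta:
        raise ValueError(f"{path}: not a PLINK .raw file (missing {missing_meta})")
    snp_cols = [c for c in df.columns if c not in meta_cols]
    # strip the counted-allele suffix plink appends ("snp_A" -> "snp")
    snp_ids = [c.rsplit("_", 1)[0] if "_" in c else c for c in snp_cols]
    counts = df[snp_cols].to_numpy(dtype=float)
    ids = df["IID"].astype(str).tolist()
    return GenotypeMatrix(counts, ids, snp_ids)


def write_bed(
    gm: GenotypeMatrix,
    prefix: str | Path,
    chromosomes: np.ndarray | None = None,
    cm_positions: np.ndarray | None = None,
    bp_positions: np.ndarray | None = None,
) -> None:
    """Write .bed plus companion .bim/.fam for the genotype matrix."""
    prefix = str(prefix)
    n, m = gm.n, gm.n_snps
    chromosomes = np.ones(m, int) if chromosomes is None else np.asarray(chromosomes)
    cm_positions = np.zeros(m) if cm_positions is None else np.asarray(cm_positions)
    if bp_positions is None:
        # integer bp surrogate from the cM map (1 cM -> 1e6 bp)
        bp_positions = np.asarray(cm_positions * 1e6 + 1, dtype=np.int64)

    with open(prefix + ".fam", "w") as fh:
        for ident in gm.ids:
            fh.write(f"{ident} {ident} 0 0 0 -9\n")
    with open(prefix + ".bim", "w") as fh:
        for k, snp in enumerate(gm.snp_ids):
            fh.write(
                f"{chromosomes[k]}\t{snp}\t{cm_positions[k]:.6f}"
                f"\t{bp_positions[k]}\tA\tC\n"
            )

    codes = np.full(gm.counts.shape, 0b01, dtype=np.uint8)  # missing
    for count, code in _COUNT_TO_CODE.items():
        codes[gm.counts == count] = code
    n_bytes = (n + 3) // 4
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_MAGIC)
        padded = np.zeros((m, n_bytes * 4), dtype=np.uint8)
        padded[:, :n] = codes.T
        packed = (
            padded[:, 0::4]
            | (padded[:, 1::4] << 2)
            | (padded[:, 2::4] << 4)
            | (padded[:, 3::4] << 6)
        )
        fh.write(packed.tobytes())


def read_bed(prefix: str | Path) -> GenotypeMatrix:
    prefix = str(prefix)
    fam = pd.read_csv(prefix + ".fam", sep=r"\s+", header=None, dtype=str)
    bim = pd.read_csv(prefix + ".bim", sep=r"\s+", header=None, dtype=str)
    ids = fam[1].tolist()
    snp_ids = bim[1].tolist()
    n, m = len(ids), len(snp_ids)
    with open(prefix + ".bed", "rb") as fh:
        magic = fh.read(3)
        if magic != _MAGIC:
            raise ValueError(f"{prefix}.bed: bad magic bytes (not SNP-major PLINK)")
        data = np.frombuffer(fh.read(), dtype=np.uint8)
    n_bytes = (n + 3) // 4
    if data.size != m * n_bytes:
        raise ValueError(f"{prefix}.bed: size inconsistent with .fam/.bim")
    data = data.reshape(m, n_bytes)
    codes = np.empty((m, n_bytes * 4), dtype=np.uint8)
    codes[:, 0::4] = data & 0b11
    codes[:, 1::4] = (data >> 2) & 0b11
    codes[:, 2::4] = (data >> 4) & 0b11
    codes[:, 3::4] = (data >> 6) & 0b11
    counts = _CODE_TO_COUNT[codes[:, :n]].T
    return GenotypeMatrix(counts, ids, snp_ids)
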