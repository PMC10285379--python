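"""Pedigrees and the numerator relationship matrix (NRM).

The NRM ``A`` holds expected additive genetic relationships implied by a
pedigree: ``a_ij`` is twice the kinship coefficient between individuals ``i``
and ``j``, and the diagonal is ``1 + F_i`` with ``F_i`` the inbreeding
coefficient.  It is built with the tabular (Henderson) recursion, which
handles inbreeding exactly:

* founders: ``a_ii = 1``, unrelated to everything processed before them;
* ``a_ij = (a_{j,sire(i)} + a_{j,dam(i)}) / 2`` for ``j`` processed before
  ``i`` (an unknown parent contributes 0);
* ``a_ii = 1 + a_{sire(i),dam(i)} / 2``.

Single-step evaluation partitions ``A`` around the genotyped subset into
blocks ``A11`` (non-genotyped), ``A22`` (genotyped) and the cross blocks
``A12 = A21'``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PedigreeRecord",
    "Pedigree",
    "NumeratorRelationshipMatrix",
    "read_pedigree",
    "build_nrm",
    "partition_nrm",
]

UNKNOWN = "0"


@dataclass(frozen=True)
class PedigreeRecord:
    """One individual with its sire and dam (:data:`UNKNOWN` if missing)."""

    id: str
    sire: str = UNKNOWN
    dam: str = UNKNOWN
    generation: int | None = None

    def __post_init__(self) -> None:
        if self.id == UNKNOWN:
            raise ValueError("individual id may not equal the unknown-parent code")
        if self.sire == self.id or self.dam == self.id:
            raise ValueError(f"individual {self.id!r} listed as its own parent")


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, duplicate ids)."""


@dataclass
class Pedigree:
    """Topologically ordered pedigree (every parent precedes its offspring)."""

    records: list[PedigreeRecord]
    index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.index = {}
        for i, rec in enumerate(self.records):
            if rec.id in self.index:
                raise PedigreeError(f"duplicate individual id {rec.id!r}")
            self.index[rec.id] = i
        for rec in self.records:
            for parent in (rec.sire, rec.dam):
                if parent == UNKNOWN:
                    continue
                if parent not in self.index:
                    raise PedigreeError(
                        f"parent {parent!r} of {rec.id!r} is not in the pedigree"
                    )
                if self.index[parent] >= self.index[rec.id]:
                    raise PedigreeError(
                        f"pedigree is not topologically sorted: parent {parent!r} "
                        f"does not precede offspring {rec.id!r}"
                    )

    @property
    def ids(self) -> list[str]:
        return [rec.id for rec in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass
class NumeratorRelationshipMatrix:
    """Symmetric NRM over an ordered id list, with optional genotype blocks."""

    values: np.ndarray
    ids: list[str]
    genotyped_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids), len(self.ids)):
            raise ValueError("NRM shape does not match id list")

    @property
    def n(self) -> int:
        return len(self.ids)

    def inbreeding(self) -> np.ndarray:
        """Per-individual inbreeding coefficients ``F = diag(A) - 1``."""
        return np.diag(self.values) - 1.0


def _toposort(records: list[PedigreeRecord]) -> list[PedigreeRecord]:
    by_id = {r.id: r for r in records}
    order: list[PedigreeRecord] = []
    state: dict[str, int] = {}  # 0 in-progress, 1 done

    for root in records:
        stack = [root.id]
        while stack:
            ident = stack[-1]
            if state.get(ident) == 1:
                stack.pop()
                continue
            rec = by_id[ident]
            pending = [
                p
                for p in (rec.sire, rec.dam)
                if p != UNKNOWN and state.get(p) != 1
            ]
            unresolved = []
            for p in pending:
                if state.get(p) == 0 or p in stack:
                    cycle = " -> ".join(stack[stack.index(p):] + [p]) if p in stack else f"{ident} -> {p}"
                    raise PedigreeError(f"pedigree cycle detected: {cycle}")
                unresolved.append(p)
            if unresolved:
                state[ident] = 0
                stack.extend(unresolved)
            else:
                state[ident] = 1
                order.append(rec)
                stack.pop()
    return order


def read_pedigree(path: str | Path, unknown_code: str = "0") -> Pedigree:
    """Read a delimited pedigree file (columns id, sire, dam[, generation]).

    The file may list offspring before parents; records are topologically
    sorted.  Parents that are referenced but never listed are inserted as
    founders.  ``unknown_code`` marks a missing parent and is normalised to
    :data:`UNKNOWN` internally.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, header=None,
                     comment="#", skip_blank_lines=True)
    first = [str(v).strip().lower() for v in df.iloc[0]]
    if first[:3] == ["id", "sire", "dam"]:
        df = df.iloc[1:].reset_index(drop=True)
    if df.shape[1] < 3:
        raise PedigreeError(f"{path}: pedigree needs at least 3 columns (id, sire, dam)")

    def norm(tok: object) -> str:
        tok = "" if tok is None or (isinstance(tok, float) and np.isnan(tok)) else str(tok).strip()
        return UNKNOWN if tok in ("", unknown_code, "NA") else tok

    records: list[PedigreeRecord] = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        ident, sire, dam = norm(row[0]), norm(row[1]), norm(row[2])
        gen = None
        if len(row) > 3 and norm(row[3]) != UNKNOWN:
            try:
                gen = int(float(row[3]))
            except (TypeError, ValueError):
                gen = None
        if ident == UNKNOWN:
            raise PedigreeError(f"{path}: blank/unknown individual id in a record")
        if ident in seen:
            raise PedigreeError(f"{path}: duplicate individual id {ident!r}")
        if ident in (sire, dam):
            raise PedigreeError(f"{path}: individual {ident!r} is its own parent")
        seen.add(ident)
        records.append(PedigreeRecord(ident, sire, dam, gen))

    # auto-insert unlisted parents as founders
    referenced = {p for r in records for p in (r.sire, r.dam) if p != UNKNOWN}
    founders = [PedigreeRecord(p) for p in sorted(referenced - seen)]
    return Pedigree(_toposort(founders + records))


def build_nrm(ped: Pedigree) -> NumeratorRelationshipMatrix:
    """Build the full NRM by the tabular method (exact inbreeding)."""
    n = len(ped)
    A = np.zeros((n, n))
    idx = ped.index
    for i, rec in enumerate(ped.records):
        s = idx.get(rec.sire, -1) if rec.sire != UNKNOWN else -1
        d = idx.get(rec.dam, -1) if rec.dam != UNKNOWN else -1
        if i:
            row = np.zeros(i)
            if s >= 0:
                row += A[s, :i]
            if d >= 0:
                row += A[d, :i]
            row *= 0.5
            A[i, :i] = row
            A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
    return NumeratorRelationshipMatrix(A, ped.ids)


def partition_nrm(
    nrm: NumeratorRelationshipMatrix, genotyped_ids: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Split ``A`` into (A11, A12, A21, A22) around the genotyped subset.

    ``A22`` rows/columns follow the order of ``genotyped_ids`` so they line
    up with the GRM built for the same individuals; ``A11`` keeps the
    pedigree order of the remaining individuals.
    """
    pos = {ident: i for i, ident in enumerate(nrm.ids)}
    missing = [g for g in genotyped_ids if g not in pos]
    if missing:
        raise KeyError(f"genotyped ids not in the pedigree: {missing}")
    g_idx = np.array([pos[g] for g in genotyped_ids], dtype=int)
    g_set = set(g_idx.tolist())
    ng_idx = np.array([i for i in range(nrm.n) if i not in g_set], dtype=int)
    A = nrm.values
    A11 = A[np.ix_(ng_idx, ng_idx)]
    A12 = A[np.ix_(ng_idx, g_idx)]
    A22 = A[np.ix_(g_idx, g_idx)]
    return A11, A12, A12.T.copy(), A22


def nrm_to_tsv(nrm: NumeratorRelationshipMatrix, path: str | Path) -> None:
    """Write the NRM as a TSV with ids as header and index."""
    pd.DataFrame(nrm.values, index=nrm.ids, columns=nrm.ids).to_csv(path, sep="\t")
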