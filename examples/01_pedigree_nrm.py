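"""Build a numerator relationship matrix from a small pedigree.

Constructs a five-individual pedigree with a parent-offspring mating and
prints the full NRM, showing how inbreeding appears on the diagonal.
"""

import numpy as np

from hblup import Pedigree, PedigreeRecord, build_nrm, partition_nrm

ped = Pedigree([
    PedigreeRecord("1"),
    PedigreeRecord("2"),
    PedigreeRecord("3", sire="1", dam="2"),
    PedigreeRecord("4", sire="1", dam="3"),   # sire mated to his daughter
    PedigreeRecord("5", sire="4", dam="2"),
])

A = build_nrm(ped)
np.set_printoptions(precision=3, suppress=True)
print("ids:", A.ids)
print(A.values)
print("inbreeding coefficients:", A.inbreeding())

# Individual 4 comes from a sire-daughter mating: F = 0.25, so its
# diagonal is 1.25.  Partition around a genotyped subset for single-step use:
A11, A12, A21, A22 = partition_nrm(A, ["4", "5"])
print("A22 (genotyped block):")
print(A22)
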