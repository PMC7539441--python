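"""Pedigree relationship machinery on a tiny worked example.

A is the numerator relationship matrix (tabular method), F the inbreeding
coefficients, and A^-1 the sparse inverse from Henderson's rules with
inbreeding; A22 is the submatrix for a chosen set of "genotyped" animals.
"""

import numpy as np

from ssgblup import A_inverse, Pedigree, build_A, inbreeding, subset_A22

# sire S and dam D, two full sibs X and Y, and Z from a full-sib mating
ped = Pedigree.from_records([
    ("S", 0, 0), ("D", 0, 0),
    ("X", "S", "D"), ("Y", "S", "D"),
    ("Z", "X", "Y"),
])

A = build_A(ped)
print("A (animals", list(A.ids), "):")
print(np.round(A.dense(), 3))

F = inbreeding(ped)
print("\ninbreeding coefficients:", dict(zip(ped.ids, np.round(F, 3))))
# Z is the offspring of full sibs: F = 0.25, so its diagonal in A is 1.25

Ainv = A_inverse(ped)
print("\nA^-1 (sparse, nonzeros only among animal/sire/dam triples):")
print(np.round(Ainv.dense(), 3))
print("max |A A^-1 - I| =", np.abs(A.dense() @ Ainv.dense() - np.eye(ped.n)).max())

A22 = subset_A22(A, ["X", "Y", "Z"])
print("\nA22 for the genotyped subset X, Y, Z:")
print(np.round(A22.dense(), 3))
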