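"""SNP quality control and the single-step H matrix on simulated data.

Runs the QC filters (call rates, Hardy-Weinberg, MAF, parent-offspring
conflicts), builds the VanRaden G, tunes and blends it with the pedigree
submatrix A22, and assembles H^-1 for single-step evaluation.
"""

import numpy as np

from ssgblup import (SimConfig, simulate_study, qc_filter, build_G,
                     build_A, A_inverse, subset_A22, tune_and_blend_G,
                     build_H_inverse)

cfg = SimConfig(n_snps=800, n_qtl=100, n_generations=4,
                n_g0_candidates=32, n_candidates_per_gen=32,
                n_dams_per_line=12, n_f0_sires=12, n_f0_dams=12, seed=7)
study, bundle = simulate_study(cfg)

geno, report = qc_filter(bundle.genotypes, bundle.pedigree)
print(report.summary())
# gene dropping creates no genotyping errors, so QC removes only SNPs that
# drifted out of the MAF range during selection

G = build_G(geno)
A = build_A(bundle.pedigree)
A22 = subset_A22(A, geno.ids)
print(f"\nmean diag(G)  = {np.mean(np.diag(G.dense())):.3f}")
print(f"mean diag(A22) = {np.mean(np.diag(A22.dense())):.3f}")

Gb = tune_and_blend_G(G, A22, blend_weight=0.05)
print(f"tuning: alpha={Gb.meta['alpha']:.4f} beta={Gb.meta['beta']:.4f} "
      f"blend weight={Gb.meta['blend_weight']}")
print(f"mean diag(G**) = {np.mean(np.diag(Gb.dense())):.3f} "
      "(matched to A22 up to the blend)")

Hinv = build_H_inverse(A_inverse(bundle.pedigree), Gb, A22)
print(f"\nH^-1: {Hinv.n} x {Hinv.n} with a dense correction on the "
      f"{len(Gb.ids)} genotyped animals")
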