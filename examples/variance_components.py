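"""Bivariate REML for a trait paired with the selection index.

Estimates the 2x2 genetic, litter and residual covariance matrices of
(ADG, index) on a small simulated study with the pedigree relationship
matrix, and compares the heritability and litter-fraction estimates with
the generator's targets.
"""

import numpy as np

from ssgblup import (SimConfig, simulate_study, prepare_phenotypes,
                     default_model, estimate_varcomp, true_variance_components)

cfg = SimConfig(n_snps=400, n_qtl=100, n_generations=4,
                n_g0_candidates=60, n_candidates_per_gen=60,
                n_dams_per_line=20, n_f0_sires=20, n_f0_dams=20,
                response_litters_per_gen=2, seed=11)
study, bundle = simulate_study(cfg)
phen = prepare_phenotypes(bundle)

vc = estimate_varcomp(phen, default_model("ADG"), bundle.pedigree)
truth = true_variance_components(cfg)["ADG"]

print(f"REML converged in {vc.n_iter} iterations, -2logL trajectory "
      f"monotone: {all(a[1] >= b[1] - 1e-6 for a, b in zip(vc.trajectory, vc.trajectory[1:]))}")
print(f"\nADG heritability:   estimate {vc.h2(0):.3f}  generator target "
      f"{truth.h2(0):.3f}")
print(f"ADG litter fraction: estimate {vc.l2(0):.3f}  generator target "
      f"{truth.l2(0):.3f}")
r_est = vc.G0[0, 1] / np.sqrt(vc.G0[0, 0] * vc.G0[1, 1])
r_true = truth.G0[0, 1] / np.sqrt(truth.G0[0, 0] * truth.G0[1, 1])
print(f"genetic correlation trait-index: estimate {r_est:.2f}  target {r_true:.2f}")
# Heritability and litter fraction are recovered tightly.  The trait-index
# genetic correlation is far noisier: the index variance is a small
# difference of large components, so the correlation *realized* in a small
# founder group can deviate substantially from the configured target, and
# REML tracks the realized base, not the target.  The recovery properties
# are validated at scale in the test suite.
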