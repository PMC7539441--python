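"""Canned simulation experiments for calibration and validation studies.

These functions define the standard study conditions used by the package's
validation suite: REML parameter recovery on a five-generation pedigree,
the LR accuracy identity on the default two-line bundle, the regression
slope of whole on partial GEBV for an unselected validation cohort, the
type-I error of the Williams test under a simulated null, and the
diagonal of the VanRaden G under Hardy-Weinberg equilibrium.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .engine import ModelSpec, solve_ssgblup
from .grm import GenotypeMatrix, build_G
from .pedigree import Pedigree, A_inverse, build_A
from .reml import estimate_varcomp
from .simulate import DataBundle, SimConfig, simulate_study, true_variance_components
from .validation import (build_scenario_bundle, line_bundle, lr_accuracy,
                         lr_bias, make_scenario, single_step_inverse,
                         williams_test)

__all__ = [
    "simulate_depth5_trait",
    "reml_recovery_trial",
    "lr_identity_trial",
    "lr_slope_unselected_trial",
    "williams_null_pvalues",
    "hwe_grm_diagonal",
]


def simulate_depth5_trait(
    seed: int,
    h2: float = 0.25,
    l2: float = 0.10,
    n_families: int = 100,
    n_generations: int = 5,
    progeny_per_litter: int = 6,
    phen_var: float = 100.0,
):
    """Random-mating pedigree of depth five with one litter per family pair.

    Returns (pedigree, phenotype frame) with n_families *
    progeny_per_litter records per generation (3 000 at the defaults: many
    moderate full-sib families, each sire used once per generation, which
    keeps the sampling variance of the heritability estimator small); used
    for variance-component recovery studies at the study's trait
    architecture (e.g. a growth-rate trait with h2 = 0.25 and litter
    fraction 0.10).
    """
    rng = np.random.default_rng(seed)
    sa2, sl2 = h2 * phen_var, l2 * phen_var
    se2 = (1.0 - h2 - l2) * phen_var
    recs, rows, tbv = [], [], {}
    males, females = [], []
    for i in range(n_families):
        for tag, pool in (("m", males), ("f", females)):
            a = f"g0_{tag}{i}"
            recs.append((a, None, None))
            tbv[a] = rng.normal(0, np.sqrt(sa2))
            pool.append(a)
    for g in range(1, n_generations + 1):
        nm, nf = [], []
        sire_order = rng.permutation(len(males))
        for i in range(n_families):
            sire = males[sire_order[i % len(males)]]
            dam = females[i % len(females)]
            lit = f"L{g}_{i}"
            leff = rng.normal(0, np.sqrt(sl2))
            for p in range(progeny_per_litter):
                a = f"g{g}_{i}_{p}"
                recs.append((a, sire, dam))
                tbv[a] = 0.5 * (tbv[sire] + tbv[dam]) + rng.normal(0, np.sqrt(sa2 / 2))
                rows.append((a, 50 + tbv[a] + leff
                             + rng.normal(0, np.sqrt(se2)), lit))
                (nm if p % 2 else nf).append(a)
        males, females = nm[:n_families], nf[:n_families]
    ped = Pedigree.from_records(recs)
    phen = pd.DataFrame(rows, columns=["id", "t1", "litter"])
    return ped, phen


def reml_recovery_trial(seed: int, h2: float = 0.25, l2: float = 0.10):
    """One REML fit on freshly simulated depth-5 data; returns (h2, l2)."""
    ped, phen = simulate_depth5_trait(seed, h2=h2, l2=l2)
    model = ModelSpec(traits=("t1",), factors=(), litter="litter")
    vc = estimate_varcomp(phen, model, ped)
    return vc.h2(0), vc.l2(0)


def _raw_phenotypes(bundle: DataBundle) -> pd.DataFrame:
    """Bundle phenotypes on the generating scale (no standardization), with
    the selection-index record attached by the generator."""
    return bundle.phenotypes.copy()


def lr_identity_trial(seed: int, config: SimConfig | None = None,
                      line: str = "HRFI", trait: str = "ADG",
                      also_scenario4: bool = False) -> dict:
    """Scenario-1 LR statistics and TBV-based accuracies on one bundle.

    Runs the whole-data and the control-scenario partial ssGBLUP for one
    line and trait with the generator's variance components, then returns
    r(GEBVp, GEBVw), the regression slope, and the correlations of both
    GEBV sets with the simulated true breeding values of the validation
    animals.  With ``also_scenario4`` the reduced-information scenario 4 is
    run on the same bundle and the GEBVp variances of both partial runs are
    reported (information-monotonicity studies).
    """
    config = config or SimConfig()
    from dataclasses import replace

    config = replace(config, seed=seed)
    study, bundle = simulate_study(config)
    phen = _raw_phenotypes(bundle)
    clean = DataBundle(bundle.pedigree, bundle.meta, bundle.genotypes, phen)
    vc = true_variance_components(config)[trait]
    model = ModelSpec(traits=(trait, "index"), litter="litter")
    A = build_A(bundle.pedigree)
    Ainv = A_inverse(bundle.pedigree)

    wb = line_bundle(clean, line)
    Hw, _ = single_step_inverse(wb, A, Ainv)
    sol_w = solve_ssgblup(wb.phenotypes, model, vc, Hw, bundle.pedigree)

    sc = make_scenario(1, line, config.n_generations)
    part, _, val_ids = build_scenario_bundle(clean, sc)
    Hp, _ = single_step_inverse(part, A, Ainv)
    sol_p = solve_ssgblup(part.phenotypes, model, vc, Hp, bundle.pedigree)

    gw = sol_w.gebv_of(val_ids, trait)
    gp = sol_p.gebv_of(val_ids, trait)
    tb = study.tbv.set_index("id").loc[list(val_ids), trait].to_numpy()
    r, se = lr_accuracy(gp, gw)
    out = dict(
        r=r, se=se, slope=lr_bias(gp, gw), n=len(val_ids),
        acc_p=float(np.corrcoef(gp, tb)[0, 1]),
        acc_w=float(np.corrcoef(gw, tb)[0, 1]),
    )
    if also_scenario4:
        # target-line-only variant of scenario 4: its data are a strict
        # subset of scenario 1's, the setting in which removing phenotypes
        # cannot add information to the partial GEBV
        from dataclasses import replace as dc_replace

        sc4 = dc_replace(make_scenario(4, line, config.n_generations),
                         other_gens=())
        part4, _, val4 = build_scenario_bundle(clean, sc4)
        Hp4, _ = single_step_inverse(part4, A, Ainv)
        sol_p4 = solve_ssgblup(part4.phenotypes, model, vc, Hp4, bundle.pedigree)
        out["var_gp_sc1"] = float(np.var(gp, ddof=1))
        out["var_gp_sc4"] = float(np.var(sol_p4.gebv_of(val4, trait), ddof=1))
    return out


def unselected_config(seed: int) -> SimConfig:
    """Reduced bundle with a selection differential of zero (random sire
    choice): the validation cohort is unselected, the condition under which
    the LR regression slope is expected to center on 1."""
    return SimConfig(
        seed=seed, random_selection=True, n_generations=5,
        n_snps=1200, n_qtl=150, n_g0_candidates=48, n_candidates_per_gen=48,
        n_dams_per_line=16, n_f0_sires=16, n_f0_dams=16,
        response_litters_per_gen=1, response_resid_scale=1.0,
        response_missing_rate=0.0,
    )


def lr_slope_unselected_trial(seed: int, line: str = "HRFI",
                              trait: str = "ADG") -> float:
    out = lr_identity_trial(seed, unselected_config(seed), line, trait)
    return out["slope"]


def williams_null_pvalues(seed: int, n: int = 400, n_reps: int = 2000,
                          rho: float = 0.5, rho23: float = 0.3) -> np.ndarray:
    """Williams-test p-values under a simulated null (equal dependent
    correlations of variables 2 and 3 with the shared variable 1)."""
    rng = np.random.default_rng(seed)
    C = np.array([[1.0, rho, rho], [rho, 1.0, rho23], [rho, rho23, 1.0]])
    L = np.linalg.cholesky(C)
    pvals = np.empty(n_reps)
    for k in range(n_reps):
        X = rng.standard_normal((n, 3)) @ L.T
        R = np.corrcoef(X.T)
        _, pvals[k], _ = williams_test(R[0, 1], R[0, 2], R[1, 2], n)
    return pvals


def hwe_grm_diagonal(seed: int, n: int = 1000, m: int = 2000) -> float:
    """Mean diagonal of the VanRaden G in a Hardy-Weinberg population."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.05, 0.95, m)
    dose = rng.binomial(2, p, size=(n, m)).astype(np.int8)
    mm = pd.DataFrame({"snp": [f"s{j}" for j in range(m)], "chrom": 1,
                       "pos": np.arange(m), "sex_chrom": False})
    geno = GenotypeMatrix(dose, np.array([f"i{k}" for k in range(n)], dtype=object), mm)
    return float(np.mean(np.diag(build_G(geno).dense())))
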