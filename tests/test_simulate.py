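"""The divergent-selection study generator: genetics, selection response,
and observability masking."""

import numpy as np
import pandas as pd
import pytest

import ssgblup as sg
from ssgblup.simulate import simulate_founders


def tiny_config(**kw):
    base = dict(n_snps=200, n_qtl=60, n_generations=2,
                n_g0_candidates=16, n_candidates_per_gen=16,
                n_dams_per_line=8, n_f0_sires=8, n_f0_dams=8,
                response_litters_per_gen=1, seed=5)
    base.update(kw)
    return sg.SimConfig(**base)


# --------------------------------------------------------------------------
# founders


def test_zero_snp_config_gives_empty_genotypes():
    cfg = tiny_config(n_snps=0)
    study, bundle = sg.simulate_study(cfg)
    assert study.genotypes.dose.shape[1] == 0
    assert study.pedigree.n > 0  # pedigree still valid


def test_point_mass_founder_frequencies():
    cfg = tiny_config(founder_maf=(0.5, 0.5), n_f0_sires=500, n_f0_dams=500,
                      n_snps=300)
    founders = simulate_founders(cfg)
    snp_idx = founders.loci["is_snp"].to_numpy()
    freqs = founders.haplotypes.mean(axis=(0, 1))[snp_idx]
    # binomial sampling error at n=1000 founders (2000 haplotypes)
    assert np.abs(freqs - 0.5).max() < 5 * np.sqrt(0.25 / 2000)


def test_founder_genic_variance_ratios_match_targets():
    cfg = tiny_config(n_f0_sires=1000, n_f0_dams=1000, n_snps=400, n_qtl=150)
    founders = simulate_founders(cfg)
    tbv = founders.tbv_qtl()
    ratios = tbv.var(axis=0, ddof=1) / np.asarray(cfg.phenotypic_variances)
    np.testing.assert_allclose(ratios, cfg.heritabilities, atol=0.03)


def test_non_psd_covariance_rejected():
    bad = np.array([[1.0, 2.0, 0.0], [2.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
    with pytest.raises(ValueError, match="positive semi-definite"):
        tiny_config(genetic_corr=bad)


def test_more_sires_than_candidates_rejected():
    with pytest.raises(ValueError, match="sires"):
        tiny_config(n_selected_sires=20, n_candidates_per_gen=16)


# --------------------------------------------------------------------------
# breeding and transmission


def test_gene_dropping_is_mendelian(small_study):
    """No offspring is opposite-homozygous to either parent at any SNP."""
    study, _ = small_study
    dose = study.genotypes.dose
    ped = study.pedigree
    pos = {a: i for i, a in enumerate(study.genotypes.ids)}
    idx = ped.positions(study.genotypes.ids)
    for row, k in enumerate(idx):
        for parent in (ped.sire[k], ped.dam[k]):
            if parent < 0:
                continue
            prow = pos[ped.ids[parent]]
            child, par = dose[row], dose[prow]
            bad = ((child == 0) & (par == 2)) | ((child == 2) & (par == 0))
            assert not bad.any()


def test_tbv_recursion_midparent():
    """Offspring TBV = midparent TBV + Mendelian sampling: the regression
    of offspring on midparent TBV has slope 1 within 0.05 at >1000 trios."""
    cfg = sg.SimConfig(n_snps=600, n_qtl=150, n_generations=6,
                       n_g0_candidates=64, n_candidates_per_gen=64,
                       n_dams_per_line=20, n_f0_sires=16, n_f0_dams=16,
                       response_litters_per_gen=1, seed=314)
    study, _ = sg.simulate_study(cfg)
    tb = study.tbv.set_index("id")["ADG"]
    meta = study.meta
    has = meta[meta.sire != "0"]
    assert len(has) >= 1000
    mp = 0.5 * (tb.loc[has.sire].to_numpy() + tb.loc[has.dam].to_numpy())
    off = tb.loc[has.id].to_numpy()
    slope = np.polyfit(mp, off, 1)[0]
    assert slope == pytest.approx(1.0, abs=0.05)


def test_random_selection_no_systematic_response():
    """With a selection differential of zero, line means differ only by
    drift: |mean difference| < 3 SE over replicate seeds."""
    diffs = []
    for seed in range(20):
        cfg = tiny_config(seed=seed, random_selection=True, n_generations=1)
        study, _ = sg.simulate_study(cfg)
        tb = study.tbv.set_index("id")
        m = study.meta.set_index("id")
        hr = tb.loc[m[m.line == "HRFI"].index, "RFI"].mean()
        lr = tb.loc[m[m.line == "LRFI"].index, "RFI"].mean()
        diffs.append(hr - lr)
    diffs = np.array(diffs)
    se = diffs.std(ddof=1) / np.sqrt(len(diffs))
    assert abs(diffs.mean()) < 3 * se


def test_selection_direction_per_line(small_study):
    """Realized index response has the selection sign in each line."""
    study, _ = small_study
    tb = study.tbv.set_index("id")
    m = study.meta.set_index("id")
    gens = [f"G{g}" for g in range(1, study.config.n_generations + 1)]
    hr = [tb.loc[m[(m.line == "HRFI") & (m.generation == g)].index, "RFI"].mean()
          for g in gens]
    lr = [tb.loc[m[(m.line == "LRFI") & (m.generation == g)].index, "RFI"].mean()
          for g in gens]
    assert hr[-1] > hr[0]
    assert lr[-1] < lr[0]
    assert hr[-1] > lr[-1]


def test_allele_frequency_divergence_grows():
    """Mean |p_HRFI - p_LRFI| larger in the last generation than early on."""
    gaps = {"early": [], "late": []}
    for seed in range(5):
        cfg = tiny_config(seed=100 + seed, n_generations=4, n_snps=300)
        study, _ = sg.simulate_study(cfg)
        m = study.meta
        dose = study.genotypes.dose
        pos = {a: i for i, a in enumerate(study.genotypes.ids)}
        for label, gen in (("early", "G1"), ("late", "G4")):
            gap = []
            for line in ("HRFI", "LRFI"):
                ids = m[(m.line == line) & (m.generation == gen)]["id"]
                rows = [pos[a] for a in ids]
                gap.append(dose[rows].mean(axis=0) / 2.0)
            gaps[label].append(np.abs(gap[0] - gap[1]).mean())
    assert np.mean(gaps["late"]) > np.mean(gaps["early"])


def test_same_seed_bit_identical_bundle():
    cfg = tiny_config(seed=31)
    s1, b1 = sg.simulate_study(cfg)
    s2, b2 = sg.simulate_study(cfg)
    np.testing.assert_array_equal(b1.genotypes.dose, b2.genotypes.dose)
    pd.testing.assert_frame_equal(b1.phenotypes, b2.phenotypes)
    pd.testing.assert_frame_equal(b1.meta, b2.meta)
    np.testing.assert_array_equal(s1.tbv.to_numpy(), s2.tbv.to_numpy())


def test_too_few_male_candidates_raises():
    cfg = tiny_config(n_selected_sires=6, n_g0_candidates=4)
    with pytest.raises(Exception):
        sg.simulate_study(cfg)


# --------------------------------------------------------------------------
# observability mask


def test_mask_all_observed_is_identity(small_config):
    cfg = sg.SimConfig(**{**small_config.__dict__,
                          "genotyping_mask_rule": "all",
                          "phenotyping_mask_rule": "all"})
    study, bundle = sg.simulate_study(cfg)
    assert bundle.genotypes.n_individuals == study.genotypes.n_individuals
    pd.testing.assert_frame_equal(bundle.phenotypes, study.phenotypes)
    assert "id" in bundle.meta.columns  # no TBV columns in the bundle
    assert not any(c in bundle.meta.columns for c in ("RFI_tbv", "tbv"))


def test_default_mask_rules(small_study):
    study, bundle = small_study
    gset = set(bundle.genotypes.ids)
    m = study.meta
    last = f"G{study.config.n_generations}"
    cands_last = m[(m.cohort == "candidate") & (m.generation == last)]["id"]
    assert all(a in gset for a in cands_last)   # every last-gen candidate
    early_resp = m[(m.cohort == "response")
                   & ~m.generation.isin([f"G{g}" for g in
                                         range(6, study.config.n_generations)])]
    assert not any(a in gset for a in early_resp["id"])


def test_genotyped_count_increases_into_last_generation():
    study, bundle = sg.simulate_study(sg.SimConfig(
        n_snps=300, n_qtl=50, seed=9, n_g0_candidates=48,
        n_candidates_per_gen=48, n_dams_per_line=18, n_f0_sires=15,
        n_f0_dams=15))
    m = study.meta
    gset = set(bundle.genotypes.ids)
    counts = [m[(m.generation == f"G{g}") & m.id.isin(gset)].shape[0]
              for g in (6, 7, 8, 9)]
    # the design concentrates genotyping in the last generations; G9
    # (all candidates) dominates
    assert counts[3] == max(counts)
    assert counts[3] > counts[0]


# --------------------------------------------------------------------------
# I/O round trips


def test_write_bundle_and_reload(tmp_path, small_study):
    study, bundle = small_study
    sg.write_bundle(bundle, tmp_path, tbv=study.tbv)
    from ssgblup.io import read_pedigree_csv, read_phenotypes, read_plink

    ped = read_pedigree_csv(tmp_path / "pedigree.csv")
    assert len(ped) == bundle.pedigree.n
    phen = read_phenotypes(tmp_path / "phenotypes.tsv")
    assert len(phen) == len(bundle.phenotypes)
    np.testing.assert_allclose(phen["ADG"].to_numpy(),
                               bundle.phenotypes["ADG"].to_numpy(), atol=1e-6)
    geno = read_plink(str(tmp_path / "genotypes"))
    assert geno.n_individuals == bundle.genotypes.n_individuals
    assert geno.n_snps == bundle.genotypes.n_snps


def test_config_yaml_round_trip(tmp_path):
    cfg = tiny_config(seed=123)
    cfg.to_yaml(tmp_path / "config.yaml")
    back = sg.SimConfig.from_yaml(tmp_path / "config.yaml")
    back.to_yaml(tmp_path / "config2.yaml")
    assert (tmp_path / "config.yaml").read_text() == \
        (tmp_path / "config2.yaml").read_text()
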