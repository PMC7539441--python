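"""H-matrix assembly and the mixed-model solver against direct oracles."""

import numpy as np
import pandas as pd
import pytest

import ssgblup as sg
from ssgblup.engine import MMEDesign, VarianceComponents

from conftest import random_pedigree


def fixture_pedigree(rng, n_founders=8, n_offspring=32):
    return random_pedigree(rng, n_founders, n_offspring)


def perturbed_G(A22, rng, scale=0.05):
    n = A22.n
    E = rng.normal(0, scale, (n, n))
    vals = A22.dense() + (E + E.T) / 2 + scale * np.eye(n)
    return sg.RelationshipMatrix(vals, A22.ids.copy(), kind="G")


# --------------------------------------------------------------------------
# H matrices


def test_H_inverse_without_genotypes_equals_A_inverse(rng):
    ped = fixture_pedigree(rng)
    Ainv = sg.A_inverse(ped)
    Hinv = sg.build_H_inverse(Ainv, None, None)
    np.testing.assert_array_equal(Hinv.dense(), Ainv.dense())


def test_H_equals_A_when_G_equals_A22(rng):
    ped = fixture_pedigree(rng)
    A, Ainv = sg.build_A(ped), sg.A_inverse(ped)
    gids = list(ped.ids[10:25])
    A22 = sg.subset_A22(A, gids)
    G = sg.RelationshipMatrix(A22.dense().copy(), np.asarray(gids, dtype=object), "G")
    np.testing.assert_allclose(sg.build_H_dense(A, G, gids).dense(), A.dense(),
                               atol=1e-10)
    np.testing.assert_allclose(sg.build_H_inverse(Ainv, G, A22).dense(),
                               Ainv.dense(), atol=1e-10)


def test_H_inverse_matches_dense_H_oracle(rng):
    """40-animal pedigree, 15 genotyped: assembled H^-1 equals the inverse
    of the dense H built from the joint conditional-expectation formula."""
    ped = fixture_pedigree(rng, 8, 32)
    A, Ainv = sg.build_A(ped), sg.A_inverse(ped)
    gids = list(rng.choice(ped.ids, size=15, replace=False))
    A22 = sg.subset_A22(A, gids)
    G = perturbed_G(A22, rng)
    Gb = sg.tune_and_blend_G(G, A22, 0.05)
    Hd = sg.build_H_dense(A, Gb, gids)
    Hinv = sg.build_H_inverse(Ainv, Gb, A22)
    assert np.abs(np.linalg.inv(Hd.dense()) - Hinv.dense()).max() < 1e-6


def test_H_dense_blocks(rng):
    ped = fixture_pedigree(rng)
    A = sg.build_A(ped)
    gids = list(ped.ids[::3])
    A22 = sg.subset_A22(A, gids)
    G = perturbed_G(A22, rng)
    H = sg.build_H_dense(A, G, gids)
    pos = ped.positions(gids)
    np.testing.assert_allclose(H.dense()[np.ix_(pos, pos)], G.dense(), atol=1e-12)


# --------------------------------------------------------------------------
# solver


def bivariate_fixture(rng, n_founders=8, n_off=52, miss=True):
    ped = fixture_pedigree(rng, n_founders, n_off)
    ids = [a for a in ped.ids if ped.sire[ped.positions([a])[0]] >= 0]
    n = len(ids)
    df = pd.DataFrame({
        "id": ids,
        "t1": rng.normal(20, 3, n),
        "t2": rng.normal(-5, 1.5, n),
        "sex": rng.choice(["M", "F"], n),
        "litter": rng.choice([f"L{k}" for k in range(8)], n),
    })
    if miss:
        df.loc[df.index[:6], "t1"] = np.nan
        df.loc[df.index[-5:], "t2"] = np.nan
    model = sg.ModelSpec(traits=("t1", "t2"), factors=("sex",), litter="litter")
    vc = VarianceComponents(np.array([[2.0, 0.5], [0.5, 1.0]]),
                            np.array([[0.6, 0.1], [0.1, 0.3]]),
                            np.array([[3.0, 0.8], [0.8, 1.5]]),
                            traits=("t1", "t2"))
    return ped, df, model, vc


def gls_solutions(ped, df, model, vc):
    """Direct generalized-least-squares BLUE/BLUP from the full variance
    matrix V = Z (G0 x A) Z' + Z_l (Rl x I) Z_l' + R."""
    d = MMEDesign(df, model, ped)
    W = d.W.toarray()
    X, Za, Zl = W[:, : d.off_a], W[:, d.off_a: d.off_l], W[:, d.off_l:]
    A = sg.build_A(ped).dense()
    Ga = np.kron(vc.G0, A)
    Gl = np.kron(vc.Rl, np.eye(d.m))
    R = np.zeros((d.N, d.N))
    for (r0, r1) in d.units_both:
        R[r0, r0], R[r1, r1] = vc.Re[0, 0], vc.Re[1, 1]
        R[r0, r1] = R[r1, r0] = vc.Re[0, 1]
    for k, only in enumerate(d.units_only):
        for r in only:
            R[r, r] = vc.Re[k, k]
    V = Za @ Ga @ Za.T + Zl @ Gl @ Zl.T + R
    Vi = np.linalg.inv(V)
    b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ d.y)
    u = Ga @ Za.T @ Vi @ (d.y - X @ b)
    return b, u


def test_solver_matches_direct_gls_oracle(rng):
    """Bivariate fixture with litters and missing-trait patterns: MME
    solutions equal BLUP computed directly from V."""
    ped, df, model, vc = bivariate_fixture(rng)
    sol = sg.solve_ssgblup(df, model, vc, sg.A_inverse(ped), ped)
    b, u = gls_solutions(ped, df, model, vc)
    got_b = np.concatenate([sol.fixed["t1"].to_numpy(), sol.fixed["t2"].to_numpy()])
    got_u = np.concatenate([sol.gebv["t1"].to_numpy(), sol.gebv["t2"].to_numpy()])
    assert np.abs(got_b - b).max() < 1e-6
    assert np.abs(got_u - u).max() < 1e-6


def test_single_record_shrinks_to_zero():
    """One animal, one record equal to the fitted mean: a-hat is zero."""
    ped = sg.Pedigree.from_records([("x", 0, 0)])
    df = pd.DataFrame({"id": ["x"], "t1": [7.0]})
    model = sg.ModelSpec(traits=("t1",), factors=(), litter=None)
    vc = VarianceComponents([[1.0]], None, [[3.0]], traits=("t1",))
    sol = sg.solve_ssgblup(df, model, vc, sg.A_inverse(ped), ped)
    assert sol.fixed["t1"]["intercept"] == pytest.approx(7.0)
    assert sol.gebv["t1"].iloc[0] == pytest.approx(0.0, abs=1e-12)


def test_solution_invariant_to_animal_reordering(rng):
    ped, df, model, vc = bivariate_fixture(rng)
    sol1 = sg.solve_ssgblup(df, model, vc, sg.A_inverse(ped), ped)
    df2 = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
    sol2 = sg.solve_ssgblup(df2, model, vc, sg.A_inverse(ped), ped)
    g1 = sol1.gebv.set_index("id").sort_index()
    g2 = sol2.gebv.set_index("id").sort_index()
    assert np.abs(g1.to_numpy() - g2.to_numpy()).max() < 1e-8


def test_zero_covariance_bivariate_equals_two_univariates(rng):
    ped, df, model, vc = bivariate_fixture(rng, miss=False)
    vc0 = VarianceComponents(np.diag(np.diag(vc.G0)), np.diag(np.diag(vc.Rl)),
                             np.diag(np.diag(vc.Re)), traits=("t1", "t2"))
    Ainv = sg.A_inverse(ped)
    sol = sg.solve_ssgblup(df, model, vc0, Ainv, ped)
    for k, t in enumerate(("t1", "t2")):
        mu = sg.ModelSpec(traits=(t,), factors=("sex",), litter="litter")
        vcu = VarianceComponents([[vc.G0[k, k]]], [[vc.Rl[k, k]]],
                                 [[vc.Re[k, k]]], traits=(t,))
        solu = sg.solve_ssgblup(df, mu, vcu, Ainv, ped)
        assert np.abs(sol.gebv[t].to_numpy() - solu.gebv[t].to_numpy()).max() < 1e-8


def test_monotone_shrinkage_with_rising_residual_variance(rng):
    ped, df, model, vc = bivariate_fixture(rng, miss=False)
    model1 = sg.ModelSpec(traits=("t1",), factors=("sex",), litter="litter")
    Ainv = sg.A_inverse(ped)
    norms = []
    for se in (1.0, 4.0, 16.0):
        vcu = VarianceComponents([[2.0]], [[0.4]], [[se]], traits=("t1",))
        sol = sg.solve_ssgblup(df, model1, vcu, Ainv, ped)
        # phenotyped animals' own deviations shrink as residual variance grows
        norms.append(np.abs(sol.gebv["t1"]).mean())
    assert norms[0] > norms[1] > norms[2]


def test_founder_mean_gebv_near_zero_without_selection(rng):
    ped, df, model, vc = bivariate_fixture(rng, miss=False)
    model1 = sg.ModelSpec(traits=("t1",), factors=(), litter=None)
    vcu = VarianceComponents([[2.0]], None, [[3.0]], traits=("t1",))
    sol = sg.solve_ssgblup(df, model1, vcu, sg.A_inverse(ped), ped)
    founders = [a for i, a in enumerate(ped.ids) if ped.sire[i] < 0]
    mean_f = sol.gebv.set_index("id").loc[founders, "t1"].mean()
    # no selection, single overall mean: base animals average ~0
    assert abs(mean_f) < 0.3


def test_aliased_fixed_levels_raise_informative_error(rng):
    ped, df, model, vc = bivariate_fixture(rng, miss=False)
    df = df.assign(dup=df["sex"])  # perfectly aliased with sex
    model2 = sg.ModelSpec(traits=("t1", "t2"), factors=("sex", "dup"),
                          litter="litter")
    with pytest.raises(np.linalg.LinAlgError, match="aliased|singular"):
        sg.solve_ssgblup(df, model2, vc, sg.A_inverse(ped), ped)


def test_solution_and_varcomp_text_exports(tmp_path, rng):
    ped, df, model, vc = bivariate_fixture(rng)
    sol = sg.solve_ssgblup(df, model, vc, sg.A_inverse(ped), ped)
    sol.to_tsv(tmp_path / "gebv.tsv")
    back = pd.read_csv(tmp_path / "gebv.tsv", sep="\t")
    assert set(back.columns) == {"id", "trait", "gebv"}
    assert len(back) == 2 * ped.n
    vc.to_text(tmp_path / "vc.txt")
    text = (tmp_path / "vc.txt").read_text()
    assert "genetic" in text and "residual" in text and "h2" in text


def test_h_inverse_id_order_must_match(rng):
    ped, df, model, vc = bivariate_fixture(rng)
    Ainv = sg.A_inverse(ped)
    bad = sg.RelationshipMatrix(Ainv.values, Ainv.ids[::-1].copy(), kind="H")
    with pytest.raises(ValueError, match="order"):
        sg.solve_ssgblup(df, model, vc, bad, ped)
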