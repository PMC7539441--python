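"""Restricted maximum likelihood for the (bi)variate animal model.

Estimates the additive-genetic (G0), litter (Rl) and residual (Re)
covariance matrices of the model y = Xb + Z1 a + Z2 l + e with
a ~ N(0, G0 (x) A), by maximizing the restricted likelihood.  The engine
takes expectation-maximization (EM) steps with average-information (AI)
acceleration: each iteration factorizes the mixed-model equations, computes
exact first derivatives and the AI matrix, and attempts a Newton-type step,
falling back to step halving and to a plain EM update whenever the AI
proposal leaves the parameter space or decreases the likelihood.  Records
with one missing trait of the pair are handled exactly through per-pattern
residual blocks.

Variance components are, per the study's procedure, estimated with the
pedigree relationship matrix A only (no genomic information), on all
available data, once per trait pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp

from .engine import MMEDesign, ModelSpec, VarianceComponents
from .pedigree import Pedigree, A_inverse, inbreeding, mendelian_variances

logger = logging.getLogger(__name__)

__all__ = ["estimate_varcomp", "RemlError"]


class RemlError(RuntimeError):
    """REML failed to converge; carries the likelihood trajectory."""

    def __init__(self, message: str, trajectory=None):
        super().__init__(message)
        self.trajectory = trajectory or []


def _vech(mats: list[np.ndarray]) -> np.ndarray:
    out = []
    for M in mats:
        t = M.shape[0]
        for i in range(t):
            for j in range(i + 1):
                out.append(M[i, j])
    return np.array(out)


def _unvech(theta: np.ndarray, t: int, n_mats: int) -> list[np.ndarray]:
    k = t * (t + 1) // 2
    mats = []
    for b in range(n_mats):
        M = np.zeros((t, t))
        vals = theta[b * k: (b + 1) * k]
        c = 0
        for i in range(t):
            for j in range(i + 1):
                M[i, j] = M[j, i] = vals[c]
                c += 1
        mats.append(M)
    return mats


def _is_pd(M: np.ndarray, floor: float = 0.0) -> bool:
    try:
        return np.linalg.eigvalsh(M).min() > floor
    except np.linalg.LinAlgError:
        return False


def _project_psd(M: np.ndarray, floor: float) -> np.ndarray:
    """Clamp eigenvalues at ``floor``: keeps boundary-bound AI proposals in
    the parameter space instead of rejecting the whole step."""
    w, V = np.linalg.eigh(M)
    if w.min() > floor:
        return M
    return (V * np.maximum(w, floor)) @ V.T


class _RemlEngine:
    def __init__(self, design: MMEDesign, Kinv: sp.spmatrix, logdet_K: float):
        self.d = design
        self.Kinv = sp.coo_matrix(Kinv)
        self.Kinv_csr = sp.csr_matrix(Kinv)
        self.logdet_K = logdet_K
        self.t = len(design.traits)
        self.use_litter = design.model.litter is not None and design.m > 0
        self.n_units = len(design.units_both) + sum(len(u) for u in design.units_only)

        # padded per-record sparse-row views of W, for W_i C^-1 W_i' gathers
        W = design.W
        kmax = int(np.diff(W.indptr).max())
        N = design.N
        self.w_idx = np.zeros((N, kmax), dtype=np.int64)
        self.w_val = np.zeros((N, kmax))
        for r in range(N):
            sl = slice(W.indptr[r], W.indptr[r + 1])
            nz = W.indptr[r + 1] - W.indptr[r]
            self.w_idx[r, :nz] = W.indices[sl]
            self.w_val[r, :nz] = W.data[sl]

    # -- per-iteration state --------------------------------------------
    def factorize(self, vc: VarianceComponents):
        d = self.d
        C, rhs, Rinv = d.build_C(vc, self.Kinv_csr)
        try:
            cf = sla.cho_factor(C, lower=True)
        except np.linalg.LinAlgError as exc:
            raise RemlError(f"coefficient matrix not positive definite: {exc}") from exc
        theta_hat = sla.cho_solve(cf, rhs)
        logdet_C = 2.0 * np.sum(np.log(np.diag(cf[0])))
        ypy = float(self.y_rinv_y(Rinv) - rhs @ theta_hat)
        m2ll = (
            logdet_C
            + d.logdet_R(vc.Re)
            + d.q * np.log(np.linalg.det(vc.G0))
            + self.t * self.logdet_K
            + (d.m * np.log(np.linalg.det(vc.Rl)) if self.use_litter else 0.0)
            + ypy
        )
        return dict(C=C, rhs=rhs, Rinv=Rinv, cf=cf, theta=theta_hat, m2ll=float(m2ll))

    def y_rinv_y(self, Rinv) -> float:
        return float(self.d.y @ (Rinv @ self.d.y))

    def loglik_only(self, vc: VarianceComponents) -> float:
        """-2 log restricted likelihood without the inverse (cheaper probe)."""
        return self.factorize(vc)["m2ll"]

    # -- derivative machinery -------------------------------------------
    def derivatives(self, vc: VarianceComponents, state):
        d, t = self.d, self.t
        C, cf, Rinv, theta = state["C"], state["cf"], state["Rinv"], state["theta"]
        from scipy.linalg.lapack import dpotri

        inv, info = dpotri(cf[0], lower=True)
        if info != 0:
            raise RemlError(f"dpotri failed with info={info}")
        # dpotri fills only the lower triangle; the upper keeps factor junk
        Cinv = np.tril(inv) + np.tril(inv, -1).T
        q, m = d.q, d.m
        G0inv = np.linalg.inv(vc.G0)
        Rlinv = np.linalg.inv(vc.Rl) if self.use_litter else None
        Re = vc.Re
        ehat = d.y - d.W @ theta
        etil = Rinv @ ehat

        uhat = np.stack([theta[d.off_a + k * q: d.off_a + (k + 1) * q] for k in range(t)])
        lhat = (np.stack([theta[d.off_l + k * m: d.off_l + (k + 1) * m] for k in range(t)])
                if self.use_litter else None)

        # genetic: S_a[v,w] = tr(K^-1 C^{a_v a_w}); Q_a[v,w] = u_v' K^-1 u_w
        Ku = np.stack([self.Kinv_csr @ uhat[k] for k in range(t)])
        Q_a = uhat @ Ku.T
        S_a = np.zeros((t, t))
        kr, kc, kd = self.Kinv.row, self.Kinv.col, self.Kinv.data
        for v in range(t):
            for w in range(v + 1):
                blk = Cinv[d.off_a + v * q: d.off_a + (v + 1) * q,
                           d.off_a + w * q: d.off_a + (w + 1) * q]
                S_a[v, w] = S_a[w, v] = float((kd * blk[kr, kc]).sum())

        if self.use_litter:
            Q_l = lhat @ lhat.T
            S_l = np.zeros((t, t))
            for v in range(t):
                for w in range(v + 1):
                    blk = Cinv[d.off_l + v * m: d.off_l + (v + 1) * m,
                               d.off_l + w * m: d.off_l + (w + 1) * m]
                    S_l[v, w] = S_l[w, v] = float(np.trace(blk))
        else:
            Q_l = S_l = None

        # per-unit T_i = W_i C^-1 W_i'
        T = self._unit_quadratics(Cinv)

        return dict(Cinv=Cinv, ehat=ehat, etil=etil, uhat=uhat, lhat=lhat,
                    Q_a=Q_a, S_a=S_a, Q_l=Q_l, S_l=S_l, T=T,
                    G0inv=G0inv, Rlinv=Rlinv)

    def _unit_quadratics(self, Cinv):
        d = self.d
        out = {}
        ub = d.units_both
        if len(ub):
            i0, i1 = self.w_idx[ub[:, 0]], self.w_idx[ub[:, 1]]
            v0, v1 = self.w_val[ub[:, 0]], self.w_val[ub[:, 1]]
            out["b00"] = np.einsum("nk,nl,nkl->n", v0, v0,
                                   Cinv[i0[:, :, None], i0[:, None, :]])
            out["b11"] = np.einsum("nk,nl,nkl->n", v1, v1,
                                   Cinv[i1[:, :, None], i1[:, None, :]])
            out["b01"] = np.einsum("nk,nl,nkl->n", v0, v1,
                                   Cinv[i0[:, :, None], i1[:, None, :]])
        for k, only in enumerate(d.units_only):
            if len(only):
                i, v = self.w_idx[only], self.w_val[only]
                out[f"o{k}"] = np.einsum("nk,nl,nkl->n", v, v,
                                         Cinv[i[:, :, None], i[:, None, :]])
        return out

    # -- score and AI ----------------------------------------------------
    def _param_list(self):
        t = self.t
        mats = ["G0"] + (["Rl"] if self.use_litter else []) + ["Re"]
        params = []
        for mat in mats:
            for i in range(t):
                for j in range(i + 1):
                    params.append((mat, i, j))
        return params

    def score_and_ai(self, vc, state, der):
        d, t = self.d, self.t
        q, m = d.q, d.m
        params = self._param_list()
        n_par = len(params)
        G0inv, Rlinv = der["G0inv"], der["Rlinv"]
        Re = vc.Re
        Reinv = np.linalg.inv(Re)
        etil = der["etil"]
        T = der["T"]
        ub = d.units_both

        def E(i, j):
            M = np.zeros((t, t))
            M[i, j] = M[j, i] = 1.0
            return M

        # trace(P V_k) and y'P V_k P y per parameter
        tr_pv = np.zeros(n_par)
        ypvpy = np.zeros(n_par)
        fvec = np.zeros((d.N, n_par))
        # residual helper: M_i = Rinv_i T_i Rinv_i per unit (2x2 for "both")
        if t == 2 and len(ub):
            Tb = np.empty((len(ub), 2, 2))
            Tb[:, 0, 0], Tb[:, 0, 1] = T["b00"], T["b01"]
            Tb[:, 1, 0], Tb[:, 1, 1] = T["b01"], T["b11"]
            Mb = np.einsum("ab,nbc,cd->nad", Reinv, Tb, Reinv)
            eb = np.stack([etil[ub[:, 0]], etil[ub[:, 1]]], axis=1)  # (n,2)

        for ip, (mat, i, j) in enumerate(params):
            Eij = E(i, j)
            if mat == "G0":
                Mm = G0inv @ Eij @ G0inv
                tr_pv[ip] = q * np.trace(Eij @ G0inv) - np.trace(
                    Eij @ G0inv @ der["S_a"] @ G0inv)
                ypvpy[ip] = float(np.sum(Mm * der["Q_a"]))
                B = Eij @ G0inv  # f = Z (B (x) I) u
                vals = (B @ der["uhat"])[d.rec_trait, d.rec_animal]
                fvec[:, ip] = vals
            elif mat == "Rl":
                Mm = Rlinv @ Eij @ Rlinv
                tr_pv[ip] = m * np.trace(Eij @ Rlinv) - np.trace(
                    Eij @ Rlinv @ der["S_l"] @ Rlinv)
                ypvpy[ip] = float(np.sum(Mm * der["Q_l"]))
                B = Eij @ Rlinv
                vals = (B @ der["lhat"])[d.rec_trait, d.rec_litter]
                fvec[:, ip] = vals
            else:  # Re
                tr1 = 0.0
                tr2 = 0.0
                yv = 0.0
                if t == 2 and len(ub):
                    tr1 += len(ub) * (Reinv[i, i] if i == j else 2 * Reinv[i, j])
                    tr2 += float(Mb[:, i, j].sum() + (Mb[:, j, i].sum() if i != j else 0.0))
                    if i == j:
                        yv += float((eb[:, i] ** 2).sum())
                        fvec[ub[:, i], ip] += eb[:, i]
                    else:
                        yv += 2.0 * float((eb[:, 0] * eb[:, 1]).sum())
                        fvec[ub[:, 0], ip] += eb[:, 1]
                        fvec[ub[:, 1], ip] += eb[:, 0]
                for k in range(t):
                    only = d.units_only[k]
                    if len(only) and i == j == k:
                        tr1 += len(only) / Re[k, k]
                        tr2 += float(T[f"o{k}"].sum()) / Re[k, k] ** 2
                        yv += float((etil[only] ** 2).sum())
                        fvec[only, ip] += etil[only]
                tr_pv[ip] = tr1 - tr2
                ypvpy[ip] = yv

        score = -0.5 * (tr_pv - ypvpy)

        # AI matrix: 0.5 * f_j' P f_k with P f = Rinv f - Rinv W C^-1 W' Rinv f
        Rf = state["Rinv"] @ fvec
        h = sla.cho_solve(state["cf"], d.W.T @ Rf)
        Pf = Rf - state["Rinv"] @ (d.W @ h)
        AI = 0.5 * (fvec.T @ Pf)
        return score, AI

    # -- EM update --------------------------------------------------------
    def em_update(self, vc, der):
        d, t = self.d, self.t
        G0_new = (der["Q_a"] + der["S_a"]) / d.q
        Rl_new = ((der["Q_l"] + der["S_l"]) / d.m) if self.use_litter else None
        # residual: E[e e' | y] averaged over units, missing traits imputed
        Re = vc.Re
        ehat, T = der["ehat"], der["T"]
        acc = np.zeros((t, t))
        ub = d.units_both
        if t == 2 and len(ub):
            e0, e1 = ehat[ub[:, 0]], ehat[ub[:, 1]]
            acc[0, 0] += float((e0 * e0 + T["b00"]).sum())
            acc[1, 1] += float((e1 * e1 + T["b11"]).sum())
            c01 = float((e0 * e1 + T["b01"]).sum())
            acc[0, 1] += c01
            acc[1, 0] += c01
        for k in range(t):
            only = d.units_only[k]
            if not len(only):
                continue
            ee = ehat[only] ** 2 + T[f"o{k}"]
            s = float(ee.sum())
            acc[k, k] += s
            if t == 2:
                mk = 1 - k
                B = Re[mk, k] / Re[k, k]
                acc[mk, k] += B * s
                acc[k, mk] += B * s
                acc[mk, mk] += B * B * s + len(only) * (
                    Re[mk, mk] - B * Re[k, mk])
        Re_new = acc / self.n_units
        return G0_new, Rl_new, Re_new


def estimate_varcomp(
    phenos: pd.DataFrame,
    model: ModelSpec,
    ped: Pedigree,
    start: VarianceComponents | None = None,
    max_iter: int = 200,
    tol: float = 1e-8,
    n_em_start: int = 2,
    identity_relationship: bool = False,
    verbose: bool = False,
) -> VarianceComponents:
    """Bivariate (or univariate) REML with the pedigree relationship matrix.

    Takes ``n_em_start`` plain EM steps, then AI steps with step halving and
    EM fallback.  Convergence: max relative parameter change below ``tol``
    (default 1e-8) within ``max_iter`` (default 200) iterations.  Estimates
    pinned near the parameter-space boundary are flagged.
    """
    design = MMEDesign(phenos, model, ped)
    t = len(design.traits)
    if model.litter and design.m < 2:
        raise ValueError("need at least 2 litters to separate litter variance")
    if identity_relationship:
        Kinv = sp.identity(ped.n, format="csr")
        logdet_K = 0.0
    else:
        F = inbreeding(ped)
        Kinv = sp.csr_matrix(A_inverse(ped, F).values)
        logdet_K = float(np.sum(np.log(mendelian_variances(ped, F))))
    eng = _RemlEngine(design, Kinv, logdet_K)

    # starting values: fractions of the observed phenotypic variance
    if start is None:
        v = np.array([np.nanvar(design.y[design.rec_trait == k], ddof=1)
                      for k in range(t)])
        sd = np.sqrt(v)
        corr0 = 0.2 * (np.ones((t, t)) - np.eye(t)) + np.eye(t)
        G0 = 0.30 * corr0 * np.outer(sd, sd)
        Rl = 0.10 * corr0 * np.outer(sd, sd) if model.litter else None
        Re = 0.60 * corr0 * np.outer(sd, sd)
        vc = VarianceComponents(G0, Rl, Re, traits=design.traits)
    else:
        vc = VarianceComponents(start.G0.copy(),
                                None if start.Rl is None else start.Rl.copy(),
                                start.Re.copy(), traits=design.traits)
    floor = 1e-8 * float(np.mean([vc.G0[i, i] + vc.Re[i, i] for i in range(t)]))

    n_mats = 2 + (1 if eng.use_litter else 0)
    trajectory = []
    state = eng.factorize(vc)
    converged = False
    stall = 0
    it = 0
    for it in range(1, max_iter + 1):
        der = eng.derivatives(vc, state)
        old = _vech([vc.G0] + ([vc.Rl] if eng.use_litter else []) + [vc.Re])

        accepted = False
        if it > n_em_start:
            score, AI = eng.score_and_ai(vc, state, der)
            try:
                delta = np.linalg.solve(AI, score)
            except np.linalg.LinAlgError:
                delta = None
            if delta is not None:
                step = 1.0
                for _ in range(7):
                    cand = old + step * delta
                    mats = [_project_psd(M, floor) for M in _unvech(cand, t, n_mats)]
                    G0c = mats[0]
                    Rlc = mats[1] if eng.use_litter else None
                    Rec = mats[-1]
                    ok = (_is_pd(G0c, 0.0) and _is_pd(Rec, 0.0)
                          and (Rlc is None or _is_pd(Rlc, 0.0)))
                    if ok:
                        cand_vc = VarianceComponents(G0c, Rlc, Rec, traits=design.traits)
                        try:
                            cand_state = eng.factorize(cand_vc)
                        except (RemlError, np.linalg.LinAlgError):
                            cand_state = None
                        if cand_state is not None and \
                                cand_state["m2ll"] <= state["m2ll"] + 1e-8:
                            vc, state = cand_vc, cand_state
                            accepted = True
                            break
                    step *= 0.5
        if not accepted:
            G0n, Rln, Ren = eng.em_update(vc, der)
            vc = VarianceComponents(G0n, Rln, Ren, traits=design.traits)
            state = eng.factorize(vc)

        new = _vech([vc.G0] + ([vc.Rl] if eng.use_litter else []) + [vc.Re])
        rel = np.max(np.abs(new - old) / (np.abs(old) + floor + 1e-12))
        d_ll = abs(trajectory[-1][1] - state["m2ll"]) if trajectory else np.inf
        trajectory.append((it, state["m2ll"], rel))
        if verbose:
            logger.info("REML iter %d: -2logL=%.6f max rel change=%.3e",
                        it, state["m2ll"], rel)
        if rel < tol:
            converged = True
            break
        # secondary criterion: likelihood numerically stationary while
        # parameters only dither (flat ridges, boundary crawls)
        if rel < 1e-4 and d_ll < 1e-9 * (1.0 + abs(state["m2ll"])):
            stall += 1
            if stall >= 5:
                converged = True
                break
        else:
            stall = 0

    if not converged:
        raise RemlError(
            f"REML did not converge in {max_iter} iterations "
            f"(last max relative change {trajectory[-1][2]:.2e})",
            trajectory,
        )

    vc.traits = design.traits
    vc.loglik = -0.5 * state["m2ll"]
    vc.converged = converged
    vc.n_iter = it
    vc.trajectory = trajectory
    # boundary diagnostics: vanishing variance or |correlation| near 1
    bound = False
    for M in [vc.G0] + ([vc.Rl] if eng.use_litter else []) + [vc.Re]:
        dg = np.diag(M)
        if (dg < 100 * floor).any():
            bound = True
        if t == 2 and dg.min() > 0:
            r = M[0, 1] / np.sqrt(dg[0] * dg[1])
            if abs(r) > 0.999:
                bound = True
    vc.boundary = bound
    if bound:
        logger.warning("REML estimates at or near the parameter boundary")
    return vc
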