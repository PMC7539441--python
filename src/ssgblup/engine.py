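"""Single-step GBLUP engine: H matrices and mixed-model equations.

The evaluation model is the bivariate animal model

    y = X b + Z1 a + Z2 l + e

with a focal trait paired with the selection index, a ~ N(0, G0 (x) H),
litter (common environment) effects l ~ N(0, Rl (x) I) and residuals
e ~ N(0, Re (x) I), where G0, Rl, Re are 2x2 covariance matrices and H is
the combined pedigree-genomic relationship matrix.  Records may carry one or
both traits of the pair; residual covariance is handled exactly per
missing-pattern block.  Henderson's mixed-model equations are assembled
sparsely and solved by dense Cholesky factorization (small and medium
systems) or Jacobi-preconditioned conjugate gradients (very large systems).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp

from .pedigree import Pedigree, RelationshipMatrix, A_inverse

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "VarianceComponents",
    "Solutions",
    "build_H_inverse",
    "build_H_dense",
    "solve_ssgblup",
    "pedigree_blup",
    "default_model",
]

DENSE_LIMIT = 20000  # MME size above which the solver switches to PCG


@dataclass
class ModelSpec:
    """Trait pair and fixed-effect structure of one bivariate analysis.

    ``traits`` is (focal trait, selection index); a single-element tuple
    gives the univariate sub-model used for closed-form checks.  Factors and
    covariates may be given per trait (dict) or shared (sequence).
    """

    traits: tuple
    factors: object = ("sex", "pen_size", "herd", "cg")
    covariates: object = field(default_factory=dict)  # e.g. {"BFT": ("BW_slaughter",)}
    litter: str | None = "litter"

    def factors_for(self, trait: str) -> tuple:
        if isinstance(self.factors, dict):
            return tuple(self.factors.get(trait, ()))
        return tuple(self.factors)

    def covariates_for(self, trait: str) -> tuple:
        if isinstance(self.covariates, dict):
            return tuple(self.covariates.get(trait, ()))
        return tuple(self.covariates)


def default_model(trait: str, index: str = "index") -> ModelSpec:
    """The study's standard bivariate model for one focal trait."""
    covs = {"BFT": ("BW_slaughter",)}
    return ModelSpec(traits=(trait, index), covariates=covs)


@dataclass
class VarianceComponents:
    """(Co)variance matrices of one (bi)variate analysis."""

    G0: np.ndarray
    Rl: np.ndarray | None
    Re: np.ndarray
    traits: tuple = ()
    loglik: float = np.nan
    converged: bool = True
    n_iter: int = 0
    boundary: bool = False
    trajectory: list = field(default_factory=list)

    def __post_init__(self):
        self.G0 = np.atleast_2d(np.asarray(self.G0, float))
        self.Re = np.atleast_2d(np.asarray(self.Re, float))
        if self.Rl is not None:
            self.Rl = np.atleast_2d(np.asarray(self.Rl, float))

    @property
    def n_traits(self) -> int:
        return self.G0.shape[0]

    def h2(self, i: int = 0) -> float:
        tot = self.G0[i, i] + self.Re[i, i] + (self.Rl[i, i] if self.Rl is not None else 0.0)
        return float(self.G0[i, i] / tot)

    def l2(self, i: int = 0) -> float:
        if self.Rl is None:
            return 0.0
        tot = self.G0[i, i] + self.Rl[i, i] + self.Re[i, i]
        return float(self.Rl[i, i] / tot)

    def to_text(self, path) -> None:
        """Small structured text dump of the component matrices."""
        lines = [f"traits: {', '.join(map(str, self.traits))}"]
        for name, M in (("genetic", self.G0), ("litter", self.Rl),
                        ("residual", self.Re)):
            if M is None:
                continue
            lines.append(f"[{name}]")
            for row in np.atleast_2d(M):
                lines.append("  " + "  ".join(f"{v:.10g}" for v in row))
        for i in range(self.n_traits):
            lines.append(f"h2[{self.traits[i] if self.traits else i}]: "
                         f"{self.h2(i):.6f}  l2: {self.l2(i):.6f}")
        lines.append(f"converged: {self.converged}  iterations: {self.n_iter}  "
                     f"boundary: {self.boundary}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# H matrices


def _chol_inverse(mat: np.ndarray, name: str) -> tuple[np.ndarray, float]:
    """Inverse and log-determinant via Cholesky; informative error if singular."""
    try:
        c, low = sla.cho_factor(mat, lower=True)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"matrix {name} is singular or not PD") from exc
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    inv = sla.cho_solve((c, low), np.eye(mat.shape[0]))
    return inv, float(logdet)


def build_H_inverse(
    A_inv: RelationshipMatrix,
    G_blend: RelationshipMatrix | None,
    A22: RelationshipMatrix | None,
) -> RelationshipMatrix:
    """H^-1 = A^-1 + [0 0; 0 G**^-1 - A22^-1] on the genotyped block.

    ``G_blend`` and ``A22`` must share ids (a subset of the A ids) in the
    same order; pass None for both to get the pedigree-only case.
    """
    if G_blend is None or A22 is None or len(getattr(G_blend, "ids", ())) == 0:
        out = RelationshipMatrix(sp.csr_matrix(A_inv.values), A_inv.ids, kind="H")
        out.meta.update(genotyped_ids=np.array([], dtype=object))
        return out
    if not np.array_equal(G_blend.ids, A22.ids):
        raise ValueError("G and A22 ids are not aligned")
    pos = np.array([A_inv._index[a] for a in G_blend.ids], dtype=np.int64)
    Ginv, _ = _chol_inverse(G_blend.dense(), "G**")
    A22inv, _ = _chol_inverse(A22.dense(), "A22")
    corr = sp.coo_matrix(Ginv - A22inv)
    n = A_inv.n
    block = sp.coo_matrix(
        (corr.data, (pos[corr.row], pos[corr.col])), shape=(n, n)
    )
    out = RelationshipMatrix(
        (sp.csr_matrix(A_inv.values) + block.tocsr()), A_inv.ids, kind="H"
    )
    out.meta.update(genotyped_ids=np.asarray(G_blend.ids))
    return out


def build_H_dense(
    A: RelationshipMatrix,
    G_blend: RelationshipMatrix | None,
    genotyped_ids=None,
) -> RelationshipMatrix:
    """Full dense H via the conditional-expectation identities.

    H22 = G**, H12 = A12 A22^-1 G**, and
    H11 = A11 + A12 A22^-1 (G** - A22) A22^-1 A21.
    """
    if G_blend is None or len(getattr(G_blend, "ids", ())) == 0:
        return RelationshipMatrix(A.dense().copy(), A.ids, kind="H")
    gids = np.asarray(genotyped_ids if genotyped_ids is not None else G_blend.ids)
    if not np.array_equal(np.asarray(G_blend.ids), gids):
        raise ValueError("G ids do not match genotyped_ids")
    pos2 = np.array([A._index[a] for a in gids], dtype=np.int64)
    pos1 = np.setdiff1d(np.arange(A.n), pos2)
    Ad = A.dense()
    A11 = Ad[np.ix_(pos1, pos1)]
    A12 = Ad[np.ix_(pos1, pos2)]
    A22 = Ad[np.ix_(pos2, pos2)]
    G = G_blend.dense()
    try:
        c, low = sla.cho_factor(A22, lower=True)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("A22 is singular") from exc
    # P = A12 A22^-1  (n1 x n2)
    P = sla.cho_solve((c, low), A12.T).T
    H = np.empty_like(Ad)
    H[np.ix_(pos2, pos2)] = G
    H12 = P @ G
    H[np.ix_(pos1, pos2)] = H12
    H[np.ix_(pos2, pos1)] = H12.T
    H[np.ix_(pos1, pos1)] = A11 + P @ (G - A22) @ P.T
    return RelationshipMatrix(H, A.ids, kind="H")


# --------------------------------------------------------------------------
# design / MME assembly


class MMEDesign:
    """Sparse design and bookkeeping for one (bi)variate mixed model."""

    def __init__(self, phenos: pd.DataFrame, model: ModelSpec, ped: Pedigree):
        self.model = model
        self.ped = ped
        self.traits = tuple(model.traits)
        t = len(self.traits)
        if t not in (1, 2):
            raise ValueError("model must have one or two traits")

        phenos = phenos.reset_index(drop=True)
        known = phenos["id"].isin(set(ped.ids))
        if not known.all():
            missing = phenos.loc[~known, "id"].head().tolist()
            raise KeyError(f"phenotyped animals missing from pedigree: {missing}")

        # fixed-effect columns per trait: intercept + drop-first dummies +
        # covariates; levels defined on the rows observed for that trait
        self.fixed_names: list[list[str]] = []
        rows_tr, cols_tr, vals_tr, y_tr, animal_tr, litter_tr = [], [], [], [], [], []
        self.n_fixed: list[int] = []
        for k, trait in enumerate(self.traits):
            needed = [trait] + list(model.covariates_for(trait))
            obs = phenos[needed].notna().all(axis=1)
            for f in model.factors_for(trait):
                obs &= phenos[f].notna()
            if model.litter:
                obs &= phenos[model.litter].notna()
            sub = phenos.loc[obs]
            if len(sub) == 0:
                raise ValueError(f"no usable records for trait {trait!r}")
            names = ["intercept"]
            cols = [np.ones(len(sub))]
            for f in model.factors_for(trait):
                levels = pd.unique(sub[f])
                if len(levels) < 2:
                    logger.info("factor %r single-level for %s; dropped", f, trait)
                    continue
                for lev in levels[1:]:
                    names.append(f"{f}={lev}")
                    cols.append((sub[f] == lev).to_numpy(float))
            for cov in model.covariates_for(trait):
                names.append(cov)
                cols.append(sub[cov].to_numpy(float))
            X = np.column_stack(cols)
            self.fixed_names.append(names)
            self.n_fixed.append(X.shape[1])
            y_tr.append(sub[trait].to_numpy(float))
            animal_tr.append(sub["id"].to_numpy(object))
            litter_tr.append(sub[model.litter].to_numpy(object) if model.litter else None)
            rows_tr.append(obs.to_numpy().nonzero()[0])
            cols_tr.append(X)

        self.litter_levels = (
            pd.unique(np.concatenate([lt for lt in litter_tr if lt is not None]))
            if model.litter else np.array([], dtype=object)
        )
        lit_index = {lv: i for i, lv in enumerate(self.litter_levels)}
        q, m = ped.n, len(self.litter_levels)
        self.q, self.m = q, m

        # parameter layout: [b_0 | b_1 | a_0 | a_1 | l_0 | l_1]
        self.off_fixed = np.r_[0, np.cumsum(self.n_fixed)]
        self.off_a = int(self.off_fixed[-1])
        self.off_l = self.off_a + t * q
        self.p = self.off_l + t * m

        # stack records trait-by-trait, then regroup into animal units
        rec_rows, rec_cols, rec_vals = [], [], []
        rec_trait, rec_animal, rec_litter, rec_y = [], [], [], []
        nrec = 0
        for k in range(t):
            X = cols_tr[k]
            n_k = X.shape[0]
            r0 = nrec
            rr, cc = np.nonzero(X)
            rec_rows.append(rr + r0)
            rec_cols.append(cc + self.off_fixed[k])
            rec_vals.append(X[rr, cc])
            apos = ped.positions(animal_tr[k])
            rec_rows.append(np.arange(n_k) + r0)
            rec_cols.append(self.off_a + k * q + apos)
            rec_vals.append(np.ones(n_k))
            if model.litter:
                lpos = np.array([lit_index[lv] for lv in litter_tr[k]], dtype=np.int64)
                rec_rows.append(np.arange(n_k) + r0)
                rec_cols.append(self.off_l + k * m + lpos)
                rec_vals.append(np.ones(n_k))
                rec_litter.append(lpos)
            rec_trait.append(np.full(n_k, k))
            rec_animal.append(apos)
            rec_y.append(y_tr[k])
            nrec += n_k
        self.N = nrec
        self.rec_litter = (np.concatenate(rec_litter)
                           if rec_litter else np.zeros(nrec, dtype=np.int64))
        self.W = sp.coo_matrix(
            (np.concatenate(rec_vals),
             (np.concatenate(rec_rows), np.concatenate(rec_cols))),
            shape=(nrec, self.p),
        ).tocsr()
        self.y = np.concatenate(rec_y)
        self.rec_trait = np.concatenate(rec_trait)
        self.rec_animal = np.concatenate(rec_animal)

        # units: group records by animal; patterns by set of observed traits
        if t == 2:
            rec_of = {}
            for r, (a, k) in enumerate(zip(self.rec_animal, self.rec_trait)):
                rec_of.setdefault(a, [None, None])[k] = r
            both, only0, only1 = [], [], []
            for a, (r0, r1) in rec_of.items():
                if r0 is not None and r1 is not None:
                    both.append((r0, r1))
                elif r0 is not None:
                    only0.append(r0)
                else:
                    only1.append(r1)
            self.units_both = np.array(both, dtype=np.int64).reshape(-1, 2)
            self.units_only = [np.array(only0, dtype=np.int64),
                               np.array(only1, dtype=np.int64)]
        else:
            self.units_both = np.empty((0, 2), dtype=np.int64)
            self.units_only = [np.arange(self.N)]

    # ---- residual structure -------------------------------------------
    def rinv_matrix(self, Re: np.ndarray) -> sp.csr_matrix:
        """Block-diagonal R^-1 over units for the current Re."""
        rows, cols, vals = [], [], []
        t = len(self.traits)
        if t == 2 and len(self.units_both):
            Rb = np.linalg.inv(Re)
            r0, r1 = self.units_both[:, 0], self.units_both[:, 1]
            for (i, j), v in np.ndenumerate(Rb):
                rows.append([r0, r1][i])
                cols.append([r0, r1][j])
                vals.append(np.full(len(r0), v))
        for k in range(t):
            only = self.units_only[k]
            if len(only):
                rows.append(only)
                cols.append(only)
                vals.append(np.full(len(only), 1.0 / Re[k, k]))
        if not rows:
            return sp.csr_matrix((self.N, self.N))
        return sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.N, self.N),
        ).tocsr()

    def logdet_R(self, Re: np.ndarray) -> float:
        t = len(self.traits)
        out = 0.0
        if t == 2 and len(self.units_both):
            out += len(self.units_both) * np.log(np.linalg.det(Re))
        for k in range(t):
            out += len(self.units_only[k]) * np.log(Re[k, k])
        return float(out)

    # ---- coefficient matrix -------------------------------------------
    def build_C(
        self,
        varcomp: VarianceComponents,
        Kinv: sp.spmatrix | np.ndarray,
    ) -> tuple[np.ndarray, np.ndarray, sp.csr_matrix]:
        """Dense MME coefficient matrix, right-hand side and R^-1."""
        t = len(self.traits)
        Rinv = self.rinv_matrix(varcomp.Re)
        C = (self.W.T @ Rinv @ self.W).toarray()
        rhs = self.W.T @ (Rinv @ self.y)
        G0inv = np.linalg.inv(varcomp.G0)
        Kd = Kinv.toarray() if sp.issparse(Kinv) else np.asarray(Kinv)
        q, m = self.q, self.m
        for i in range(t):
            for j in range(t):
                sl_i = slice(self.off_a + i * q, self.off_a + (i + 1) * q)
                sl_j = slice(self.off_a + j * q, self.off_a + (j + 1) * q)
                C[sl_i, sl_j] += G0inv[i, j] * Kd
        if self.model.litter and m:
            Rlinv = np.linalg.inv(varcomp.Rl)
            for i in range(t):
                for j in range(t):
                    sl_i = slice(self.off_l + i * m, self.off_l + (i + 1) * m)
                    sl_j = slice(self.off_l + j * m, self.off_l + (j + 1) * m)
                    idx = np.arange(m)
                    C[sl_i, sl_j][idx, idx] += Rlinv[i, j]
        return C, rhs, Rinv


@dataclass
class Solutions:
    """MME solutions: fixed effects, GEBV for every pedigree animal, litter
    effects, and solver diagnostics."""

    gebv: pd.DataFrame               # columns: id, one column per trait
    fixed: dict                      # trait -> Series (effect name -> estimate)
    litter: pd.DataFrame | None
    traits: tuple
    residual_norm: float = np.nan
    method: str = "cholesky"

    def gebv_of(self, ids, trait: str) -> np.ndarray:
        s = self.gebv.set_index("id")[trait]
        return s.loc[list(ids)].to_numpy()

    def to_tsv(self, path, labels: pd.DataFrame | None = None) -> None:
        """Long-format TSV (id, trait, gebv), optionally joined with label
        columns (line/generation/cohort) keyed by id."""
        long = self.gebv.melt(id_vars="id", var_name="trait", value_name="gebv")
        if labels is not None:
            long = long.merge(labels, on="id", how="left")
        long.to_csv(path, sep="\t", index=False)


def _solve_dense(C: np.ndarray, rhs: np.ndarray, design: MMEDesign) -> np.ndarray:
    try:
        c, low = sla.cho_factor(C, lower=True)
    except np.linalg.LinAlgError:
        # identify aliased fixed-effect columns for the error message
        fixed_block = C[: design.off_a, : design.off_a]
        d = np.diag(fixed_block).copy()
        names = [n for ns in design.fixed_names for n in ns]
        bad = [names[i] for i in np.flatnonzero(d <= 1e-12)]
        raise np.linalg.LinAlgError(
            "MME coefficient matrix singular; aliased fixed levels: "
            + (", ".join(bad) if bad else "(collinearity among fixed effects)")
        ) from None
    return sla.cho_solve((c, low), rhs)


def _solve_pcg(C: sp.spmatrix, rhs: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    from scipy.sparse.linalg import cg, LinearOperator

    d = C.diagonal()
    M = LinearOperator(C.shape, matvec=lambda x: x / d)
    sol, info = cg(C, rhs, rtol=tol, maxiter=5000, M=M)
    if info != 0:
        raise RuntimeError(f"PCG failed to converge (info={info})")
    return sol


def solve_ssgblup(
    phenos: pd.DataFrame,
    model: ModelSpec,
    varcomp: VarianceComponents,
    H_inv: RelationshipMatrix,
    ped: Pedigree | None = None,
) -> Solutions:
    """Solve the mixed-model equations with the given relationship inverse.

    ``H_inv`` may be the single-step H^-1 or a pedigree-only A^-1; its id
    set must cover all pedigree animals, and GEBV are returned for every
    animal (phenotyped or not) via pedigree propagation.
    """
    if ped is None:
        ped = Pedigree.from_records(
            (a, None, None) for a in H_inv.ids
        )  # degenerate: ids only; caller normally passes the real pedigree
    if not np.array_equal(np.asarray(H_inv.ids), ped.ids):
        raise ValueError("H^-1 id order must match pedigree order")
    design = MMEDesign(phenos, model, ped)
    C, rhs, _ = design.build_C(varcomp, H_inv.values)
    if design.p <= DENSE_LIMIT:
        sol = _solve_dense(C, rhs, design)
        method = "cholesky"
    else:
        sol = _solve_pcg(sp.csr_matrix(C), rhs)
        method = "pcg"
    resid = float(np.linalg.norm(C @ sol - rhs) / max(np.linalg.norm(rhs), 1e-300))

    t, q, m = len(design.traits), design.q, design.m
    gebv = pd.DataFrame({"id": ped.ids})
    for k, trait in enumerate(design.traits):
        gebv[trait] = sol[design.off_a + k * q: design.off_a + (k + 1) * q]
    fixed = {
        trait: pd.Series(
            sol[design.off_fixed[k]: design.off_fixed[k + 1]],
            index=design.fixed_names[k],
        )
        for k, trait in enumerate(design.traits)
    }
    litter = None
    if model.litter and m:
        litter = pd.DataFrame({"litter": design.litter_levels})
        for k, trait in enumerate(design.traits):
            litter[trait] = sol[design.off_l + k * m: design.off_l + (k + 1) * m]
    return Solutions(gebv, fixed, litter, design.traits, resid, method)


def pedigree_blup(
    phenos: pd.DataFrame,
    model: ModelSpec,
    varcomp: VarianceComponents,
    ped: Pedigree,
) -> Solutions:
    """Conventional BLUP: the same equations with the pedigree A^-1."""
    Ainv = A_inverse(ped)
    return solve_ssgblup(phenos, model, varcomp, Ainv, ped)
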