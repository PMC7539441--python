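"""Training/validation scenarios and LR-method accuracy and bias statistics.

Twelve configurations (six scenarios applied to each of two lines) probe how
composing the training set from two genetically-related divergent lines
affects genomic prediction of the last three generations (the validation
set) of a target line:

====  =======================  =========================
 id   target-line training      other-line training
====  =======================  =========================
 1    G0-G6                     none (control)
 2    G0-G6                     G4-G9
 3    G0-G6                     G7-G9
 4    G4-G6                     G4-G9
 5    G4-G6                     G7-G9
 6    G4-G6                     G9
====  =======================  =========================

Validation animals are the genotyped pigs of the last three generations of
the target line; their phenotypes never enter training.  Phenotypes and
genotypes of line-generation cells outside the training and validation sets
are removed, but the full pedigree is kept so relationships trace back to
the founders.

Accuracy and bias follow the LR (legacy "method LR") semi-parametric
approach: GEBV from each partial (scenario) run are compared with GEBV from
the whole-data run of the target line via their correlation r(GEBVp, GEBVw)
and the regression slope of GEBVw on GEBVp; differences between scenarios
are tested with the Williams t-test for dependent correlations sharing one
variable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .engine import (ModelSpec, Solutions, VarianceComponents, build_H_inverse,
                     default_model, solve_ssgblup)
from .grm import QCThresholds, build_G, qc_filter, tune_and_blend_G
from .pedigree import (Pedigree, RelationshipMatrix, A_inverse, build_A,
                       subset_A22)
from .simulate import DataBundle
from . import traits as tr

logger = logging.getLogger(__name__)

__all__ = [
    "Scenario",
    "LRResult",
    "RelationshipSummary",
    "make_scenario",
    "build_scenario_bundle",
    "prepare_phenotypes",
    "run_whole_evaluation",
    "lr_accuracy",
    "lr_bias",
    "williams_test",
    "adjusted_phenotype_accuracy",
    "relationship_summary",
    "estimate_all_varcomps",
    "evaluate_scenarios",
]

ANALYSIS_TRAITS = ("ADG", "BFT", "DFI", "FCR", "RFI")


@dataclass
class Scenario:
    """One training-set configuration for a given target line."""

    id: int
    target_line: str
    target_gens: tuple
    other_gens: tuple
    validation_gens: tuple = ("G7", "G8", "G9")

    @property
    def other_line(self) -> str:
        return "LRFI" if self.target_line == "HRFI" else "HRFI"


def make_scenario(sid: int, target_line: str, n_generations: int = 9) -> Scenario:
    """Standard scenario definitions; validation is the last 3 generations."""
    gens = [f"G{g}" for g in range(0, n_generations + 1)]
    last3 = tuple(gens[-3:])
    early = tuple(gens[: n_generations - 2])          # G0..G6
    near = tuple(gens[n_generations - 5: n_generations - 2])  # G4..G6
    late6 = tuple(gens[n_generations - 5:])           # G4..G9
    defs = {
        1: (early, ()),
        2: (early, late6),
        3: (early, last3),
        4: (near, late6),
        5: (near, last3),
        6: (near, (gens[-1],)),
    }
    if sid not in defs:
        raise ValueError(f"unknown scenario id {sid}")
    target_gens, other_gens = defs[sid]
    return Scenario(sid, target_line, target_gens, other_gens, last3)


@dataclass
class LRResult:
    trait: str
    scenario: int
    target_line: str
    r: float
    se: float
    slope: float
    n: int

    @property
    def bias(self) -> float:
        """Deviation of the regression slope of GEBVw on GEBVp from 1."""
        return self.slope - 1.0


@dataclass
class RelationshipSummary:
    scenario: int
    target_line: str
    subset: str           # "target" or "other"
    minimum: float
    mean: float
    maximum: float


# --------------------------------------------------------------------------
# phenotype preparation


def prepare_phenotypes(bundle: DataBundle) -> pd.DataFrame:
    """RFI computation, candidate standardization, and the index record.

    RFI is computed per cohort as an OLS residual (different covariate sets
    for candidates and response animals), the five analysis traits of the
    candidates are rescaled to the response-animal phenotypic SD, and the
    fixed selection index is attached for candidate records.
    """
    phen = bundle.phenotypes.copy()
    is_cand = phen["cohort"] == "candidate"
    is_resp = phen["cohort"] == "response"
    phen["RFI"] = np.nan
    if is_cand.any():
        phen.loc[is_cand, "RFI"] = tr.rfi_candidates(phen.loc[is_cand])
    if is_resp.any():
        phen.loc[is_resp, "RFI"] = tr.rfi_response(phen.loc[is_resp])
    if "index" not in phen.columns:
        idx = tr.selection_index(phen["DFI"], phen["ADG"], phen["BFT"])
        phen["index"] = np.where(is_cand, idx, np.nan)
    params = tr.estimate_standardization(phen, ANALYSIS_TRAITS)
    return tr.standardize_candidates(phen, params)


# --------------------------------------------------------------------------
# scenario construction


def _cells(meta: pd.DataFrame, line: str, gens, include_base: bool) -> pd.Series:
    m = meta["line"].eq(line) & meta["generation"].isin(gens)
    if include_base:
        m |= meta["line"].eq("base") & meta["generation"].isin(gens)
    return m


def build_scenario_bundle(
    bundle: DataBundle,
    scenario: Scenario,
    keep_validation_genotypes: bool = True,
) -> tuple[DataBundle, np.ndarray, np.ndarray]:
    """Partial-data bundle plus training / validation id lists.

    Phenotypes AND genotypes of non-contributing line-generation cells are
    removed; the pedigree stays complete.  Validation animals (genotyped,
    last three generations of the target line) lose their phenotypes but by
    default keep their genotypes.  Common-base animals count toward the
    target line.  Training ids are the genotyped animals of the training
    cells.
    """
    meta = bundle.meta
    geno_ids = set(bundle.genotypes.ids)
    in_target = _cells(meta, scenario.target_line, scenario.target_gens, True)
    in_other = _cells(meta, scenario.other_line, scenario.other_gens, False)
    training = in_target | in_other
    is_val = (meta["line"].eq(scenario.target_line)
              & meta["generation"].isin(scenario.validation_gens)
              & meta["id"].isin(geno_ids))

    train_ids = meta.loc[training, "id"]
    train_ids = train_ids[train_ids.isin(geno_ids)].to_numpy(object)
    val_ids = meta.loc[is_val, "id"].to_numpy(object)
    if training.sum() == 0 or len(train_ids) == 0:
        raise ValueError(f"scenario {scenario.id}: empty training set")

    keep_pheno = set(meta.loc[training, "id"])
    phen = bundle.phenotypes[bundle.phenotypes["id"].isin(keep_pheno)].copy()

    keep_geno = set(train_ids)
    if keep_validation_genotypes:
        keep_geno |= set(val_ids)
    geno = bundle.genotypes.subset(
        ids=[a for a in bundle.genotypes.ids if a in keep_geno])
    part = DataBundle(bundle.pedigree, meta, geno, phen)
    return part, train_ids, val_ids


def line_bundle(bundle: DataBundle, line: str) -> DataBundle:
    """Whole-data bundle of one line (plus the common base generations)."""
    meta = bundle.meta
    keep = meta["line"].isin([line, "base"])
    ids = set(meta.loc[keep, "id"])
    phen = bundle.phenotypes[bundle.phenotypes["id"].isin(ids)].copy()
    geno = bundle.genotypes.subset(
        ids=[a for a in bundle.genotypes.ids if a in ids])
    return DataBundle(bundle.pedigree, meta, geno, phen)


# --------------------------------------------------------------------------
# genomic machinery shared by whole/partial runs


def single_step_inverse(
    bundle: DataBundle,
    A: RelationshipMatrix,
    Ainv: RelationshipMatrix,
    blend_weight: float = 0.05,
) -> tuple[RelationshipMatrix, RelationshipMatrix | None]:
    """H^-1 (and the blended G) for the bundle's genotyped animals."""
    if bundle.genotypes.n_individuals == 0:
        return build_H_inverse(Ainv, None, None), None
    G = build_G(bundle.genotypes)
    A22 = subset_A22(A, bundle.genotypes.ids)
    Gb = tune_and_blend_G(G, A22, blend_weight)
    return build_H_inverse(Ainv, Gb, A22), Gb


# --------------------------------------------------------------------------
# evaluations


def run_whole_evaluation(
    bundle: DataBundle,
    model: ModelSpec,
    varcomp: VarianceComponents,
    A: RelationshipMatrix,
    Ainv: RelationshipMatrix,
    blend_weight: float = 0.05,
) -> Solutions:
    """Whole-data ssGBLUP of one line's bundle (GEBVw source)."""
    Hinv, _ = single_step_inverse(bundle, A, Ainv, blend_weight)
    return solve_ssgblup(bundle.phenotypes, model, varcomp, Hinv, bundle.pedigree)


# --------------------------------------------------------------------------
# LR statistics


def lr_accuracy(gebv_p: np.ndarray, gebv_w: np.ndarray) -> tuple[float, float]:
    """Pearson r(GEBVp, GEBVw) and its SE sqrt((1-r^2)/(n-2))."""
    gebv_p, gebv_w = np.asarray(gebv_p, float), np.asarray(gebv_w, float)
    if len(gebv_p) != len(gebv_w) or len(gebv_p) <= 2:
        raise ValueError("need paired vectors with n > 2")
    if np.std(gebv_p) == 0 or np.std(gebv_w) == 0:
        raise ValueError("undefined correlation: zero variance")
    r = float(np.corrcoef(gebv_p, gebv_w)[0, 1])
    se = float(np.sqrt((1.0 - r**2) / (len(gebv_p) - 2)))
    return r, se


def lr_bias(gebv_p: np.ndarray, gebv_w: np.ndarray) -> float:
    """Regression slope of GEBVw on GEBVp (1 = unbiased)."""
    gebv_p, gebv_w = np.asarray(gebv_p, float), np.asarray(gebv_w, float)
    v = np.var(gebv_p)
    if v == 0:
        raise ValueError("var(GEBVp) is zero")
    return float(np.cov(gebv_w, gebv_p, ddof=1)[0, 1] / np.var(gebv_p, ddof=1))


def williams_test(r12: float, r13: float, r23: float, n: int) -> tuple[float, float, int]:
    """Williams t-test for two dependent correlations sharing variable 1.

    Variable 1 is GEBVw; variables 2 and 3 are two scenarios' GEBVp.
    Returns (t, two-sided p, df = n - 3).
    """
    if n <= 3:
        raise ValueError("need n > 3")
    for r in (r12, r13, r23):
        if not -1 < r < 1:
            raise ValueError("correlations must be in (-1, 1)")
    K = 1.0 - r12**2 - r13**2 - r23**2 + 2.0 * r12 * r13 * r23
    if K <= 0:
        raise ValueError("degenerate correlation matrix (determinant <= 0)")
    rbar = 0.5 * (r12 + r13)
    denom = 2.0 * K * (n - 1) / (n - 3) + rbar**2 * (1.0 - r23) ** 3
    t = (r12 - r13) * np.sqrt((n - 1) * (1.0 + r23) / denom)
    df = n - 3
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(p), df


def adjusted_phenotype_accuracy(gebv_p: np.ndarray, y_star: np.ndarray,
                                h2: float) -> float:
    """Cross-validation criterion r(GEBVp, y*)/sqrt(h2).

    y* is the validation animals' own phenotype adjusted for fixed effects;
    only animals with their own record should enter.
    """
    if h2 <= 0:
        raise ValueError("heritability must be positive")
    r = float(np.corrcoef(np.asarray(gebv_p, float), np.asarray(y_star, float))[0, 1])
    return r / float(np.sqrt(h2))


def adjust_phenotypes(phenos: pd.DataFrame, model: ModelSpec,
                      solutions: Solutions, trait: str) -> pd.Series:
    """y* = observed phenotype minus estimated fixed effects for ``trait``."""
    fx = solutions.fixed[trait]
    obs = phenos[trait].notna()
    y = phenos.loc[obs, trait].astype(float).copy()
    y -= fx.get("intercept", 0.0)
    for f in model.factors_for(trait):
        levels = phenos.loc[obs, f]
        eff = levels.map(lambda lv: fx.get(f"{f}={lv}", 0.0)).astype(float)
        y -= eff.to_numpy()
    for cov in model.covariates_for(trait):
        y -= fx.get(cov, 0.0) * phenos.loc[obs, cov].astype(float).to_numpy()
    return pd.Series(y, index=phenos.index[obs])


def relationship_summary(
    H: RelationshipMatrix, validation_ids, subset_ids,
    scenario: int = 0, target_line: str = "", subset: str = "",
) -> RelationshipSummary:
    """Min/mean/max of H coefficients between validation and a training subset.

    Only the off-diagonal cross-block enters; any animal present in both
    sets is excluded from the subset side.
    """
    validation_ids = list(validation_ids)
    subset_ids = [a for a in subset_ids if a not in set(validation_ids)]
    if not subset_ids:
        raise ValueError("empty training subset after removing overlap")
    vi = [H._index[a] for a in validation_ids]
    si = [H._index[a] for a in subset_ids]
    block = H.dense()[np.ix_(vi, si)]
    return RelationshipSummary(scenario, target_line, subset,
                               float(block.min()), float(block.mean()),
                               float(block.max()))


# --------------------------------------------------------------------------
# variance components and the full grid


def estimate_all_varcomps(
    phenos: pd.DataFrame,
    ped: Pedigree,
    traits=ANALYSIS_TRAITS,
    **reml_kwargs,
) -> dict:
    """REML per trait pair (trait, index) on all data with the A matrix."""
    from .reml import estimate_varcomp

    out = {}
    for t in traits:
        model = default_model(t)
        out[t] = estimate_varcomp(phenos, model, ped, **reml_kwargs)
        logger.info("REML %s: h2=%.3f l2=%.3f (%d iters)",
                    t, out[t].h2(0), out[t].l2(0), out[t].n_iter)
    return out


def evaluate_scenarios(
    bundle: DataBundle,
    varcomps: dict,
    traits=ANALYSIS_TRAITS,
    scenario_ids=(1, 2, 3, 4, 5, 6),
    lines=("HRFI", "LRFI"),
    blend_weight: float = 0.05,
    keep_validation_genotypes: bool = True,
    qc_thresholds: QCThresholds | None = None,
    prepared: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """The full trait x scenario x line LR evaluation grid.

    Returns a tidy frame with one row per combination: training/validation
    sizes, LR accuracy r and its SE, slope and bias, Williams test against
    the control scenario, and H-relationship summaries between the
    validation set and the two training subsets.
    """
    phenos = prepared if prepared is not None else prepare_phenotypes(bundle)
    ped = bundle.pedigree
    geno, qc_report = qc_filter(bundle.genotypes, ped, qc_thresholds)
    clean = DataBundle(ped, bundle.meta, geno, phenos)
    A = build_A(ped)
    Ainv = A_inverse(ped)
    n_gens = max(int(g[1:]) for g in bundle.meta["generation"].unique()
                 if g.startswith("G") and g[1:].isdigit())

    rows = []
    for line in lines:
        wb = line_bundle(clean, line)
        whole_sol = {}
        for t in traits:
            model = default_model(t)
            whole_sol[t] = run_whole_evaluation(
                wb, model, varcomps[t], A, Ainv, blend_weight)

        gebv_p_store = {}
        for sid in scenario_ids:
            sc = make_scenario(sid, line, n_gens)
            part, train_ids, val_ids = build_scenario_bundle(
                clean, sc, keep_validation_genotypes)
            Hinv, Gb = single_step_inverse(part, A, Ainv, blend_weight)
            # relationship summaries between validation and training subsets
            meta_ix = bundle.meta.set_index("id")
            t_train = [a for a in train_ids
                       if meta_ix.loc[a, "line"] in (line, "base")]
            o_train = [a for a in train_ids if a not in set(t_train)]
            rel = {}
            Hd = Gb if Gb is not None else A
            for name, subset in (("target", t_train), ("other", o_train)):
                if subset and len(val_ids):
                    usable = [a for a in subset if a in Hd._index] \
                        if Gb is not None else subset
                    if usable:
                        rel[name] = relationship_summary(
                            Hd, [a for a in val_ids if a in Hd._index],
                            usable, sid, line, name)
            for t in traits:
                model = default_model(t)
                sol = solve_ssgblup(part.phenotypes, model, varcomps[t],
                                    Hinv, ped)
                gp = sol.gebv_of(val_ids, t)
                gw = whole_sol[t].gebv_of(val_ids, t)
                r, se = lr_accuracy(gp, gw)
                slope = lr_bias(gp, gw)
                gebv_p_store[(t, sid)] = gp
                row = dict(trait=t, scenario=sid, line=line,
                           n_train=len(train_ids), n_val=len(val_ids),
                           r=r, se=se, slope=slope, bias=slope - 1.0)
                for name in ("target", "other"):
                    s = rel.get(name)
                    row[f"rel_{name}_min"] = s.minimum if s else np.nan
                    row[f"rel_{name}_mean"] = s.mean if s else np.nan
                    row[f"rel_{name}_max"] = s.maximum if s else np.nan
                row["_gw"] = gw
                rows.append(row)

        # Williams tests against the control scenario (shared GEBVw)
        for row in rows:
            if row["line"] != line or row["scenario"] == 1:
                row.setdefault("williams_t", np.nan)
                row.setdefault("williams_p", np.nan)
                continue
            t, sid = row["trait"], row["scenario"]
            if (t, 1) not in gebv_p_store or (t, sid) not in gebv_p_store:
                continue
            gw = row["_gw"]
            g1, gs = gebv_p_store[(t, 1)], gebv_p_store[(t, sid)]
            r12 = float(np.corrcoef(gw, gs)[0, 1])
            r13 = float(np.corrcoef(gw, g1)[0, 1])
            r23 = float(np.corrcoef(gs, g1)[0, 1])
            try:
                wt, wp, _ = williams_test(r12, r13, r23, len(gw))
            except ValueError:
                wt, wp = np.nan, np.nan
            row["williams_t"], row["williams_p"] = wt, wp

    out = pd.DataFrame(rows).drop(columns=["_gw"])
    out.attrs["qc_report"] = qc_report
    return out
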