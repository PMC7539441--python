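"""Selection index, residual feed intake, and cohort standardization.

The selection criterion is a fixed linear index of daily feed intake (DFI,
g/day), average daily gain (ADG, g/day) and backfat thickness (BFT, mm):

    index = DFI - 1.06 * ADG - 37 * BFT

Residual feed intake (RFI) is realized as the residual of an ordinary
least-squares regression of DFI on production and maintenance traits, with a
different covariate set for selection candidates (tested over a fixed
live-weight window) and for response animals (tested from 10 weeks of age to
slaughter).  Because the two cohorts are measured over different growth
windows, candidate records are rescaled to the phenotypic standard deviation
of the response animals before joint analysis.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "INDEX_ADG_COEF",
    "INDEX_BFT_COEF",
    "selection_index",
    "rfi_candidates",
    "rfi_response",
    "estimate_standardization",
    "standardize_candidates",
]

#: fixed index weights of the selection experiment (g/day per unit of trait)
INDEX_ADG_COEF = 1.06
INDEX_BFT_COEF = 37.0


def selection_index(dfi, adg, bft):
    """Selection index DFI - 1.06*ADG - 37*BFT (all inputs on recorded scale).

    Accepts scalars or aligned arrays; missing inputs yield missing output.
    """
    return np.asarray(dfi, float) - INDEX_ADG_COEF * np.asarray(adg, float) \
        - INDEX_BFT_COEF * np.asarray(bft, float)


def _ols_residuals(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Least-squares residuals with an explicit rank check."""
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise ValueError(
            f"rank-deficient regression design: rank {rank} < {X.shape[1]} columns"
        )
    return y - X @ beta


def rfi_candidates(
    table: pd.DataFrame,
    dfi: str = "DFI",
    adg: str = "ADG",
    bft: str = "BFT",
) -> pd.Series:
    """RFI of selection candidates: OLS residual of DFI on {1, ADG, BFT}.

    Fitted within the rows given (the candidate cohort); rows with any
    missing input are returned as NaN.
    """
    ok = table[[dfi, adg, bft]].notna().all(axis=1)
    sub = table.loc[ok]
    X = np.column_stack([np.ones(len(sub)), sub[adg].to_numpy(float), sub[bft].to_numpy(float)])
    res = pd.Series(np.nan, index=table.index, name="RFI")
    res.loc[ok] = _ols_residuals(sub[dfi].to_numpy(float), X)
    return res


def rfi_response(
    table: pd.DataFrame,
    dfi: str = "DFI",
    covariates: tuple = ("AMBW", "ADG", "carcBFT", "LMC", "BW_start"),
    factors: tuple = ("sex", "pen_size", "cg"),
) -> pd.Series:
    """RFI of response animals.

    OLS residual of DFI on an intercept, the maintenance/production
    covariates (average metabolic BW, ADG over the test, carcass backfat,
    lean meat content, BW at test start) and dummy blocks for the fixed
    factors.  Factors observed at a single level are dropped with a log note;
    rank deficiency after dropping raises.
    """
    cols = [dfi, *covariates, *factors]
    ok = table[list(cols)].notna().all(axis=1)
    sub = table.loc[ok]
    blocks = [np.ones((len(sub), 1))]
    blocks += [sub[c].to_numpy(float).reshape(-1, 1) for c in covariates]
    for f in factors:
        levels = pd.unique(sub[f])
        if len(levels) < 2:
            logger.info("factor %r has a single level; dropped from RFI model", f)
            continue
        dummies = pd.get_dummies(sub[f], drop_first=True).to_numpy(float)
        blocks.append(dummies)
    X = np.hstack(blocks)
    res = pd.Series(np.nan, index=table.index, name="RFI")
    res.loc[ok] = _ols_residuals(sub[dfi].to_numpy(float), X)
    return res


def estimate_standardization(
    table: pd.DataFrame,
    traits,
    cohort_col: str = "cohort",
    candidate: str = "candidate",
    response: str = "response",
) -> pd.DataFrame:
    """Per-trait phenotypic SDs in the candidate and response cohorts.

    Returns a frame indexed by trait with columns ``sigma_s`` (candidates)
    and ``sigma_R`` (response animals).
    """
    cand = table[table[cohort_col] == candidate]
    resp = table[table[cohort_col] == response]
    rows = {}
    for t in traits:
        rows[t] = (cand[t].std(ddof=1), resp[t].std(ddof=1))
    out = pd.DataFrame.from_dict(rows, orient="index", columns=["sigma_s", "sigma_R"])
    if (out <= 0).any().any() or out.isna().any().any():
        bad = out.index[(out <= 0).any(axis=1) | out.isna().any(axis=1)].tolist()
        raise ValueError(f"non-positive or undefined cohort SD for traits {bad}")
    return out


def standardize_candidates(
    table: pd.DataFrame,
    params: pd.DataFrame,
    cohort_col: str = "cohort",
    candidate: str = "candidate",
) -> pd.DataFrame:
    """Rescale candidate records to the response-animal scale.

    Each candidate record y of trait i becomes y / sigma_si * sigma_Ri;
    response records are untouched.  Returns a copy.
    """
    out = table.copy()
    is_cand = out[cohort_col] == candidate
    for trait, row in params.iterrows():
        if row["sigma_s"] == 0:
            raise ValueError(f"sigma_s is zero for trait {trait!r}")
        out.loc[is_cand, trait] = (
            out.loc[is_cand, trait] / row["sigma_s"] * row["sigma_R"]
        )
    return out
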