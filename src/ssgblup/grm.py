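"""SNP quality control and the VanRaden genomic relationship matrix.

The QC pipeline applies, in a fixed and auditable order, the filters used in
routine pig SNP-chip analyses: sex-chromosome markers, SNP call rate,
individual call rate, Hardy-Weinberg equilibrium, minor allele frequency, and
parent-offspring opposite-homozygote incompatibility.  The genomic
relationship matrix follows VanRaden's first method,
G = ZZ' / (2 * sum p_i (1 - p_i)), with Z the dose matrix centered by twice
the observed allele frequency, and is subsequently tuned (affine adjustment of
its diagonal/off-diagonal means to those of A22) and blended with A22 for
invertibility.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .pedigree import Pedigree, RelationshipMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "QCThresholds",
    "QCReport",
    "qc_filter",
    "allele_frequencies",
    "impute_mean",
    "build_G",
    "tune_and_blend_G",
]

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs dose matrix; dose counts the second allele.

    Entries are 0/1/2 with ``-1`` for missing.  ``marker_map`` has one row
    per SNP with at least columns ``snp``, ``chrom``, ``pos`` and the boolean
    ``sex_chrom`` flag.
    """

    dose: np.ndarray
    ids: np.ndarray
    marker_map: pd.DataFrame

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=np.int8)
        self.ids = np.asarray(self.ids)
        if self.dose.ndim != 2:
            raise ValueError("dose must be 2-D (individuals x SNPs)")
        if self.dose.shape[1] != len(self.marker_map):
            raise ValueError("marker map length does not match SNP count")
        if self.dose.shape[0] != len(self.ids):
            raise ValueError("one dose row required per genotyped animal")
        if self.dose.size and (self.dose.max() > 2 or self.dose.min() < -1):
            raise ValueError("doses must be in {0,1,2} or -1 for missing")
        if "sex_chrom" not in self.marker_map.columns:
            self.marker_map = self.marker_map.assign(sex_chrom=False)

    @property
    def n_individuals(self) -> int:
        return self.dose.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dose.shape[1]

    def subset(self, ids=None, snp_mask=None) -> "GenotypeMatrix":
        dose, out_ids, mm = self.dose, self.ids, self.marker_map
        if ids is not None:
            index = {a: i for i, a in enumerate(self.ids)}
            pos = np.array([index[a] for a in ids], dtype=np.int64)
            dose = dose[pos]
            out_ids = (self.ids[pos] if len(pos)
                       else np.array([], dtype=self.ids.dtype))
        if snp_mask is not None:
            dose = dose[:, snp_mask]
            mm = mm.loc[snp_mask].reset_index(drop=True)
        return GenotypeMatrix(dose.copy(), out_ids.copy(), mm.copy())


@dataclass
class QCThresholds:
    """Default thresholds for the genotype quality-control filters."""

    snp_call_rate: float = 0.95
    ind_call_rate: float = 0.90
    hwe_pvalue: float = 1e-10
    maf: float = 0.01
    parent_offspring_conflict_rate: float = 0.01


@dataclass
class QCReport:
    """Per-rule removal record produced by :func:`qc_filter`."""

    thresholds: QCThresholds
    removed_snps: dict = field(default_factory=dict)      # rule -> list of snp ids
    removed_individuals: dict = field(default_factory=dict)  # rule -> list of ids
    n_input_snps: int = 0
    n_output_snps: int = 0
    n_input_individuals: int = 0
    n_output_individuals: int = 0
    empty_output: bool = False

    def counts(self) -> pd.DataFrame:
        rows = [("snp", rule, len(v)) for rule, v in self.removed_snps.items()]
        rows += [("individual", rule, len(v)) for rule, v in self.removed_individuals.items()]
        return pd.DataFrame(rows, columns=["unit", "rule", "n_removed"])

    def to_tsv(self, path) -> None:
        self.counts().to_csv(path, sep="\t", index=False)

    def summary(self) -> str:
        lines = [
            f"SNPs: {self.n_input_snps} in, {self.n_output_snps} out",
            f"individuals: {self.n_input_individuals} in, {self.n_output_individuals} out",
        ]
        for unit, removed in (("SNP", self.removed_snps), ("individual", self.removed_individuals)):
            for rule, items in removed.items():
                lines.append(f"  {unit} rule '{rule}': removed {len(items)}")
        if self.empty_output:
            lines.append("WARNING: quality control removed all genotypes")
        return "\n".join(lines)


def _call_rates(dose: np.ndarray, axis: int) -> np.ndarray:
    if dose.size == 0:
        return np.ones(dose.shape[1 - axis])
    return (dose != MISSING).mean(axis=axis)


def hwe_pvalues(dose: np.ndarray) -> np.ndarray:
    """Chi-square (1 df) goodness-of-fit p-values for Hardy-Weinberg.

    Computed from observed genotype counts vs expectations at the observed
    allele frequency, per SNP, over non-missing calls.
    """
    obs = np.stack([(dose == g).sum(axis=0) for g in (0, 1, 2)]).astype(float)
    n = obs.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = (obs[1] + 2 * obs[2]) / (2 * n)
        exp = np.stack([n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p**2])
        chi2 = np.where(exp > 0, (obs - exp) ** 2 / np.where(exp > 0, exp, 1), 0.0).sum(axis=0)
    pvals = stats.chi2.sf(chi2, df=1)
    # monomorphic SNPs fit HWE trivially
    pvals[(p == 0) | (p == 1) | np.isnan(p)] = 1.0
    return pvals


def qc_filter(
    geno: GenotypeMatrix,
    ped: Pedigree | None = None,
    thresholds: QCThresholds | None = None,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the SNP/individual quality-control filters in fixed order.

    Order: sex chromosomes -> SNP call rate -> individual call rate -> HWE
    (chi-square 1 df, p below threshold) -> MAF -> parent-offspring
    opposite-homozygote rate.  An empty output is flagged in the report, not
    raised.
    """
    th = thresholds or QCThresholds()
    report = QCReport(
        thresholds=th,
        n_input_snps=geno.n_snps,
        n_input_individuals=geno.n_individuals,
    )
    cur = geno

    def drop_snps(rule: str, bad: np.ndarray) -> None:
        nonlocal cur
        report.removed_snps[rule] = list(cur.marker_map["snp"][bad])
        if bad.any():
            cur = cur.subset(snp_mask=~bad)

    def drop_inds(rule: str, bad: np.ndarray) -> None:
        nonlocal cur
        report.removed_individuals[rule] = list(cur.ids[bad])
        if bad.any():
            cur = cur.subset(ids=cur.ids[~bad])

    drop_snps("sex_chromosome", cur.marker_map["sex_chrom"].to_numpy(bool))
    drop_snps("snp_call_rate", _call_rates(cur.dose, axis=0) < th.snp_call_rate)
    drop_inds("individual_call_rate", _call_rates(cur.dose, axis=1) < th.ind_call_rate)
    drop_snps("hwe", hwe_pvalues(cur.dose) < th.hwe_pvalue)

    p = np.where(
        _call_rates(cur.dose, axis=0) > 0,
        np.ma.masked_equal(cur.dose, MISSING).mean(axis=0).filled(0) / 2.0,
        0.0,
    )
    maf = np.minimum(p, 1 - p)
    drop_snps("maf", maf < th.maf)

    bad_po = np.zeros(cur.n_individuals, dtype=bool)
    if ped is not None and cur.n_snps > 0:
        index = {a: i for i, a in enumerate(cur.ids)}
        ped_index = {a: i for i, a in enumerate(ped.ids)}
        for row, animal in enumerate(cur.ids):
            k = ped_index.get(animal)
            if k is None:
                continue
            for parent_pos in (ped.sire[k], ped.dam[k]):
                if parent_pos < 0:
                    continue
                prow = index.get(ped.ids[parent_pos])
                if prow is None:
                    continue
                child, parent = cur.dose[row], cur.dose[prow]
                both = (child != MISSING) & (parent != MISSING)
                if not both.any():
                    continue
                opp = ((child == 0) & (parent == 2)) | ((child == 2) & (parent == 0))
                if opp[both].mean() > th.parent_offspring_conflict_rate:
                    bad_po[row] = True
                    break
    drop_inds("parent_offspring_incompatibility", bad_po)

    report.n_output_snps = cur.n_snps
    report.n_output_individuals = cur.n_individuals
    report.empty_output = cur.n_snps == 0 or cur.n_individuals == 0
    if report.empty_output:
        logger.warning("quality control produced an empty genotype matrix")
    return cur, report


def allele_frequencies(geno: GenotypeMatrix | np.ndarray) -> np.ndarray:
    """Second-allele frequency p_i = mean(dose_i)/2 over non-missing calls."""
    dose = geno.dose if isinstance(geno, GenotypeMatrix) else np.asarray(geno)
    observed = dose != MISSING
    counts = observed.sum(axis=0)
    if (counts == 0).any():
        bad = np.where(counts == 0)[0]
        raise ValueError(f"SNP column(s) {bad[:5].tolist()} have no observed calls")
    return (np.where(observed, dose, 0).sum(axis=0) / counts) / 2.0


def impute_mean(geno: GenotypeMatrix, p: np.ndarray | None = None) -> np.ndarray:
    """Replace missing doses with their expectation 2*p_i; returns float array."""
    if p is None:
        p = allele_frequencies(geno)
    dose = geno.dose.astype(float)
    missing = geno.dose == MISSING
    if missing.any():
        dose[missing] = np.broadcast_to(2.0 * p, dose.shape)[missing]
    return dose


def build_G(
    geno: GenotypeMatrix, p: np.ndarray | None = None
) -> RelationshipMatrix:
    """VanRaden method-1 genomic relationship matrix.

    G = ZZ' / (2 * sum p_i(1-p_i)) with Z = dose - 2p per column.  Allele
    frequencies default to the observed frequencies of the current genotyped
    set; missing doses are mean-imputed beforehand.
    """
    if p is None:
        p = allele_frequencies(geno)
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom == 0:
        raise ValueError("all SNPs are monomorphic: sum 2p(1-p) is zero")
    Z = impute_mean(geno, p) - 2.0 * p
    G = (Z @ Z.T) / denom
    return RelationshipMatrix(G, geno.ids, kind="G")


def tune_and_blend_G(
    G: RelationshipMatrix,
    A22: RelationshipMatrix,
    blend_weight: float = 0.05,
) -> RelationshipMatrix:
    """Tune G to A22's diagonal/off-diagonal means, then blend with A22.

    The affine map G* = alpha + beta*G solves
    mean(diag(G*)) = mean(diag(A22)) and mean(offdiag(G*)) = mean(offdiag(A22));
    the result is blended as G** = (1-w) G* + w A22 (default w = 0.05) so the
    combined matrix is positive definite.  alpha, beta and w are recorded in
    ``meta`` of the returned matrix.
    """
    if not np.array_equal(G.ids, A22.ids):
        raise ValueError("G and A22 must share the same ids in the same order")
    g, a = G.dense(), A22.dense()
    n = g.shape[0]
    off = ~np.eye(n, dtype=bool)
    md_g, md_a = g.diagonal().mean(), a.diagonal().mean()
    if n > 1:
        mo_g, mo_a = g[off].mean(), a[off].mean()
    else:
        mo_g = mo_a = 0.0
    if np.isclose(md_g, mo_g):
        raise ValueError("degenerate G: equal diagonal and off-diagonal means")
    beta = (md_a - mo_a) / (md_g - mo_g)
    if beta <= 0:
        raise ValueError(f"degenerate G: tuning slope beta={beta:.4f} <= 0")
    alpha = mo_a - beta * mo_g
    g_star = alpha + beta * g
    g_blend = (1.0 - blend_weight) * g_star + blend_weight * a
    out = RelationshipMatrix(g_blend, G.ids, kind="G")
    out.meta.update(alpha=alpha, beta=beta, blend_weight=blend_weight)
    return out
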