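"""Text-format readers and writers.

Supported formats: pedigree CSV (id,sire,dam plus optional label columns;
``0`` marks an unknown parent), PLINK ped/map text dialect for SNP genotypes
(alleles as A/C/G/T or 1/2, missing coded ``0 0``), tab-separated phenotype
and breeding-value tables, and a YAML configuration file mirroring
:class:`~ssgblup.simulate.SimConfig`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grm import GenotypeMatrix

__all__ = [
    "write_pedigree_csv",
    "read_pedigree_csv",
    "write_plink",
    "read_plink",
    "load_genotype_panels",
    "write_phenotypes",
    "read_phenotypes",
]


def write_pedigree_csv(frame: pd.DataFrame, path) -> None:
    """Write a pedigree table (id, sire, dam, extra label columns) as CSV."""
    out = frame.copy()
    for col in ("sire", "dam"):
        out[col] = out[col].fillna("0").replace("", "0")
    out.to_csv(path, index=False)


def read_pedigree_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype=str)
    return frame


def write_plink(geno: GenotypeMatrix, prefix: str) -> None:
    """Write genotypes in PLINK .ped/.map text format.

    Doses count the second allele (coded ``2``); missing genotypes are
    written as ``0 0``.  The .map has columns chrom, snp id, genetic
    position (cM), bp position.
    """
    m = geno.marker_map
    with open(f"{prefix}.map", "w") as fh:
        for _, row in m.iterrows():
            fh.write(f"{row['chrom']}\t{row['snp']}\t{row.get('cm', 0)}\t{row['pos']}\n")
    alleles = {0: "1 1", 1: "1 2", 2: "2 2", -1: "0 0"}
    with open(f"{prefix}.ped", "w") as fh:
        for i, animal in enumerate(geno.ids):
            doses = geno.dose[i]
            geno_str = " ".join(alleles[int(d)] for d in doses)
            fh.write(f"0 {animal} 0 0 0 -9 {geno_str}\n")


def read_plink(prefix: str) -> GenotypeMatrix:
    """Read PLINK .ped/.map text files.

    The second allele (dose-counted) is defined as the minor allele observed
    at load time; the chosen allele codes are recorded in the marker map
    columns ``a1``/``a2`` (a2 = dose-counted second allele).
    """
    mm = pd.read_csv(
        f"{prefix}.map", sep=r"\s+", header=None,
        names=["chrom", "snp", "cm", "pos"], dtype={"chrom": str, "snp": str},
    )
    n_snps = len(mm)
    ids, rows = [], []
    with open(f"{prefix}.ped") as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            ids.append(parts[1])
            al = parts[6:]
            if len(al) != 2 * n_snps:
                raise ValueError(
                    f"animal {parts[1]}: expected {2 * n_snps} alleles, got {len(al)}"
                )
            rows.append(al)
    alleles = np.array(rows, dtype="U1").reshape(len(ids), n_snps, 2)

    dose = np.full((len(ids), n_snps), -1, dtype=np.int8)
    a1_codes = np.empty(n_snps, dtype="U1")
    a2_codes = np.empty(n_snps, dtype="U1")
    for j in range(n_snps):
        col = alleles[:, j, :]
        obs = col[col != "0"]
        uniq, counts = np.unique(obs, return_counts=True)
        if len(uniq) > 2:
            raise ValueError(f"SNP {mm['snp'][j]}: more than two alleles")
        if len(uniq) == 0:
            a1_codes[j], a2_codes[j] = "0", "0"
            continue
        # second allele := minor allele; ties broken by code order
        order = np.argsort(counts, kind="stable")
        if len(uniq) == 1:
            major = minor = uniq[0]
        else:
            minor, major = uniq[order[0]], uniq[order[1]]
        a1_codes[j], a2_codes[j] = major, minor
        observed = (col[:, 0] != "0") & (col[:, 1] != "0")
        dose[observed, j] = (col[observed] == minor).sum(axis=1)
    mm = mm.assign(a1=a1_codes, a2=a2_codes, sex_chrom=False)
    return GenotypeMatrix(dose=dose, ids=np.asarray(ids, dtype=object), marker_map=mm)


def load_genotype_panels(prefixes) -> GenotypeMatrix:
    """Load genotypes from PLINK prefixes; a single panel only.

    Cross-panel imputation is outside this package's scope: merging animals
    genotyped on different SNP chips requires imputing each panel to the
    other first.
    """
    prefixes = list(prefixes)
    if len(prefixes) != 1:
        raise NotImplementedError(
            "multiple SNP panels detected: pre-impute externally to a single "
            "shared panel before loading")
    return read_plink(prefixes[0])


def write_phenotypes(table: pd.DataFrame, path) -> None:
    """Phenotype (or TBV) table as TSV, one row per animal, NA for missing."""
    table.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values="NA", dtype={"id": str, "litter": str})
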