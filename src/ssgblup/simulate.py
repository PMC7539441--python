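"""Synthetic divergent-selection study generator.

Simulates a two-line pig breeding experiment: a base population (F0) is mated
to produce G0 litters, male G0 candidates are ranked on a fixed phenotypic
feed-efficiency index (DFI - 1.06*ADG - 37*BFT), and the extreme boars found a
high-index (HRFI) and a low-index (LRFI) line.  Each line then undergoes nine
generations of within-line truncation selection of sires on the index, with
random dams, recombination-based gene dropping over an 18-autosome genome, and
additional "response" litters that carry phenotypes but play no selection
role.

Three traits (ADG g/day, BFT mm, DFI g/day) are controlled by shared QTL with
a target genetic covariance; FCR is defined as DFI/ADG (kg scale) plus noise,
and the RFI analysis trait is realized downstream as a regression residual, so
the definitional dependencies among the five analysis traits mirror the
recorded data.  Phenotypes carry contemporary-group, pen-size, herd and sex
fixed effects, a litter (common environment) random effect, and residuals
correlated across traits.

All randomness flows from a single seeded ``numpy.random.Generator``; the
same seed yields a bit-identical study.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .pedigree import Pedigree
from .grm import GenotypeMatrix
from .traits import selection_index

__all__ = [
    "SimConfig",
    "FounderPopulation",
    "SimulatedStudy",
    "DataBundle",
    "simulate_founders",
    "run_divergent_selection",
    "apply_observability_mask",
    "simulate_study",
    "write_bundle",
]

QTL_TRAITS = ("ADG", "BFT", "DFI")
TRAITS = ("ADG", "BFT", "DFI", "FCR", "RFI")


def _default_genetic_corr() -> np.ndarray:
    # order (ADG, BFT, DFI); chosen so the emergent index heritability is
    # ~0.12 at the default trait heritabilities (see docs/methods.md)
    return np.array([
        [1.00, 0.30, 0.80],
        [0.30, 1.00, 0.61],
        [0.80, 0.61, 1.00],
    ])


def _default_residual_corr() -> np.ndarray:
    return np.array([
        [1.000, 0.219, 0.497],
        [0.219, 1.000, 0.182],
        [0.497, 0.182, 1.000],
    ])


@dataclass
class SimConfig:
    """Parameters of the simulated divergent-selection experiment.

    Defaults emulate the structure of a closed experimental pig herd selected
    divergently on a residual-feed-intake index for nine generations: 6 sires
    selected out of 96 tested male candidates per line and generation, ~36
    dams per line (6 per sire), and a couple of extra response litters per
    generation carrying correlated-response phenotypes.
    """

    # genome
    n_chromosomes: int = 18
    chrom_length_morgans: float = 1.0
    n_snps: int = 5000
    n_qtl: int = 300
    founder_maf: tuple = (0.05, 0.5)

    # population structure
    n_f0_sires: int = 30
    n_f0_dams: int = 30
    n_g0_candidates: int = 116
    n_candidates_per_gen: int = 96
    n_selected_sires: int = 6
    n_dams_per_line: int = 36
    n_generations: int = 9
    response_litters_per_gen: int = 2
    response_litter_size: float = 10.0  # Poisson mean, truncated >= 1
    random_selection: bool = False      # selection differential of zero

    # trait genetics (order ADG, BFT, DFI)
    trait_names: tuple = TRAITS
    trait_means: tuple = (760.0, 27.0, 2100.0)
    phenotypic_variances: tuple = (5811.7, 14.37, 40000.0)
    heritabilities: tuple = (0.25, 0.36, 0.24)
    litter_variance_ratios: tuple = (0.10, 0.12, 0.09)
    genetic_corr: np.ndarray = field(default_factory=_default_genetic_corr)
    residual_corr: np.ndarray = field(default_factory=_default_residual_corr)
    fcr_noise_sd: float = 0.07

    # fixed-effect structure
    n_batches_per_gen: int = 4
    cg_sd_frac: float = 0.30
    pen_sd_frac: float = 0.10
    herd_sd_frac: float = 0.08
    sex_shift_frac: tuple = (0.0, -0.15, -0.05)  # male, female, castrate
    response_resid_scale: float = 1.15

    # observability
    genotyping_mask_rule: str = "default"   # or "all"
    phenotyping_mask_rule: str = "default"  # or "all"
    response_missing_rate: float = 0.05

    seed: int = 2020

    def __post_init__(self) -> None:
        self.genetic_corr = np.asarray(self.genetic_corr, float)
        self.residual_corr = np.asarray(self.residual_corr, float)
        h2 = np.asarray(self.heritabilities)
        l2 = np.asarray(self.litter_variance_ratios)
        if not ((h2 > 0) & (h2 < 1)).all() or not ((h2 + l2) < 1).all():
            raise ValueError("need 0 < h2 < 1 and h2 + l2 < 1 per trait")
        if self.n_selected_sires > self.n_candidates_per_gen:
            raise ValueError("cannot select more sires than candidates")
        for name, m in (("genetic_corr", self.genetic_corr),
                        ("residual_corr", self.residual_corr)):
            if not np.allclose(m, m.T):
                raise ValueError(f"{name} must be symmetric")
            if np.linalg.eigvalsh(m).min() < -1e-10:
                raise ValueError(f"{name} must be positive semi-definite")

    # covariance helpers -------------------------------------------------
    def _cov(self, ratios, corr) -> np.ndarray:
        sd = np.sqrt(np.asarray(ratios) * np.asarray(self.phenotypic_variances))
        return corr * np.outer(sd, sd)

    @property
    def genetic_covariance(self) -> np.ndarray:
        """3x3 additive genetic covariance of the QTL traits (ADG, BFT, DFI)."""
        return self._cov(self.heritabilities, self.genetic_corr)

    @property
    def litter_covariance(self) -> np.ndarray:
        return self._cov(self.litter_variance_ratios, self.genetic_corr)

    @property
    def residual_covariance(self) -> np.ndarray:
        e2 = 1 - np.asarray(self.heritabilities) - np.asarray(self.litter_variance_ratios)
        return self._cov(e2, self.residual_corr)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        for key in ("genetic_corr", "residual_corr"):
            data[key] = np.asarray(data[key]).tolist()
        for key, val in data.items():
            if isinstance(val, tuple):
                data[key] = list(val)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        data = yaml.safe_load(Path(path).read_text())
        for key in ("founder_maf", "trait_names", "trait_means", "phenotypic_variances",
                    "heritabilities", "litter_variance_ratios", "sex_shift_frac"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class FounderPopulation:
    ids: np.ndarray
    sex: np.ndarray               # "M"/"F"
    haplotypes: np.ndarray        # (n, 2, n_loci) int8
    loci: pd.DataFrame            # chrom, pos_morgan, is_snp, snp id
    qtl_effects: np.ndarray       # (n_qtl, 3) allele substitution effects
    config: SimConfig

    @property
    def qtl_idx(self) -> np.ndarray:
        return np.flatnonzero(~self.loci["is_snp"].to_numpy())

    def tbv_qtl(self, haplotypes=None) -> np.ndarray:
        hap = self.haplotypes if haplotypes is None else haplotypes
        dose = hap[:, 0, :][:, self.qtl_idx] + hap[:, 1, :][:, self.qtl_idx]
        return dose.astype(float) @ self.qtl_effects


@dataclass
class SimulatedStudy:
    pedigree: Pedigree
    meta: pd.DataFrame            # id, sire, dam, line, generation, cohort, sex, litter
    genotypes: GenotypeMatrix     # SNP doses, all simulated animals
    tbv: pd.DataFrame             # id + five analysis traits
    phenotypes: pd.DataFrame
    config: SimConfig

    def line_of(self, animal) -> str:
        return self.meta.set_index("id").loc[animal, "line"]

    def generation_of(self, animal) -> str:
        return self.meta.set_index("id").loc[animal, "generation"]

    def cohort_of(self, animal) -> str:
        return self.meta.set_index("id").loc[animal, "cohort"]


@dataclass
class DataBundle:
    """What the evaluation pipeline gets to see: no true breeding values."""

    pedigree: Pedigree
    meta: pd.DataFrame
    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame


# --------------------------------------------------------------------------
# genome and founders


def _make_loci(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """SNPs equally spaced per chromosome; QTL at random non-SNP positions."""
    per_chrom_snps = np.full(config.n_chromosomes, config.n_snps // config.n_chromosomes)
    per_chrom_snps[: config.n_snps % config.n_chromosomes] += 1
    per_chrom_qtl = np.full(config.n_chromosomes, config.n_qtl // config.n_chromosomes)
    per_chrom_qtl[: config.n_qtl % config.n_chromosomes] += 1
    frames = []
    for c in range(config.n_chromosomes):
        L = config.chrom_length_morgans
        n_s, n_q = per_chrom_snps[c], per_chrom_qtl[c]
        snp_pos = (np.arange(n_s) + 0.5) * L / max(n_s, 1)
        qtl_pos = rng.uniform(0, L, size=n_q)
        pos = np.concatenate([snp_pos, qtl_pos])
        is_snp = np.r_[np.ones(n_s, bool), np.zeros(n_q, bool)]
        order = np.argsort(pos, kind="stable")
        frames.append(pd.DataFrame({
            "chrom": c + 1, "pos_morgan": pos[order], "is_snp": is_snp[order],
        }))
    loci = pd.concat(frames, ignore_index=True)
    snp_counter = loci["is_snp"].cumsum()
    loci["snp"] = np.where(
        loci["is_snp"], "snp" + snp_counter.astype(str).str.zfill(5), ""
    )
    return loci


def simulate_founders(
    config: SimConfig, rng: np.random.Generator | None = None
) -> FounderPopulation:
    """Unrelated base animals with linkage-equilibrium haplotypes.

    QTL allele-substitution effects are drawn from a multivariate normal with
    the target genetic covariance and rescaled per trait so the realized base
    additive variance matches h2 * phenotypic variance exactly.
    """
    rng = rng or np.random.default_rng(config.seed)
    loci = _make_loci(config, rng)
    n_loci = len(loci)
    n = config.n_f0_sires + config.n_f0_dams
    lo, hi = config.founder_maf
    p = rng.uniform(lo, hi, size=n_loci)
    flip = rng.random(n_loci) < 0.5
    p = np.where(flip, 1.0 - p, p)
    haplotypes = (rng.random((n, 2, n_loci)) < p).astype(np.int8)
    sex = np.array(["M"] * config.n_f0_sires + ["F"] * config.n_f0_dams)
    ids = np.array(
        [f"F0S{i+1:03d}" for i in range(config.n_f0_sires)]
        + [f"F0D{i+1:03d}" for i in range(config.n_f0_dams)], dtype=object
    )

    n_qtl = int((~loci["is_snp"]).sum())
    if n_qtl:
        cov = config.genetic_covariance
        if np.linalg.eigvalsh(cov).min() < -1e-8:
            raise ValueError("genetic covariance is not positive semi-definite")
        effects = rng.multivariate_normal(
            np.zeros(3), cov / n_qtl, size=n_qtl, method="cholesky"
        )
        founders = FounderPopulation(ids, sex, haplotypes, loci, effects, config)
        # rescale effects so the realized base genic variance
        # sum_q 2 p_q (1-p_q) alpha_q^2 matches h2 * phenotypic variance:
        # the pedigree model's base variance and the Mendelian-sampling
        # variance of descendants both reference the genic variance
        qidx = founders.qtl_idx
        p_real = (haplotypes[:, 0, :][:, qidx] + haplotypes[:, 1, :][:, qidx]
                  ).mean(axis=0) / 2.0
        het = 2.0 * p_real * (1.0 - p_real)
        target = (np.asarray(config.heritabilities)
                  * np.asarray(config.phenotypic_variances))
        genic = het @ (effects**2)
        if (genic == 0).any():
            raise ValueError("degenerate QTL genotypes: zero base additive variance")
        founders.qtl_effects = effects * np.sqrt(target / genic)
        return founders
    return FounderPopulation(ids, sex, haplotypes, loci,
                             np.zeros((0, 3)), config)


# --------------------------------------------------------------------------
# meiosis and breeding


def _gamete(hap: np.ndarray, loci_pos: np.ndarray,
            chrom_starts: np.ndarray, L: float, rng: np.random.Generator) -> np.ndarray:
    """One recombinant gamete: Poisson(L) crossovers, uniform positions."""
    out = np.empty(hap.shape[1], dtype=np.int8)
    n_chrom = len(chrom_starts) - 1
    start_phase = rng.integers(0, 2, size=n_chrom)
    n_cross = rng.poisson(L, size=n_chrom)
    for c in range(n_chrom):
        lo, hi = chrom_starts[c], chrom_starts[c + 1]
        pos = loci_pos[lo:hi]
        if n_cross[c] == 0:
            out[lo:hi] = hap[start_phase[c], lo:hi]
            continue
        xpos = np.sort(rng.uniform(0, L, size=n_cross[c]))
        phase = (start_phase[c] + np.searchsorted(xpos, pos)) % 2
        seg = np.where(phase == 0, hap[0, lo:hi], hap[1, lo:hi])
        out[lo:hi] = seg
    return out


class _Sim:
    """Internal growing population state during breeding."""

    def __init__(self, founders: FounderPopulation, rng: np.random.Generator):
        self.f = founders
        self.cfg = founders.config
        self.rng = rng
        self.loci_pos = founders.loci["pos_morgan"].to_numpy()
        chrom = founders.loci["chrom"].to_numpy()
        self.chrom_starts = np.r_[0, np.flatnonzero(np.diff(chrom)) + 1, len(chrom)]
        self.haps = [founders.haplotypes[i] for i in range(len(founders.ids))]
        self.rows = []  # meta rows
        self.index = {}
        for i, a in enumerate(founders.ids):
            self.rows.append(dict(id=a, sire="0", dam="0", line="base",
                                  generation="F0", cohort="founder",
                                  sex=founders.sex[i], litter=""))
            self.index[a] = i
        self.counter = 0

    def add(self, sire, dam, line, generation, cohort, sex, litter) -> str:
        self.counter += 1
        animal = f"A{self.counter:05d}"
        hs = self.haps[self.index[sire]]
        hd = self.haps[self.index[dam]]
        g1 = _gamete(hs, self.loci_pos, self.chrom_starts,
                     self.cfg.chrom_length_morgans, self.rng)
        g2 = _gamete(hd, self.loci_pos, self.chrom_starts,
                     self.cfg.chrom_length_morgans, self.rng)
        self.index[animal] = len(self.haps)
        self.haps.append(np.stack([g1, g2]))
        self.rows.append(dict(id=animal, sire=sire, dam=dam, line=line,
                              generation=generation, cohort=cohort,
                              sex=sex, litter=litter))
        return animal

    def meta_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def hap_array(self) -> np.ndarray:
        return np.stack(self.haps)


def _index_phenotype(sim: _Sim, animals, c_idx: np.ndarray,
                     sigma_env_idx: float) -> np.ndarray:
    """Phenotypic selection index = index TBV + environmental noise.

    Used only to rank candidates during breeding; full phenotype tables with
    fixed effects are generated afterwards.  The environmental SD matches the
    index's non-genetic phenotypic variation so realized selection intensity
    is consistent with index heritability.
    """
    rows = [sim.index[a] for a in animals]
    hap = np.stack([sim.haps[r] for r in rows])
    tbv_idx = sim.f.tbv_qtl(hap) @ c_idx
    return tbv_idx + sim.rng.normal(0.0, sigma_env_idx, size=len(rows))


def run_divergent_selection(
    founders: FounderPopulation, config: SimConfig | None = None,
    rng: np.random.Generator | None = None,
) -> SimulatedStudy:
    """Breed two divergently selected lines from the founder population."""
    config = config or founders.config
    rng = rng or np.random.default_rng(config.seed + 1)
    sim = _Sim(founders, rng)
    cfg = config

    c_idx = np.array([-1.06, -37.0, 1.0])  # (ADG, BFT, DFI) index weights
    # full phenotypic covariance implied by the three variance components
    G = cfg.genetic_covariance
    Pfull = G + cfg.litter_covariance + cfg.residual_covariance
    var_idx_pheno = c_idx @ Pfull @ c_idx
    var_idx_gen = c_idx @ G @ c_idx
    sigma_env_idx = float(np.sqrt(max(var_idx_pheno - var_idx_gen, 1e-12)))

    # ---- G0: base litters from F0 matings -------------------------------
    f0_sires = [a for a in founders.ids if a.startswith("F0S")]
    f0_dams = [a for a in founders.ids if a.startswith("F0D")]
    litters0 = []
    for k, dam in enumerate(f0_dams):
        sire = f0_sires[k % len(f0_sires)]
        litters0.append((sire, dam, f"L_G0_{k+1:03d}"))
    # male candidates spread round-robin over the base litters
    g0_candidates = []
    for j in range(cfg.n_g0_candidates):
        sire, dam, lit = litters0[j % len(litters0)]
        g0_candidates.append(sim.add(sire, dam, "base", "G0", "candidate", "M", lit))
    # female pool for the two lines' first dams
    g0_females = []
    for j in range(2 * cfg.n_dams_per_line):
        sire, dam, lit = litters0[j % len(litters0)]
        g0_females.append(sim.add(sire, dam, "base", "G0", "dam", "F", lit))

    if len(g0_candidates) < 2 * cfg.n_selected_sires:
        raise RuntimeError(
            f"only {len(g0_candidates)} male candidates for "
            f"2 x {cfg.n_selected_sires} founding sires")
    score = _index_phenotype(sim, g0_candidates, c_idx, sigma_env_idx)
    order = np.argsort(score)
    if cfg.random_selection:
        order = rng.permutation(len(g0_candidates))
    low = [g0_candidates[i] for i in order[: cfg.n_selected_sires]]
    high = [g0_candidates[i] for i in order[-cfg.n_selected_sires:]]
    females = rng.permutation(np.array(g0_females, dtype=object))
    line_state = {
        "HRFI": {"sires": high, "dams": list(females[: cfg.n_dams_per_line])},
        "LRFI": {"sires": low, "dams": list(females[cfg.n_dams_per_line:])},
    }
    selected_sires = set(low) | set(high)

    # ---- G1..G9 ---------------------------------------------------------
    for g in range(1, cfg.n_generations + 1):
        gen = f"G{g}"
        for line in ("HRFI", "LRFI"):
            st = line_state[line]
            sires, dams = st["sires"], st["dams"]
            # assign dams to sires avoiding full-sib matings where possible
            meta = {r["id"]: r for r in sim.rows}
            dams_sh = list(rng.permutation(np.array(dams, dtype=object)))
            per_sire = len(dams_sh) // len(sires)
            assignment = []
            for si, sire in enumerate(sires):
                chunk = dams_sh[si * per_sire: (si + 1) * per_sire]
                for dj, dam in enumerate(chunk):
                    ms, md = meta[sire], meta[dam]
                    if ms["sire"] == md["sire"] and ms["dam"] == md["dam"] \
                            and ms["sire"] != "0":
                        # swap with a dam of another sire if it breaks the tie
                        other = dams_sh[(si * per_sire + dj + per_sire) % len(dams_sh)]
                        chunk[dj] = other
                        dam = other
                    assignment.append((sire, dam))
            # leftover dams (if not divisible) go to the last sire
            for dam in dams_sh[len(sires) * per_sire:]:
                assignment.append((sires[-1], dam))

            # candidate litters: round-robin males + one future dam per litter
            n_litters = len(assignment)
            new_candidates, new_dams = [], []
            for j in range(cfg.n_candidates_per_gen):
                sire, dam = assignment[j % n_litters]
                lit = f"L_{gen}_{line[0]}{j % n_litters + 1:03d}"
                new_candidates.append(
                    sim.add(sire, dam, line, gen, "candidate", "M", lit))
            for k, (sire, dam) in enumerate(assignment):
                lit = f"L_{gen}_{line[0]}{k+1:03d}"
                new_dams.append(sim.add(sire, dam, line, gen, "dam", "F", lit))

            # response litters: extra parities, both sexes, no selection role
            resp_pairs = [assignment[i] for i in
                          rng.choice(n_litters, size=cfg.response_litters_per_gen,
                                     replace=False)]
            for k, (sire, dam) in enumerate(resp_pairs):
                lit = f"L_{gen}_{line[0]}R{k+1:02d}"
                size = max(1, int(rng.poisson(cfg.response_litter_size)))
                for _ in range(size):
                    sex = "F" if rng.random() < 0.5 else "C"
                    sim.add(sire, dam, line, gen, "response", sex, lit)

            # select sires for the next generation within line
            if len(new_candidates) < cfg.n_selected_sires:
                raise RuntimeError(
                    f"{line} {gen}: only {len(new_candidates)} male candidates "
                    f"for {cfg.n_selected_sires} sire slots")
            score = _index_phenotype(sim, new_candidates, c_idx, sigma_env_idx)
            order = np.argsort(score)
            if cfg.random_selection:
                order = rng.permutation(len(new_candidates))
            if line == "HRFI":
                chosen = [new_candidates[i] for i in order[-cfg.n_selected_sires:]]
            else:
                chosen = [new_candidates[i] for i in order[: cfg.n_selected_sires]]
            selected_sires |= set(chosen)
            st["sires"], st["dams"] = chosen, new_dams

    meta = sim.meta_frame()
    meta["selected_sire"] = meta["id"].isin(selected_sires)
    hap = sim.hap_array()

    # SNP panel genotypes for every simulated animal
    snp_idx = np.flatnonzero(founders.loci["is_snp"].to_numpy())
    dose = (hap[:, 0, :][:, snp_idx] + hap[:, 1, :][:, snp_idx]).astype(np.int8)
    mm = founders.loci.loc[founders.loci["is_snp"]].reset_index(drop=True)
    marker_map = pd.DataFrame({
        "snp": mm["snp"], "chrom": mm["chrom"],
        "pos": (mm["pos_morgan"] * 1e6).round().astype(int),
        "cm": mm["pos_morgan"] * 100.0, "sex_chrom": False,
    })
    genotypes = GenotypeMatrix(dose, meta["id"].to_numpy(object), marker_map)

    # five-trait true breeding values
    tbv3 = founders.tbv_qtl(hap)
    mu = np.asarray(cfg.trait_means)
    adg_kg, dfi_kg = mu[0] / 1000.0, mu[2] / 1000.0
    fcr_mean = dfi_kg / adg_kg
    tbv_fcr = (tbv3[:, 2] / 1000.0 - fcr_mean * tbv3[:, 0] / 1000.0) / adg_kg
    tbv_rfi = tbv3 @ c_idx
    tbv = pd.DataFrame({
        "id": meta["id"], "ADG": tbv3[:, 0], "BFT": tbv3[:, 1], "DFI": tbv3[:, 2],
        "FCR": tbv_fcr, "RFI": tbv_rfi,
    })

    phenotypes = _generate_phenotypes(cfg, meta, tbv3, rng)

    pedigree = Pedigree.from_frame(meta[["id", "sire", "dam"]])
    return SimulatedStudy(pedigree, meta, genotypes, tbv, phenotypes, cfg)


# --------------------------------------------------------------------------
# phenotypes


def _generate_phenotypes(cfg: SimConfig, meta: pd.DataFrame, tbv3: np.ndarray,
                         rng: np.random.Generator) -> pd.DataFrame:
    """Trait records for candidate and response animals.

    Breeding females (cohort "dam") and founders are unphenotyped, mirroring
    a design where only tested candidates and response batches are measured.
    """
    sdP = np.sqrt(np.asarray(cfg.phenotypic_variances))
    mu = np.asarray(cfg.trait_means)
    measured = meta["cohort"].isin(["candidate", "response"]).to_numpy()
    sub = meta.loc[measured].reset_index(drop=True)
    n = len(sub)

    # contemporary groups: generation x line x batch
    batch = rng.integers(0, cfg.n_batches_per_gen, size=n)
    cg = (sub["generation"].astype(str) + "_" + sub["line"].astype(str)
          + "_b" + pd.Series(batch).astype(str))
    cg_levels = pd.unique(cg)
    cg_eff = {lev: rng.normal(0.0, cfg.cg_sd_frac * sdP) for lev in cg_levels}
    pen_levels = np.array([8, 9, 10, 11, 12])
    pen = pen_levels[rng.integers(0, 5, size=n)]
    pen_eff = {lev: rng.normal(0.0, cfg.pen_sd_frac * sdP) for lev in pen_levels}
    herd = rng.integers(1, 3, size=n)
    herd_eff = {1: np.zeros(3), 2: cfg.herd_sd_frac * sdP}
    sex_map = {"M": 0, "F": 1, "C": 2}
    sex_eff = np.array([np.asarray(cfg.sex_shift_frac)[sex_map[s]] * sdP
                        for s in sub["sex"]])

    # litter effects shared by littermates
    Llit = np.linalg.cholesky(cfg.litter_covariance + 1e-9 * np.eye(3))
    lit_levels = pd.unique(sub["litter"])
    lit_eff = {lev: Llit @ rng.standard_normal(3) for lev in lit_levels}

    Lres = np.linalg.cholesky(cfg.residual_covariance + 1e-9 * np.eye(3))
    resid = rng.standard_normal((n, 3)) @ Lres.T
    is_resp = (sub["cohort"] == "response").to_numpy()
    resid[is_resp] *= cfg.response_resid_scale

    fixed = (np.stack([cg_eff[c] for c in cg])
             + np.stack([pen_eff[p] for p in pen])
             + np.stack([herd_eff[h] for h in herd])
             + sex_eff)
    tbv_measured = tbv3[measured.nonzero()[0]]
    lit_mat = np.stack([lit_eff[l] for l in sub["litter"]])
    y3 = mu + fixed + tbv_measured + lit_mat + resid

    out = pd.DataFrame({
        "id": sub["id"], "line": sub["line"], "generation": sub["generation"],
        "cohort": sub["cohort"], "sex": sub["sex"], "litter": sub["litter"],
        "cg": cg.to_numpy(), "pen_size": pen, "herd": herd,
        "ADG": y3[:, 0], "BFT": y3[:, 1], "DFI": y3[:, 2],
    })

    # covariates
    bw_sl = rng.normal(105.0, 5.0, size=n)
    out["BW_slaughter"] = bw_sl
    out["BFT"] = out["BFT"] + 0.12 * (bw_sl - 105.0)

    ambw = rng.normal(30.0, 1.5, size=n)
    bw_start = rng.normal(25.0, 3.0, size=n)
    lmc = 60.0 - 0.9 * (y3[:, 1] - mu[1]) + rng.normal(0.0, 1.5, size=n)
    carc_bft = y3[:, 1] + rng.normal(0.0, 0.8, size=n)
    out["AMBW"] = np.where(is_resp, ambw, np.nan)
    out["BW_start"] = np.where(is_resp, bw_start, np.nan)
    out["LMC"] = np.where(is_resp, lmc, np.nan)
    out["carcBFT"] = np.where(is_resp, carc_bft, np.nan)
    # response DFI includes maintenance/production dependencies that the
    # response-cohort RFI regression is meant to remove
    out.loc[is_resp, "DFI"] = (out.loc[is_resp, "DFI"]
                               + 35.0 * (ambw[is_resp] - 30.0)
                               + 8.0 * (bw_start[is_resp] - 25.0)
                               - 3.0 * (lmc[is_resp] - 60.0))
    # response animals report carcass backfat as their BFT record
    out.loc[is_resp, "BFT"] = out.loc[is_resp, "carcBFT"]

    # feed conversion ratio: definitional, kg feed per kg gain, plus noise
    out["FCR"] = (out["DFI"] / 1000.0) / (out["ADG"] / 1000.0) \
        + rng.normal(0.0, cfg.fcr_noise_sd, size=n)

    # selection index record (candidates only; the selection criterion)
    is_cand = (sub["cohort"] == "candidate").to_numpy()
    idx = selection_index(out["DFI"], out["ADG"], out["BFT"])
    out["index"] = np.where(is_cand, idx, np.nan)
    return out


# --------------------------------------------------------------------------
# observability mask


def apply_observability_mask(
    study: SimulatedStudy, config: SimConfig | None = None,
    rng: np.random.Generator | None = None,
) -> DataBundle:
    """Restrict genotypes and phenotypes to what the study design observes.

    Default genotyping rule: breeding animals (selected sires and dams) of
    all generations, response animals of G6-G8, and every G9 candidate.
    Default phenotyping rule: candidates and response animals keep records,
    with a small per-trait missing fraction among response animals; breeding
    females stay genotype-only.  ``"all"`` rules return everything (minus
    true breeding values).
    """
    cfg = config or study.config
    rng = rng or np.random.default_rng(cfg.seed + 2)
    meta = study.meta

    if cfg.genotyping_mask_rule == "all":
        geno = study.genotypes
    elif cfg.genotyping_mask_rule == "none":
        geno = study.genotypes.subset(ids=np.array([], dtype=object))
    else:
        late = {f"G{g}" for g in range(6, cfg.n_generations)}  # G6..G8
        keep = (
            meta["selected_sire"].to_numpy()
            | (meta["cohort"] == "dam").to_numpy()
            | ((meta["cohort"] == "response")
               & meta["generation"].isin(late)).to_numpy()
            | ((meta["cohort"] == "candidate")
               & (meta["generation"] == f"G{cfg.n_generations}")).to_numpy()
        )
        geno = study.genotypes.subset(ids=meta.loc[keep, "id"].to_numpy(object))

    phen = study.phenotypes.copy()
    if cfg.phenotyping_mask_rule != "all" and cfg.response_missing_rate > 0:
        is_resp = (phen["cohort"] == "response").to_numpy()
        for t in ("ADG", "BFT", "DFI", "FCR"):
            miss = is_resp & (rng.random(len(phen)) < cfg.response_missing_rate)
            phen.loc[miss, t] = np.nan

    return DataBundle(study.pedigree, meta.copy(), geno, phen)


def simulate_study(config: SimConfig | None = None, seed: int | None = None
                   ) -> tuple[SimulatedStudy, DataBundle]:
    """Convenience wrapper: founders -> selection -> observability mask."""
    config = config or SimConfig()
    if seed is not None:
        from dataclasses import replace
        config = replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)
    founders = simulate_founders(config, rng)
    study = run_divergent_selection(founders, config, rng)
    bundle = apply_observability_mask(study, config, rng)
    return study, bundle


def true_variance_components(config: SimConfig) -> dict:
    """Generator-implied (trait, index) covariance components per analysis trait.

    Each analysis trait is a linear (or linearized) combination of the three
    QTL traits, so its 2x2 covariance matrices with the selection index
    follow from the configured 3x3 components.  FCR uses a first-order
    (delta-method) linearization of DFI/ADG and carries its definitional
    noise in the residual; RFI uses the population OLS projection of DFI on
    {ADG, BFT}, which is what the residual-computation step estimates.
    These are reference values for simulation studies; the analysis pipeline
    normally estimates components by REML.
    """
    from .engine import VarianceComponents

    G = config.genetic_covariance
    Lc = config.litter_covariance
    R = config.residual_covariance
    P = G + Lc + R
    c = np.array([-1.06, -37.0, 1.0])  # index weights on (ADG, BFT, DFI)

    mu = np.asarray(config.trait_means)
    adg_kg, dfi_kg = mu[0] / 1000.0, mu[2] / 1000.0
    fcr_mean = dfi_kg / adg_kg
    f = np.array([-fcr_mean / (1000.0 * adg_kg), 0.0, 1.0 / (1000.0 * adg_kg)])

    # population OLS of DFI on (ADG, BFT): the RFI projection
    S = P[np.ix_([0, 1], [0, 1])]
    b = np.linalg.solve(S, P[[0, 1], 2])
    r = np.array([-b[0], -b[1], 1.0])

    vectors = {"ADG": np.array([1.0, 0, 0]), "BFT": np.array([0, 1.0, 0]),
               "DFI": np.array([0, 0, 1.0]), "FCR": f, "RFI": r}
    out = {}
    for trait, v in vectors.items():
        M = np.stack([v, c])
        G0 = M @ G @ M.T
        Rl = M @ Lc @ M.T
        Re = M @ R @ M.T
        if trait == "FCR":
            Re = Re + np.diag([config.fcr_noise_sd**2, 0.0])
        out[trait] = VarianceComponents(G0, Rl, Re, traits=(trait, "index"))
    return out


def write_bundle(bundle: DataBundle, outdir, tbv: pd.DataFrame | None = None) -> None:
    """Write a bundle as plain-text files (pedigree CSV, PLINK ped/map,
    phenotype TSV); true breeding values, if given, go to a separate TSV."""
    from . import io as sio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ped = bundle.meta[["id", "sire", "dam", "line", "generation", "cohort"]]
    sio.write_pedigree_csv(ped, outdir / "pedigree.csv")
    sio.write_plink(bundle.genotypes, str(outdir / "genotypes"))
    sio.write_phenotypes(bundle.phenotypes, outdir / "phenotypes.tsv")
    if tbv is not None:
        sio.write_phenotypes(tbv, outdir / "tbv.tsv")
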