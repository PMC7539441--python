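# Methods

## The problem and the model

The package studies genomic prediction when the training set mixes animals
from two small, genetically-related lines bred by divergent selection from a
common base. Every evaluation is a bivariate animal model in which a focal
production trait is paired with the selection criterion (a fixed
feed-efficiency index), so that the analysis is conditioned on the
information selection acted on:

    y = X b + Z1 a + Z2 l + e
    a ~ N(0, G0 ⊗ K),   l ~ N(0, Rl ⊗ I),   e ~ N(0, Re ⊗ I)

`G0`, `Rl`, `Re` are 2×2 covariance matrices of additive-genetic, litter
(common-environment) and residual effects; `K` is either the pedigree
numerator relationship matrix `A` (for variance-component estimation) or the
single-step matrix `H` (for genomic prediction). Records may carry one or
both traits of the pair; the residual covariance is handled exactly per
missing-pattern block, never by imputation of phenotypes.

The selection index is the fixed linear combination
`index = DFI − 1.06·ADG − 37·BFT` (DFI and ADG in g/day, BFT in mm), the
criterion of the emulated selection experiment. Residual feed intake (RFI)
as an analysis trait is the OLS residual of DFI on production/maintenance
covariates, computed separately for selection candidates (intercept, ADG,
BFT) and response animals (intercept, AMBW, ADG, carcass BFT, lean meat
content, BW at test start, plus sex/pen-size/contemporary-group factors).
Because the two cohorts are measured over different growth windows,
candidate records of each trait are rescaled by `σ_R/σ_s` — the ratio of
the response-cohort to candidate-cohort phenotypic SD — before joint
analysis.

## Relationship matrices

* `A` — tabular method, `a(i,j) = ½(a(j,s_i) + a(j,d_i))`,
  `a(i,i) = 1 + ½ a(s_i,d_i)`; unknown parents are unrelated, non-inbred
  base animals (no genetic groups).
* Inbreeding — Meuwissen–Luo ancestor-walk algorithm; used both on its own
  and inside `A⁻¹`.
* `A⁻¹` — Henderson's rules with inbreeding: Mendelian-sampling variance
  `d_i = ½ − ¼(F_s + F_d)` (¾ − ¼F with one known parent, 1 for founders).
  `log|A| = Σ log d_i` feeds the REML likelihood.
* `G` — VanRaden method 1, `G = ZZ′ / (2Σ p_i(1−p_i))` with `Z` the dose
  matrix centered by twice the observed allele frequency of the current
  genotyped set; missing doses (none in simulated data) are mean-imputed.
* Compatibility — `G* = α + βG` with `α, β` solving for equal mean diagonal
  and mean off-diagonal with `A22`, then `G** = 0.95·G* + 0.05·A22`
  (blend weight configurable). The tuning makes G and A22 refer to the same
  base; the blend guarantees positive definiteness.
* `H⁻¹ = A⁻¹ + [0 0; 0 G**⁻¹ − A22⁻¹]`; the dense `H` (used for
  relationship summaries and as a test oracle) follows the
  conditional-expectation identities `H22 = G**`, `H12 = A12 A22⁻¹ G**`,
  `H11 = A11 + A12 A22⁻¹ (G** − A22) A22⁻¹ A21`.

## Genotype quality control

Filters run in a fixed, auditable order with the removal counts per rule
recorded in a report: sex-chromosome SNPs → SNP call rate < 0.95 →
individual call rate < 0.90 → Hardy–Weinberg χ² (1 df) p < 1e-10 → MAF <
0.01 → individuals whose opposite-homozygote rate with a genotyped parent
exceeds 1 % (the rate threshold tolerates isolated genotyping errors; the
paper-family criterion names only the conflict itself). The HWE test pools
all genotyped animals. An empty post-QC matrix is flagged, not raised.

## REML

Variance components are estimated once per trait pair on all data with the
pedigree `A` only, then reused across scenarios. The maximizer takes two
expectation-maximization (EM) steps and then average-information (AI)
steps: each iteration factorizes the mixed-model equations (dense Cholesky),
computes the exact score from MME identities
(`Z′PZ = Gu⁻¹ − Gu⁻¹C^{uu}Gu⁻¹`, per-unit `W_i C⁻¹ W_i′` blocks for the
residual terms) and the AI matrix `½ f_j′ P f_k`, and applies a Newton step
with step-halving; proposals outside the parameter space are projected onto
the PSD cone (eigenvalue clamp at a floor of 1e-8 of the phenotypic
variance), and a step that would decrease the restricted likelihood falls
back to a plain EM update (which, for the residual with missing traits,
uses the conditional-expectation augmentation
`E[e_m|y] = Re_mo Re_oo⁻¹ ê_o`). Convergence: maximum relative parameter
change < 1e-8, capped at 200 iterations; a secondary stop accepts the fit
when the likelihood is numerically stationary (relative change < 1e-9 for
five iterations) while parameters only dither below 1e-4 — this covers
boundary-pinned components, which EM otherwise approaches geometrically
forever. Estimates at the boundary (vanishing variance, |correlation| >
0.999) are flagged. The score was verified against central finite
differences of the restricted likelihood (agreement ~1e-8), the likelihood
itself against the dense-`V` formula
`log|V| + log|X′V⁻¹X| + y′Py`, and the whole fit against Henderson's
closed-form ANOVA estimators on a balanced nested design (agreement 1e-13).

## Solving the single-step equations

Henderson's MME with Kronecker covariance structure are assembled sparsely
(records × effects) and solved by dense Cholesky up to 20 000 equations
(all study sizes here), with a Jacobi-preconditioned conjugate-gradient
fallback above that. Fixed effects use drop-first dummy coding per trait on
the levels present in that trait's records; a singular system raises an
error naming the aliased levels. GEBV are returned for every pedigree
animal, phenotyped or not. Solutions were verified to machine precision
against direct GLS/BLUP computed from the full variance matrix on bivariate
fixtures with litters and missing-trait patterns.

## Scenarios and LR validation

Validation animals are the genotyped pigs of the last three generations of
a target line; their phenotypes never enter training. Six training designs
per line: (1) target line G0–G6 (control); (2) + other line G4–G9; (3) +
other line G7–G9; (4) target G4–G6 + other G4–G9; (5) target G4–G6 + other
G7–G9; (6) target G4–G6 + other G9. Phenotypes *and* genotypes of
line-generation cells outside training/validation are removed; the pedigree
always stays complete. Common-base animals (F0 and the unsplit G0) count
toward the target line. Validation animals keep their genotypes in partial
runs by default (`keep_validation_genotypes=False` gives the pedigree-only
sensitivity variant). The whole-data run of a line uses only that line plus
the common base.

Accuracy is `r(GEBVp, GEBVw)` with `SE = √((1−r²)/(n−2))`; bias is the
deviation from 1 of the regression slope of GEBVw on GEBVp; scenario
differences are tested with the Williams t statistic for two dependent
correlations sharing one variable (GEBVw), df = n−3. The auxiliary
criterion `r(GEBVp, y*)/√h²` (y* = own phenotype adjusted by the whole-run
fixed-effect estimates) is provided for comparison. Relationship summaries
are the min/mean/max of the off-diagonal H coefficients between the
validation set and the target-line / other-line training subsets; since
both subsets are genotyped these coefficients live in the `H22 = G**`
block, which is what the pipeline reads.

## The synthetic study

The generator emulates the structure of a closed divergent-selection
experiment rather than any particular dataset:

* Genome: 18 autosomes of 1 Morgan, 5 000 equally spaced SNPs, 300 QTL at
  random non-SNP positions; founder haplotypes in linkage equilibrium with
  allele frequencies uniform on (0.05, 0.5) (randomly oriented). Meiosis:
  Poisson(1) crossovers per chromosome, uniform positions. No mutation, no
  genotyping error, no sex chromosomes.
* Base: 30 F0 boars × 30 gilts → 30 G0 litters; 116 G0 boar candidates are
  ranked on the phenotypic index and the 6 highest found the high-index
  (HRFI) line, the 6 lowest the low-index (LRFI) line. Each generation
  G1–G9 per line: 6 sires × 36 dams (6 per sire, full-sib matings avoided
  where possible), 96 recorded male candidates (round-robin across the 24+
  litters) and one recorded female per litter as the next dam cohort, plus
  2 response litters (~Poisson(10) piglets, females and castrates) that are
  phenotyped but never selected. Default totals: ~2 960 pedigree animals,
  ~1 130 genotyped.
* Traits: ADG (g/day), BFT (mm) and DFI (g/day) are QTL traits with
  heritabilities 0.25 / 0.36 / 0.24, litter fractions 0.10 / 0.12 / 0.09
  and phenotypic variances 5811.7 / 14.37 / 40 000 (g- and mm-scale
  equivalents of the emulated study's variance-component table). QTL
  effects are multivariate normal and rescaled so the *genic* base variance
  `Σ 2p(1−p)α²` matches `h²σ²_P` exactly — matching the sample variance of
  60 founders instead would bias pedigree REML low, because both the base
  parameter of A and the Mendelian-sampling variance track the genic
  variance. Genetic correlations (ADG,BFT,DFI) = (0.30 with BFT, 0.80 with
  DFI; BFT–DFI 0.61) were solved analytically so the derived index
  `DFI − 1.06·ADG − 37·BFT` has heritability ≈ 0.12, the emulated study's
  value for the selection trait; litter correlations equal the genetic
  ones and residual correlations (0.22, 0.50, 0.18) reproduce phenotypic
  correlations of 0.25 / 0.60 / 0.35. FCR = DFI/ADG (kg scale) + N(0,
  0.07²) and RFI/index are derived, so their heritabilities are emergent
  (index ≈ 0.12 by construction, FCR ≈ 0.12 rather than the table's 0.24 —
  a known consequence of the definitional construction, accepted to keep
  the trait dependencies real).
* Fixed effects: contemporary group (generation × line × batch, 4 batches,
  SD 0.30 σ_P), pen size (5 levels, SD 0.10 σ_P), herd (2 levels, shift
  0.08 σ_P), sex (3 levels, shifts 0/−0.15/−0.05 σ_P). Response-animal
  records carry extra maintenance/production dependencies (AMBW, BW at
  start, LMC) that the response RFI regression is meant to remove, a
  residual scale of 1.15, and 5 % per-trait missingness.
* Observability: genotypes for breeding animals (selected sires and dams)
  of all generations, response animals of G6–G8, and every G9 candidate;
  phenotypes for candidates and response animals only. `"all"` and
  `"none"` mask rules exist for testing.
* All randomness flows from one seeded `numpy.random.Generator`; a seed
  fully determines the study.

What passing tests on this generator do *not* show about real data:
founders are in linkage equilibrium (LD arises only from drift and
selection during the 10 simulated generations), there is no genotyping
error or imputation step, litter sizes and missingness are idealized, and
the two chips / imputation workflow of a real study is out of scope (a
two-panel input raises an explicit "pre-impute externally" error).

## Problem sizes used in the validation studies

REML parameter recovery uses a five-generation random-mating pedigree of
~3 200 animals with 3 000 records (100 full-sib litters of 6 per
generation, each sire mated once per generation — a design chosen for a
low sampling variance of the heritability estimator), truth h² = 0.25,
l² = 0.10, 20 seeds. The LR identity study runs the
control scenario and the whole-data run for one line and trait on 20
default bundles with the generator's variance components on the generating
scale (correct model specification, so the semi-parametric identity holds
without REML noise); the unselected-slope study uses 20 reduced bundles
(5 generations, 48 candidates, random sire choice). Williams-test
calibration uses 2 000 replicates of trivariate normal samples of size 400
with equal dependent correlations (0.5) and r23 = 0.3. The full grid runs
2 lines × 6 scenarios × 5 traits on one default bundle.

## Known limitations

* Variance components for the grid can come from REML or be supplied; the
  bundled acceptance run estimates the ADG pair by REML and uses
  generator-derived values for the rest. A bivariate fit on the full bundle
  costs minutes per pair, and the simulated candidate RFI record is itself
  a re-fitted index residual, which makes the (RFI, index) pair nearly
  collinear — a generator artifact (real candidate RFI and the fixed index
  differ through measurement windows and covariates) that parks REML at
  the correlation boundary.
* The dense-Cholesky solver targets the study's scale (10³–10⁴ equations);
  national-evaluation scale would need sparse factorization and APY-type
  approximations, which are deliberately out of scope.
* Single-trait ssGBLUP, genetic groups/metafounders, and across-line
  bivariate modelling of the same trait in two lines are not implemented.
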