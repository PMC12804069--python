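# Methods notes

These notes document the modelling, numerical and simulation choices the
package makes, in the spirit of a statistical-software methods appendix.

## Mixed model

The maternal-effects animal model is `y = Xb + Za + Wm + e` with joint
random-effect prior `[a; m] ~ N(0, G0 ⊗ G)`,
`G0 = [[σa², σam], [σam, σm²]]`, and `e ~ N(0, I σe²)`. Writing `a` and `m`
with a direct-maternal covariance is the standard maternal-model reading of
separately stated `N(0, Gσa²)` and `N(0, Gσm²)` margins; the covariance is
what makes the model useful for growth traits, where direct and maternal
effects are negatively correlated.

* **W maps a record to its dam.** A record whose dam is unknown (or not
  genotyped) gets a zero maternal link; the count is logged. Founders
  therefore contribute direct information only.
* **Fixed effects.** One column per contemporary group (birth year × dam
  age class; the intercept is absorbed) plus sex contrasts against the
  first sex level. Aliased columns are dropped by pivoted QR and reported;
  their effect is absorbed by the retained columns.
* **Variance components are inputs, never estimated.** The populations are
  too small to estimate them reliably; literature values are wired in as
  `LITERATURE_VARCOMP` (kg² throughout; the YW maternal and residual
  entries are printed ambiguously in their source and are taken as kg²).
  `σm² = 0` (with `σam = 0`) drops the maternal block and the model
  reduces to single-effect GBLUP.
* **No maternal permanent-environment effect** — the model statement the
  package follows has none; adding one would change the meaning of σm².
* **Solver.** Henderson's MME with `[kaa, kam; kam, kmm] = σe²·G0⁻¹` on the
  random blocks. A dense Cholesky is used up to coefficient dimension
  3000; above that, Jacobi-preconditioned conjugate gradients with
  relative-residual tolerance 1e-10 (both paths are tested to agree to
  1e-6). Animals present in G without records receive GEBV through the
  G⁻¹ coupling — this is exactly how validation animals are predicted.

## Relationship matrices

`G = M D M′ / Σⱼ 2pⱼqⱼ` over centered dosages `M[i,j] = xᵢⱼ − 2pⱼ`.

* **Frequencies** for centering and the denominator are the observed
  frequencies of the analyzed animals; base-population frequencies do not
  exist for these closed herds. A consequence worth knowing: own-frequency
  centering puts the ones-vector in G's null space, so the plain G is
  always rank-deficient by one.
* **Conditioning.** Because of that, and because subset/weighted panels can
  lose more rank, G gets a ridge (`+0.01·I`) if and only if its smallest
  eigenvalue is ≤ 1e-8. Ridge conditioning was chosen over blending with a
  pedigree A matrix deliberately: the evaluation is pure GBLUP and
  A-blending would smuggle pedigree information into a G-only model. The
  applied ridge is recorded on the matrix and propagated to backsolve
  provenance, because it bounds the reconstruction error `M ŝ ≈ â`.
* **Weights** are normalized to mean 1 so `Σ dⱼ 2pⱼqⱼ` stays on the plain-G
  scale and variance components keep their interpretation across arms.
  With `d ≡ 1` the weighted matrix takes the same code path as the plain
  one, so the identity `Gw = G` holds bit-for-bit.
* **Subsets** reuse the full-panel frequencies of the retained markers
  (identical to recomputation, since the same animals are counted); the
  denominator sums over the subset only.

## Fst prioritization

Per-SNP Weir & Cockerham (1984) two-population θ̂ = a/(a+b+c) with the
diploid heterozygosity term, computed from observed genotype counts — the
same estimator PLINK 1.9 reports per SNP for two clusters. Cohorts split at
birth year 2010; the boundary year joins the "before" cohort (the
before/after phrasing leaves 2010 unassigned, and inclusive-lower is the
documented resolution). Raw θ̂ may be negative; ranking and weighting use
the zero-clipped value (weights must be nonnegative to keep Gw positive
semidefinite). The Fst→weight transform is not uniquely fixed by the
methodology this package follows; mean-normalized clipped Fst is the
package's documented choice and is isolated in `fst_weights` so an
alternative transform is a one-function change. Markers with undefined θ̂
(uncallable in a cohort, or zero total variance) are excluded from ranking
and enter weighting at the panel-average weight.

Cohort assignment uses all genotyped animals' birth years, including
validation animals. Birth year is not a phenotype, and the temporal scan
conceptually precedes any train/validation split; this mild information
sharing is accepted and documented, while the GWAS arm below is strictly
training-only.

## Backsolved SNP effects and iterative weighting

`ŝ = D M′ G⁻¹ â / Σ 2pq`, which reconstructs `M ŝ = â` exactly for an
unconditioned G and within a ridge-proportional error otherwise. The
iterative scheme starts from uniform weights; each iteration solves the
model, backsolves, and sets `dᵢ ← ŝᵢ² · 2pᵢqᵢ` (the per-SNP variance
explained — frequency-comparable, matching the "variance of each SNP
effect" reading) before mean-normalization and a rebuild of Gw. Ten
iterations by default. No window smoothing is applied: weights are strictly
per-SNP. Effect-based *selection* always uses the first iteration's effects
(uniform weights), so the subset arm is a pure GWAS ranking and is not
entangled with the weighting arm.

## Quality control

Markers are retained iff MAF ≥ 0.05, call rate ≥ 0.90 and exact-test HWE
P ≥ 1e-5 (retention is a logical AND; the removal log attributes each loss
to its first failing filter in the order call rate → MAF → HWE). The HWE
test is the plain exact conditional test on genotype counts — not mid-P —
computed with log-gamma arithmetic. MAF uses min(p, 1−p) after call-rate
masking. Individuals are never filtered. Residual missingness is closed by
mean imputation (2pᵢ), which preserves marker means and is adequate once
heavy missingness has been filtered; LD-aware imputation is out of scope.

## Cross-validation

Random 2/3 : 1/3 split of phenotyped animals (training size =
round-half-up of n·2/3, e.g. 1192 → 795/397), replicated 5 times by
default. Partition seeds derive only from the master seed and replicate
index, so the five scenario arms see identical partitions and contrasts are
paired. Validation animals stay in G (genotypes are not phenotypes) but
their records never enter fixed-effect estimation, backsolving or weight
iteration — the test suite checks this by perturbing validation phenotypes
and asserting bit-identical training artifacts. Corrected phenotypes
`y − Xb̂` use training-estimated fixed effects; validation records with
fixed-effect levels unseen in training are dropped and counted. Failed
replicates are reported as failed, never resampled. An optional
family-blocked split (whole full-sib families on one side) is provided for
leakage analyses, default off, since the plain random split lets close
relatives straddle the partition and that is part of the design being
emulated.

The inflation slope is OLS of GEBV on corrected phenotype (response =
GEBV); values below 1 read as deflated (over-shrunken) predictions. Note
the corrected phenotype contains the full residual, so accuracies against
it are much smaller than accuracies against true breeding values — on
simulated data the report carries both.

## Simulator

The simulator emulates the two study population *structures*, not their
genomes:

* **Pedigree.** Discrete non-overlapping generations, closed after the
  founders; per-generation sire/dam counts set the drift rate
  (`inbred_line`: 2 sires/8 dams, full-sib mating allowed, Ne ≈ 6–8,
  inbreeding reaching ≈ 0.3 in 8 generations; `composite`: 20 sires/60
  dams, no full-sib matings, inbreeding ≈ 0.1 in 12 generations). Sexes
  are balanced within cohorts so mating designs stay feasible. Generation
  g maps linearly onto birth years 1990–2023, making the 2010 cohort split
  meaningful. Per-dam litter sizes are inflated relative to real cattle to
  reach the study-scale genotyped counts at small parent numbers; this
  affects family sizes, not drift behaviour per generation.
* **Genomes.** Founders draw Hardy–Weinberg genotypes at uniform
  frequencies in [maf_min, 1−maf_min]; gametes recombine under a Haldane
  (interference-free) map on equally spaced markers — the simplest
  defensible recombination model; linkage-disequilibrium decay rates are
  not an emulation claim. Default panels are a few thousand markers: a
  deliberate scale-down of the ~68k study panels that preserves the
  animals-to-markers regime that matters for GBLUP rank and drift.
  Missingness is absent by construction and masked on demand for QC tests.
* **Genetics.** True breeding values are a QTL part (centered QTL dosages ×
  effects; effects for direct and maternal drawn with the correlation
  implied by G0) plus a pedigree-transmitted polygenic part (founder pairs
  from G0, Mendelian sampling halved and reduced by parental inbreeding).
  The QTL share of genetic variance is a knob (default 0.5) — the true
  number of QTL for growth in these herds is unknown, so it is a free
  parameter, not an emulation claim. Both parts are calibrated *exactly*:
  a shared 2×2 linear transform rescales each part so the realized
  covariance matrix of (a, m) across all animals equals its target share
  of G0. Because the transform is linear and common to all individuals it
  preserves pedigree additivity and the exact QTL-dosage identity. Tests
  of variance/covariance recovery therefore check the composition logic,
  not a loose Monte-Carlo draw; only the QTL-vs-polygenic cross term
  (O(1/√n)) remains stochastic.
* **Phenotypes.** Intercept + sex effect (+2.5 kg for males by default) +
  contemporary-group effects (N(0, 3²) kg per birth-year × dam-age class)
  + own direct BV + dam's maternal BV + N(0, σe²) residual. Defaults are
  on the birth-weight scale.
* **Determinism.** One master seed; child seeds are derived per stage
  (pedigree, gametes, effects, residuals), so identical scenarios produce
  bit-identical datasets.

What the simulator does **not** emulate: overlapping generations and
selection on phenotype (drift-only breeding), mutation, sequence-level
variation, real LD/MAF spectra, the X chromosome, and genotyping-platform
error. Passing tests on simulated data therefore demonstrate the
correctness and internal calibration of the machinery and the *relative*
behaviour of prioritization arms under drift — not absolute accuracies on
the real herds.

## Problem sizes in the shipped checks

The test suite runs the solver-equivalence check on 50 random instances of
up to 50 animals × 200 markers, and the recovery/null checks on a simulated
inbred line of ~1,000 animals × 5,000 markers (200 QTL) with 10–20
replicates. The acceptance script uses ~620 animals × 2,000 markers for its
cross-validation section. These sizes keep full runs to minutes while
staying in the small-n regime the method targets.

## Known limitations

* The Fst-weighting transform is a documented stand-in (see above).
* Mean imputation ignores LD; panels with heavy residual missingness
  should be imputed externally before entry.
* The CG solver path shares no sparsity with the dense path's G⁻¹; for
  populations beyond ~10⁴ animals an APY-style inverse would be needed
  (out of scope).
* Single-trait only; no REML/Gibbs estimation; no single-step H matrix.
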