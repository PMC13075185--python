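# Methods

## Scope and data model

The package analyses a germplasm panel phenotyped at two developmental
stages (germination and early seedling) under a control and a salinity
treatment, with replicate-level trait values, plus a biallelic SNP matrix
and (optionally) a GFF3 gene annotation. The in-memory containers are a
long-format pandas phenotype table (`genotype_id, stage, trait, condition,
replicate, value`), a `GenotypeMatrix` (samples, marker map, int8 call
matrix coded 0/1/2 alt-allele dosage, −1 missing), and plain DataFrames for
every derived table. File formats are CSV/TSV, VCF (GT-only, read through
cyvcf2), HapMap TSV (two-letter or IUPAC single-letter heterozygote codes)
and GFF3.

## Indices and classification

**STI orientation.** The index is defined as stressed mean over control
mean, so values above 1 mean performance above the non-stressed mean and
higher values mean stronger tolerance; the package exposes the inverse
orientation (`control_over_stress`) as a parameter for users who follow the
opposite convention. STIs are computed from per-condition replicate means
rather than averaged per-replicate ratios: replicates are unpaired between
conditions, and a ratio of means is robust to unequal replicate counts. A
zero control mean makes the index undefined; such records are flagged
(NaN), logged, and dropped before scaling.

**SES.** The visual injury score exists only under stress (controls are
symptom-free by design), so no control/stress ratio exists. The package
defines `SESSTI = 1/SES` — best possible score over observed score — which
equals 1 exactly for symptom-free genotypes and decreases with injury. This
is a convention, and it is logged as such.

**MFV/AMFV.** Min–max scaling is per trait within a stage, across
genotypes; a trait constant across genotypes has no defined membership and
raises an error naming the trait. AMFV is the unweighted mean across all
stage traits, including ion traits; no trait-direction flipping is applied
(sodium-accumulation indices enter as-is) because the index orientation
already encodes performance, and per-trait direction overrides are
available where a user disagrees for ion traits.

**Classification thresholds** are computed from the full-precision sample
mean and sample standard deviation (ddof = 1) of the analysed AMFV
distribution — never from rounded display values, whose reconstructed cut
points can disagree with full-precision ones in the second decimal. Lower
bounds are inclusive: HT at `X̄ + 1.64 SD` and above, T from `X̄ + 1 SD`, MT
from `X̄ − 1 SD`, S from `X̄ − 1.64 SD`, HS below. The classifier is exposed
in fit/predict form (`ToleranceClassifier`), with thresholds learned from
the sample it classifies.

**Cross-stage dynamics** compare classes under the ordinal order
HS < S < MT < T < HT; summaries report counts and percentages to one
decimal. Cluster-level groupings of transition flows are out of scope
(no construction for them is defined in the workflow this package
implements).

## Check comparisons

Genotype-vs-check contrasts use a one-sided Welch (unequal-variance)
two-sample t-test per trait on replicate-level STIs at α = 0.05 by default.
Welch is the safest default when no specific test is prescribed and
replicate variances differ between genotypes. Groups with fewer than two
replicates are flagged untestable and never significant.

## Regularized prediction

The estimator (`ElasticNetCD`) minimizes the glmnet-parameterized objective

    (1/2n) Σᵢ (yᵢ − β₀ − xᵢ'β)² + λ [ α‖β‖₁ + (1−α)/2 ‖β‖₂² ],

by cyclic coordinate descent with soft-thresholding. Predictors are
standardized internally (mean 0, variance 1, 1/n convention) so λ is on the
conventional glmnet scale; coefficients and the intercept are
back-transformed and reported on the original predictor scale, which is
what exported prediction equations use. Convergence is declared when the
largest coefficient change in a sweep falls below 1e−7, with a cap of 1e5
sweeps. The sweep kernel runs on the Gram matrix (`X'X/n`) so each
coordinate update is O(p); it is JIT-compiled with numba, with an identical
pure-Python path used when the per-sweep objective is being recorded (the
objective is asserted non-increasing in tests).

Cross-validation evaluates an α grid (default 0, 0.1, …, 1.0) over a
60-point log-spaced λ path from the smallest all-zero λ down to 1e−4 of it
(1e−2 when p ≥ n), warm-starting along the path. Fold assignment is seeded
and shared across α values; k defaults to 10. `λ_min` minimizes mean CV
MSE; `λ_1se` is the largest λ within one standard error (over folds) of
that minimum. The reported "significant predictors" of a fitted model are
its nonzero-coefficient (active) set — no coefficient inference is
performed.

Fit metrics: MSE, RMSE, `NMSE = MSE / var(y)` with the population-variance
convention (so a constant mean predictor scores NMSE = 1 and R² = 0),
`R² = 1 − SSE/SST`, and adjusted R² with p = size of the active set.
Single-trait predictive strength is the squared Pearson correlation between
AMFV and one trait's STI.

The stratified 80/20 split samples without replacement within each
tolerance class at `floor(0.8 × class size)` training members; a singleton
class goes entirely to training, because an empty training stratum damages
stratification more than an empty test stratum. VIF is computed per
predictor as `1/(1 − R²ⱼ)` from OLS of predictor j on the others; exact
collinearity reports +inf with a named-column warning.

## Genotype quality control

Filters follow the conventional order — samples by missingness (> 20%
removed), then markers by missingness (> 10%), minor allele frequency
(< 5%) and heterozygosity (> 50%), with marker statistics recomputed after
sample removal. Thresholds quoted with strict inequalities are honoured
strictly: a marker exactly at a boundary is retained (dialects of panel QC
tools differ here, so the rule is documented and configurable). Because
removing markers changes per-sample missingness, the filter sequence is
repeated until no record is removed; this fixed point makes `apply_qc`
idempotent, and the QC report accumulates per-filter removal counts across
passes while conserving `removed + retained = input` in both dimensions.
MAF uses allele counts over non-missing calls; heterozygosity is per marker
over samples.

## Association scan

The scan is a per-marker additive ordinary-least-squares regression of the
trait (per-genotype stress-condition mean) on alt-allele dosage over
non-missing samples, with a two-sided t-test on the slope and
`PVE = 100 × R²`. This is a deliberate, clearly-labelled stand-in for
multi-locus mixed-model scanners, whose machinery is out of scope here; the
computations this package is about — Bonferroni thresholding at `α/m`
(α default 0.05, configurable), PVE, favourable alleles, multilocus
combinations, peak naming `qTRAIT<chrom>.<index>` by position order — sit
identically on top of any scan. No kinship or structure covariates are
included by default; an optional covariate matrix is regressed out of the
phenotype when supplied. Monomorphic or nearly-all-missing markers (< 3
informative samples) get undefined statistics and are excluded from
significance.

## Allele mining

Favourable-allele calls use homozygous carriers only (heterozygotes are
excluded from class means), matching the homozygous-combination semantics
of the downstream tables; ties are broken alphabetically with a warning.
The allelic advantage is fixed as `100 × (FA mean − AA mean) / AA mean`
under higher-is-better (mirrored under lower-is-better); trait direction
defaults to higher-is-better for every trait, with per-trait overrides
available (e.g. for sodium accumulation). Multilocus combinations group
genotypes homozygous at every listed locus by their allele string; group
means rank the combinations, and the per-trait best combinations feed an
UpSet-ready membership matrix restricted to genotypes carrying at least one
best combination. The candidate-gene window is ±150 kb (configurable),
motivated by typical linkage-disequilibrium decay in rice panels
(~100–300 kb); distance is zero inside a gene, else the gap to the nearest
gene boundary (1-based inclusive intervals, feature type `gene` only), so
a within-gene hit always has distance 0. Non-synonymous status is ingested
from a user-supplied annotation, never predicted.

## Synthetic-data generator

The generator emulates the screening design: 201 genotypes, three
replicates, control vs. 120 mM NaCl stress, a germination stage with six
measured traits (two vigour indices derived downstream, giving eight
indices) and an early-seedling stage with sixteen traits including the
stress-only SES score.

Genetics: allele frequencies Beta(0.5, 0.5) truncated to [0.05, 0.95];
Hardy–Weinberg calls on 12 chromosomes with strictly increasing positions
(cumulative random gaps, mean 30 kb); no linkage disequilibrium, population
structure or dominance. The latent tolerance of a genotype at a stage is
`√h² · G + √(1−h²) · E`, where `G` is the standardized sum of planted
additive causal dosages (default five loci of effect 0.5, residual SD 1,
giving h² ≈ 0.4) and the stage residuals `E` are correlated so the latent
scores correlate across stages at the configured value (default 0.75 —
high enough that most genotypes keep their class across stages while a
minority improve or decline). Configurations whose target correlation is
unreachable given the genetic share raise an error rather than silently
clamping.

Phenotypes: control replicate = trait baseline × unit-mean lognormal noise
(CV default 0.10, a typical replicate-level CV for controlled screens);
stress replicate = baseline × `(1 − severity·(1 − sigmoid(latent)))` ×
noise, with severity 0.5 chosen so the panel-mean index falls in the
0.6–0.8 range typical of an effective but non-lethal stress level. Trait
baselines are arbitrary positive constants — every downstream index is
scale-free, so units need no biological calibration. SES is emitted as
`clip(round(1 + 8·(1 − sigmoid(latent)) + N(0, 0.5)), 1, 9)` under stress
only.

Data pathologies are injected to exercise QC: missing-completely-at-random
calls at `missing_marker_rate` (default 2%); a `missing_genotype_rate`
fraction of samples get an extra 30% dropout (to trip the sample filter);
and a `het_excess_rate` fraction of markers have calls resampled to
heterozygous with probability 0.7. The heterozygote excess is concentrated
per marker rather than spread per call because a uniform per-call rate
below 50% could never trip the per-marker heterozygosity filter the knob
exists to exercise.

What passing on synthetic data does *not* show: robustness to linkage
disequilibrium, population structure and kinship confounding (the scan has
no structure correction), genotype-by-environment interaction beyond the
single stress factor, non-additive gene action, informative missingness, or
trait distributions far from lognormal. Results on real panels depend on
all of these.

## Reproducibility

All randomness derives from explicit seeds. The pipeline fans a single
global seed out to per-stage seeds via
`numpy.random.SeedSequence(seed, spawn_key=(stage_index,))`, so stages can
be rerun in isolation from serialized intermediates without drift; the
generator uses Philox streams keyed the same way. Two runs with the same
config and seed produce byte-identical output trees (asserted in tests).
Tabular outputs carry full precision; rounding happens only in display
fields (percentages to one decimal, rendered equations to three decimals).

## Known limitations and open choices

- The association stand-in will show inflation on structured panels; it is
  calibrated (family-wise error ≤ α under Bonferroni) only under the
  exchangeable null the generator produces.
- Whether replicate means or medians should feed the index, and which test
  underlies check comparisons, are conventions; both are parameterized or
  documented above.
- The allelic-advantage formula is stated explicitly because more than one
  convention circulates; users comparing against other reports should check
  the denominator (this package divides by the alternate-allele mean).
- Test problem sizes (panels of 60–201 genotypes, 100–500 markers, 200-
  replicate Monte-Carlo calibrations) were chosen to make the full suite
  and the acceptance script run in minutes on a single CPU while keeping
  every statistical check adequately powered.
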