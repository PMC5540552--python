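# Methods

## Overview

`immunomap` implements a two-cohort coexpression analysis: discover
modules of tightly coexpressing probes in a discovery cohort, test
their topological preservation in a replication cohort (and in a
longitudinal follow-up), distill each replicated module to its core
probes, and map the modules onto metabolite measures and genetic
variation with cross-cohort meta-analysis. All stages operate on plain
tables (TSV expression/metabolite/covariate matrices, VCF dosages) and
are deterministic given a seed.

## The synthetic study

The generator (`immunomap.simulate`) is the package's model of the data
it expects in the wild: two population cohorts of unequal size
(defaults 500 and 1500), a follow-up re-sampling of 200 cohort-1
participants, 2000 probes carrying 8 planted modules of 10–150 probes,
160 metabolite measures (159 platform measures plus CRP), and 500 SNPs.

* **Expression.** Module probe g follows x_g = λ_g f_m + σ ε with a
  standard-normal module factor f_m per sample; loadings are drawn as
  λ ± U(−0.2, 0.2) around `loading_mean` (default 0.7) with 10% of
  signs flipped, so modules are imperfect and core-gene filtering is
  non-trivial. Background probes are pure noise. One planted cis
  variant per `n_cis_eqtl` adds a per-allele shift to a single probe.
* **Factors.** f_m = γ(g − ḡ) + 0.1·age_std + 0.1·sex_std + N(0, 1):
  each module has one trans-acting variant (γ = 0.25 per allele by
  default) and small direct covariate effects, so covariate adjustment
  matters.
* **Metabolites.** Associated measures are readouts of the standardized
  factor: met = b·f_std + 0.1·age_std + 0.1·sex_std + √(1 − b²)·ε with
  b = 0.3 for 5 measures per module. Writing metabolites as readouts
  (rather than as inputs into f) pins the planted *standardized* effect
  at exactly b and keeps the factor variance near 1, so the dosage
  R² on the factor is 2·MAF(1 − MAF)γ²/Var(f) and the planted QTL is
  detectable at genome-wide significance in a 500 + 1500 meta-analysis.
  For a joint Gaussian system the association structure is equivalent;
  only the variance bookkeeping differs.
* **Genotypes.** Hardy–Weinberg dosages with per-SNP MAF from
  `maf_range`; one contiguous 5-SNP LD block (allelic correlation 0.9,
  dosage r² ≈ 0.8) exercises LD pruning. The follow-up keeps cohort-1
  genotypes and sex, ages everyone by 7 years, re-draws all noise, and
  omits the oral-contraceptive covariate (not collected at follow-up).
* **Cell counts.** Leukocyte and platelet counts are log-normal with
  correlation ≈ 0.3 to the factors of modules 1 and 2 respectively, so
  the cell-count sensitivity analysis has something to find.

What the generator does **not** emulate: probe-level array artefacts,
metabolite detection limits on the raw concentration scale (cleaning is
tested on hand-built matrices), population structure/relatedness, LD
beyond the one planted block, and non-linear or interaction effects.
Passing tests therefore demonstrate correctness of the statistical
machinery and calibration under the linear-Gaussian study model, not
robustness to those real-data complications.

## Network construction

Spearman correlation is computed on age/sex-residualized expression
(residualize first, rank second — the adjustment modifies the
quantities being correlated); ties get average ranks; constant probes
are dropped and logged. The soft power is either fixed (5 for the
discovery cohort, 4 for the replication cohort, matching the analysis
constants) or selected as the smallest β ∈ 1..20 whose log-log degree
fit reaches R² ≥ 0.85 with negative slope. Because equal-occupancy
binning makes raw bin counts constant, the degree distribution is
fitted as log10(bin density) on log10(mean bin connectivity), density
being count/(width·total).

### Tree cut

The dendrogram (UPGMA on 1 − TOM) is cut at one deterministic height.
With soft power 5 the dissimilarities of unstructured probes compress
into a band within ~10⁻⁴ of 1.0 while module merges occupy a lower
band, so any fixed quantile of merge heights (e.g. 0.99) lands inside
the unstructured band and shreds the partition. The default cut is
therefore adaptive: among gaps in the sorted merge heights whose
midpoint lies in the upper half of the height range, choose the gap
maximizing gap × q (q = fraction of merges below), and cut at its
midpoint. The upper-range restriction keeps the cut above the
structured band; the q weight discounts spurious gaps among the few
earliest merges. An explicit quantile cut remains available via
`cut_quantile`. Clusters of ≥ `min_module_size` (default 10) leaves are
modules; everything else is background, and background probes are never
reassigned (no PAM-style rescue), keeping the partition deterministic.

Eigengenes are first-PC scores of the standardized module expression,
unit variance, sign-fixed so mean member kME ≥ 0; variance explained is
the leading correlation-matrix eigenvalue over module size. Modules
whose eigengenes cluster (average linkage on 1 − Pearson) below height
0.2 are merged, iterating to a fixed point.

## Preservation statistics

The seven statistics (see the module docstring of
`immunomap.preservation` for formulas) measure module density in the
test data (avg_weight, coherence, sign-aware avg_cor and avg_contrib)
and the concordance of connectivity patterns between datasets (cor_cor,
cor_degree, cor_contrib). Node contributions are computed from the
correlation submatrix as √λ₁·v₁, which equals the data-level
correlation of each probe with the probe-set eigengene. Sign-aware
forms penalize anti-correlated "replication". Null draws are probe sets
of matching size sampled uniformly (without replacement per draw) from
all non-module probes of the test dataset — not size-matched strata —
and all seven tests are one-sided (greater), since preservation is
directional. p = (#{null ≥ observed} + 1)/(n_perm + 1), so p is never 0
and the minimum is 1/(n_perm + 1); with the default 20 000 permutations
the α = 0.001 decision has ~20 null exceedances of headroom.

## Core genes

The exact permutation p-value estimator subtracts from the (b+1)/(v+1)
upper bound the integral ∫₀^{0.5/(v+1)} F(b; v, x) dx, where F is the
binomial CDF in the per-draw exceedance probability x — the
finite-permutation bias correction appropriate when the null is the
complete set of v non-module probes. b counts null memberships at or
above / at or below the probe's kME, whichever is smaller, with ties
counted on both sides (conservative); the p-value is doubled and capped
at 1. The integral is evaluated by adaptive quadrature (absolute
tolerance 10⁻¹²) with closed forms at b = 0 and b = v. BH-FDR is
applied within each module, separately per dataset; core requires
adjusted p < 0.05 in both cohorts.

## Associations and QTLs

Cohort-level association models are OLS with SD-scaled eigengene and
measure, complete-case per measure; covariates (age, sex, oc_use when
collected) are left unscaled, which does not affect the measure
coefficient. Cohort p-values use the residual-df t distribution; the
fixed-effects inverse-variance meta p uses the normal, as the scheme
implies. SD-scaling happens after sample exclusions, per dataset.
Within each module the 160 meta p-values are BH-corrected and flagged
at 6.25 × 10⁻³ (0.05/8 modules). Longitudinal stability is the
intersection of per-time-point significant sets.

QTL scans regress the (unscaled) eigengene or probe expression on minor
allele dosage with age, sex, and the top 10 PCs of the LD-pruned
standardized dosage matrix; the per-SNP fits use the
Frisch–Waugh–Lovell decomposition, which is exact OLS but lets the scan
share the covariate projection across SNPs. LD pruning is a greedy
sliding window (50 SNPs, step 5, r² > 0.2 removes the lower-MAF member,
ties broken toward the later position). Meta-analysis is the
sample-size-weighted Z-score method; effect signs come from the cohort
regression coefficients, and per-analysis complete-case n supplies the
weights. cis/trans classification measures distance from the SNP to the
nearest probe-interval boundary (0 inside): cis ≤ 1 Mb; trans > 5 Mb or
cross-chromosome; the 1–5 Mb zone is reported "neither" and excluded —
the two printed bounds leave it undefined. The cis permutation test
shuffles expression labels per cohort from one seeded index stream,
recombines permuted per-cohort p-values by weighted-Z, and reports
(#{p_perm ≤ p_obs} + 1)/(n_perm + 1).

## Numerical and design choices

* Permutation seeds: one global pipeline seed fans out to per-stage
  seeds by fixed offsets, so re-running a stage reproduces it.
* Missing metabolite values propagate as NaN and are excluded pairwise;
  no imputation.
* Rank-deficient covariate designs fail loudly, naming the collinear
  columns; degenerate inputs (constant probes/SNPs, all-zero metabolite
  columns) are dropped with logged warnings rather than silently.
* `weighted_z_meta` rejects p = 0 (the caller must supply the
  underlying statistic); scan code floors underflowed p-values at the
  smallest positive double before meta-combination.
* BH-FDR is implemented directly from the step-up definition and
  cross-checked against statsmodels in the tests.
* The hypergeometric enrichment takes annotation terms as flat gene
  sets over an explicit universe — no ontology graph or semantic
  summarization.

## Test problem sizes

The planted-recovery check runs at the full study scale (2000 probes,
8 modules, n = 500/1500, 1000 preservation permutations). The
calibration and power checks use reduced panels chosen so the quantity
under test is unchanged: type-I calibration uses 200 replicate null
datasets of 60 probes (199 permutations, so p < 0.05 is exact at the
permutation resolution); FDR calibration uses 500 replicate null scans
of one module × 40 measures at n = 150/300; effect-recovery uses 200
replicates of a 60-probe module at n = 500; and QTL power uses 100
replicates of a 100-probe module with a 300-SNP panel at n = 500 + 1500
(a panel large enough that the 10 genetic PCs absorb a negligible share
of any single SNP's variance, as in a realistic genome-wide panel).

## Known limitations

* The adaptive tree cut assumes a bimodal merge-height structure
  (structured band + noise band); data with a continuum of module
  tightness may need the explicit quantile cut or external assignment.
* The preservation statistics are this package's concrete
  interpretation of density/connectivity preservation; numerical
  results are not interchangeable with other implementations of
  module-preservation testing.
* Single-factor modules only; nested or overlapping modules are out of
  scope, as are signed networks and block-wise decomposition for very
  large probe sets.
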