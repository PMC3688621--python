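# Methods

This note documents the models, estimators and design choices in
`namqg`, and what the synthetic-data studies do and do not demonstrate.

## Synthetic NAM panels

A panel consists of biparental RIL families sharing one common parent.
Each RIL chromosome is simulated directly at the fully-inbred
(F-infinity) expectation as a two-state Markov walk over marker
positions: the founder origin at the first marker is Bernoulli(1/2), and
between adjacent markers at map distance `d` cM the origin flips with
probability `R = 2r/(1+2r)`, where `r = (1 − exp(−2d/100))/2` is the
single-meiosis recombination fraction from Haldane's map function.
Simulating finished RILs rather than iterating meioses gives the exact
marginal expectation at a fraction of the cost; the downstream analyses
only ever see finished RILs.  Intermated (IBM-style) families are
modelled by multiplying map distances by an expansion factor (default 2
when requested); no generation-level detail is represented.
Lines are fully inbred: residual heterozygosity is ignored and founder
dosage is coded 0 (common parent) / 1 (alternate parent).

Dense SNPs are simulated jointly with the linkage markers in one Markov
pass per chromosome, so RIL SNP dosages are exactly consistent with
founder haplotypes (drawn per founder with allele frequencies uniform on
[0.1, 0.9] by default).  SNP genetic positions are interpolated from the
linkage map through physical position.

Trait architectures combine (i) QTL at linkage markers with per-family
effects drawn around a shared mean (`allele_series_sd > 0` produces the
sign heterogeneity across families seen for real stalk-strength QTL —
an allele series relative to the common parent) and (ii) a polygenic
RIL-within-family component with per-family variances.  When a QTL
variance target is given, effects are rescaled so the realized mean
within-family QTL variance matches it exactly on that population.
Multiple traits are generated with a requested genetic correlation by
mixing standardized line values through the Cholesky factor of the
correlation matrix; this targets the correlation of total genetic
values, which is what downstream covariate analyses consume.

Plot values are

    mean + family + RIL(family) + env + family×env + RIL(family)×env
         + block + row + column + AR1⊗AR1 spatial + plant noise,

with plant-sampling noise of variance `plant / plants_per_plot` (plots
record the mean of `n` plants), one plot per line and environment at a
random grid cell, and blocks as bands of grid rows.  Defaults mirror a
stalk-strength-like trait: genetic variance split ~35% between families
and ~65% within, line-means heritability around 0.2 for the focal trait
and ~0.9 for covariate traits, two to three environments.  Features of
real trials that are *not* emulated: genotyping error and missingness
mechanisms, maturity-group blocking, check-plot layouts (replicated
parents are optional and off by default), method/equipment differences
between environments, and selection during line development.  Passing
tests on these panels therefore validates the estimators' statistics,
not robustness to those real-data artifacts.

## REML machinery

Three fitters maximize the restricted likelihood.

*General dense engine* (`reml_dense`): arbitrary random-effect design
matrices with one variance each and a residual that is iid or
AR1(row)×AR1(col) within groups (environments), heterogeneous across
groups.  The covariance matrix is formed densely; variance parameters
are optimized by L-BFGS-B with analytic REML gradients (AR1 parameters
by finite differences) and then polished with average-information
Newton steps so that on balanced designs the estimates agree with
closed-form ANOVA expected-mean-squares estimators to ~1e-9 (an oracle
the test suite checks at 1e-6).  Negative components are constrained to
zero (boundary).  This path is intended for thousands of observations
at most.

*Crossed fast path* (`reml_crossed`): the complete line × environment
layout with one plot per cell and no field-design terms — the layout
used at NAM scale.  An orthonormal (Helmert) rotation of the environment
dimension splits the likelihood into an environment-mean problem and
iid contrast problems, each with family-block plus low-rank covariance
handled by closed-form block inverses and Woodbury identities, giving
O(n_lines) cost per likelihood evaluation.  Powell search on
log-variances; per-family or pooled RIL variances.  With one plot per
line-environment the RIL×environment and residual variances are
confounded; the fit reports their sum as the residual and zero for
RIL×environment.  Heritability is unaffected because the two terms'
denominators (harmonic mean of environments, harmonic mean of plots)
coincide in that design.

*AR1 grid fitter* (`reml_ar1_grid`): a single field grid with an
AR1⊗AR1 spatial component plus nugget, via Kronecker eigendecomposition;
used for per-environment spatial analysis and validated by recovering
rho = 0.6 on 50×50 grids.

Model building follows the bottom-up idea: per-environment models
(dense engine) with likelihood-ratio backward elimination of
block/row/column/spatial terms at p < 0.05 using the 50:50 chi-square
boundary mixture, then the multi-environment model keeping the retained
structure.  The covariate adjustment ("accounting for a correlated
trait") is implemented as a random regression on the covariate's
centered line mean — one extra variance component, a rank-one term in
the fast path.

BLUP line means are conditional expectations of family + RIL effects
given the data; BLUE line means refit the genetic terms as fixed
effects, computed as two-way (line, environment) fixed-effect estimates
by alternating demeaning.  In a balanced single-environment design the
BLUE equals the arithmetic plot mean, and as the RIL variance grows the
BLUP approaches the BLUE (no shrinkage), both verified in tests.

## Heritability on a line-means basis

Across the panel the numerator is the family variance plus the
arithmetic mean of per-family RIL variances; within a family it is that
family's RIL variance.  The denominator adds family×environment and
RIL×environment divided by harmonic means of the number of environments
per family and per RIL, plus the arithmetic mean of the per-environment
residual variances divided by the harmonic mean of plots per RIL.  The
arithmetic-mean-of-residuals reading is implemented literally for
heterogeneous residuals.  Recovery studies at 25 families × 80 RILs × 3
environments show the estimator unbiased within ±0.01–0.02 at true H²
from 0.05 to 0.9 (mean over 50 replicates); single-replicate estimates
are noisy because the between-family variance is estimated from few
families — a real feature of NAM designs, not an artifact.

## Joint-linkage mapping

The model is family intercepts plus family-nested marker terms: one
slope per family in which the marker segregates (monomorphic families
contribute no slope, so their effect is exactly absent, not zero-
estimated).  Forward steps add the group with the smallest marginal-F
p-value below the entry threshold; after each addition, terms whose
marginal p (from the coefficient covariance — identical to drop-one
refitting) exceeds the exit threshold are removed.  Entry and exit
default to the same p, 5e-4.  Ties break deterministically by
chromosome, then cM, then marker name.  Duplicated (collinear) marker
columns are dropped with a warning.

RMIP: each of B resamples draws, within every family, 75% of lines
without replacement plus 25% with replacement, preserving family sizes,
and rebuilds the model; a marker's RMIP is the fraction of resamples
selecting it, optionally collapsed over a 3 cM window (the reporting
convention for linked markers tagging one QTL).

Resamples contain duplicated lines.  Treating duplicates as independent
observations makes nominal F-tests severely anticonservative (the
slope's true sampling variance is inflated by roughly E[w²]/E[w] ≈ 1.4
under this scheme, which at a 5e-4 threshold inflates per-resample
family-wise selection from ~5% to ~87% in our measurements).  The
package therefore represents a resample as unique lines with frequency
weights and tests with a line-clustered sandwich F statistic
(`v' M⁻¹ v` with the weighted meat matrix), using the Kish effective
sample size for residual degrees of freedom.  With unit weights this
reduces exactly to the classical marginal F, so full-data model
selection is untouched.  Under this treatment the null calibration of
the RMIP rule (any marker above 10% of models) lands at or below the 5%
family-wise level the procedure is meant to guarantee.

Permutation thresholds permute line means within families (preserving
family means) and return the target-alpha quantile of the minimum
marginal p across markers.  The pleiotropy test refits one trait's
selected terms on another trait and correlates the two per-family
effect vectors per QTL (t-test across families; fewer than three shared
segregating families is flagged).  Variance partitioning is sequential:
family first, then each QTL in selection order; the ΔR² values sum to
the total by construction.

## GWAS

RIL-panel mode: for each chromosome, the line means are refit on the
QTL model *without* the family term and without that chromosome's QTL;
the residuals carry error plus the held-out chromosome's signal
(including its between-family component).  Forward selection of
single-slope SNP terms (after a family term) runs on B subsamples of
75% of lines without replacement at entry p < 5e-8; a SNP's RMIP is its
selection fraction.  SNP effects are deliberately *not* nested in
families — a single unidirectional slope — so this scan and the
family-nested linkage scan answer different questions.  For large null
studies a screening pass computes all first-step statistics in batched
linear algebra and re-runs only flagged subsamples exactly.

Diversity-panel mode: y = mu + SNP + polygene with polygenic covariance
K·σ²_g.  Variance components are estimated once on the null model by
REML through one eigendecomposition of K and reused for every SNP
(the standard two-step approximation); each SNP is then a GLS t-test in
the rotated basis.  Benjamini–Hochberg q-values are computed by the
step-up rule (tested against a brute-force reference).  On a simulated
two-subpopulation panel with a trait aligned to structure, naive
regression shows genomic inflation above 10 while the mixed model sits
at ~1.0.

## Genomic prediction

Van Raden kinship from [0,1] dosages rescaled to allele counts;
monomorphic SNPs excluded.  For inbred lines the diagonal is ≈ 2 and
small-sample centering leaves off-diagonals near −(1+F)/n, which is why
"unrelated → 0" holds only for large panels.  GBLUP estimates the
variance ratio by REML on the training submatrix (bounded scalar search
on the eigenvalue scale) and predicts held-out lines by conditional
expectation through the cross-covariance block of the full K —
identical under the model to refitting with missing records, and
verified against the ridge-regression dual to 1e-8.  A zero genetic
variance at the boundary collapses predictions to the training mean and
is flagged.

Cross-validation: per repeat, a fresh random five-way partition
(optionally family-stratified; families smaller than the subset count
are pooled with a warning); for calibration fraction k, all C(5,k)
subset combinations calibrate and the complement is predicted; accuracy
is the coefficient of determination of observed line means regressed on
predictions (equal to squared Pearson correlation; degenerate constant
predictions score 0), averaged over folds then repeats.  Per-fold
results are retained so pooled summaries can be formed if preferred.
The family-nested QTL comparator reuses the stepwise machinery at
entry/exit p = 0.05 with at most 40 terms and predicts from family
intercepts plus nested effects; unseen families fall back to the
training grand mean (flagged).

The architecture-contrast study uses 10 families × 100 RILs with 200
small-effect QTL and line-mean heritability 0.7.  Smaller panels (a few
hundred lines) leave the QTL predictor with essentially no power at 20%
calibration, collapsing its fold-to-fold variance; at 1,000 lines the
expected pattern is robust: GBLUP is more accurate and the QTL
predictor's fold-to-fold accuracy spread is larger.

## Problem sizes in the standard studies

Chosen as the package's desk-scale defaults: joint-linkage null
calibration at 10 families × 60 RILs × 200 markers with 50 bootstrap
models and 120 replicates; GWAS null calibration at 3,000 lines ×
10,000 SNPs with 50 subsamples and 100 replicates; heritability
recovery at 25 families × 80 RILs × 3 environments with 50 replicates
per target; AR1 recovery on 50×50 grids; prediction studies at 480–
1,000 lines with 20 cross-validation repeats.

## Known limitations

- The dense REML engine is O(n³) per likelihood evaluation; very large
  unbalanced trials with spatial terms are out of reach (the crossed
  fast path covers the complete-layout case at NAM scale).
- One plot per line-environment confounds RIL×environment with error;
  the split is only identifiable with replicate plots.
- The two-stage design (line means first, then mapping/prediction) is
  retained; a single-stage analysis with a genomic relationship matrix
  inside the line-mean model is not implemented.
- The sandwich F calibration of bootstrap resamples is asymptotic;
  families of only a handful of lines are rejected rather than modelled.
- BLUE computation ignores residual correlation (it is the two-way
  fixed-effects estimator), which matches the balanced-design target
  but is only approximate under strong spatial structure.
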