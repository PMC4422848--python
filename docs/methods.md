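# Methods

## The model

`pubertwin` fits a correlated-factor ACE structural model to longitudinal
twin data with two traits — a pubertal hormone level and voxel-wise grey
matter density — each measured at two occasions (around ages 9 and 12).
Phenotypes are indexed 1 = hormone at age 9, 2 = density at age 9,
3 = hormone at age 12, 4 = density at age 12, and each decomposes as

    x_i = mu_i + a_i A_i + c_i C_i + e_i E_i

with latent additive-genetic (A), common-environment (C) and
unique-environment (E) factors of unit variance.  Factors of the same kind
correlate across phenotypes within a person (matrices `R_g`, `R_c`, `R_e`);
these correlations are the only channel for cross-trait and cross-age
covariance.  Across the members of a twin pair, A factors correlate 1 in
monozygotic and 0.5 in dizygotic pairs, C factors correlate 1 by
definition, and E factors are independent.  The model-implied covariance of
the stacked pair vector is therefore built from A = D_a R_g D_a (C, E
analogously): the within-twin block is A + C + E and the cross-twin block
is r_z·A + C.

All change quantities are *latent*: with Cov(i,j) = a_i r_g(i,j) a_j +
c_i r_c(i,j) c_j + e_i r_e(i,j) e_j,

    V_chGM  = Var(2) + Var(4) − 2·Cov(2,4)
    V_chH   = Var(1) + Var(3) − 2·Cov(1,3)
    Cov_ch  = Cov(3,4) + Cov(1,2) − Cov(1,4) − Cov(2,3)
    r_ch    = Cov_ch / sqrt(V_chGM · V_chH)

No per-subject difference score is ever formed, so subjects observed at a
single occasion still contribute.  The phenotypic (change) correlation
splits exactly into the parts transmitted by each factor kind: rph-a keeps
only the `r_g` terms of the numerator (rph-c, rph-e likewise), and
rph-a + rph-c + rph-e = r_ch identically.  The same decomposition applies
to the single cross-trait covariance Cov(3,4) for the age-12-only
hypothesis, and to the 2-phenotype submodel that uses second-occasion data
alone.

## Estimation

Estimation is full-information maximum likelihood: each family contributes
the multivariate-normal log-density of exactly its observed phenotype
subvector, using the matching submatrix of the pair covariance.  Censored
hormone values, missing occasions and incomplete pairs (e.g. members of
opposite-sex pairs entering a same-sex stratum alone) enter without
imputation; this is consistent under MCAR/MAR missingness, and the
generator's dropout is MCAR by design.  Families are grouped by
(zygosity, missingness pattern) so the likelihood and its gradient are
computed pattern-wise and vectorised.

Numerical choices that matter:

* **Correlation matrices** are parameterized by hyperspherical angles of a
  unit-row Cholesky factor, box-bounded to (0.02, pi−0.02).  Any interior
  angle vector maps to a valid (PSD, unit-diagonal) correlation matrix, so
  the optimizer cannot leave the feasible cone.  Direct bounded angles
  converged in roughly a third of the iterations needed by a logistic
  squash of the same angles.
* **e paths** are log-linked (e_i > 0 is required for identifiability);
  `a`/`c` paths are free in sign — only squares and products are
  identified, and fits report a², c², e² fractions.
* **Gradients** are analytic: the pattern-wise score with respect to the
  pair covariance and mean vector is chained through closed-form
  derivatives of A/C/E with respect to paths and of R with respect to each
  angle.
* **Standardization**: phenotypes are centred/scaled internally per
  phenotype before optimization (hormone and density live on scales an
  order of magnitude apart); fitted models and log-likelihoods are mapped
  back to the raw scale exactly.
* **Starting values**: a moment start (pairwise-complete within- and
  cross-twin covariances, A = 2(Σ_MZ − Σ_DZ) etc., eigenvalue-clipped to
  the feasible region), a neutral equal-split start, and seeded jitters;
  `n_starts` controls how many are tried (default 5, the mass-univariate
  scan uses 1 with a cohort-level warm start).  Ties are broken by
  parameter-vector norm.
* **Equality constraints** (zero change covariance, zero age-12
  cross-trait covariance, zero single-component part of either) are
  enforced on the *raw* data scale — the four terms of the change
  covariance carry different standardization factors, so a
  standardized-scale zero would not be a raw-scale zero.  SLSQP with the
  analytic constraint gradient runs first; an augmented-Lagrangian loop
  polishes until |g| ≤ 1e−8.  Convergence is declared from the constraint
  residual and the projected-gradient norm, not an optimizer's flag.
* **Boundary estimates** (variance fractions at 0) are permitted; LRT
  p-values are reported from the nominal chi-square(1), as is conventional
  for these models.  Near a variance boundary the true null distribution
  is a chi-bar-square mixture, making the nominal test conservative.
* **Degenerate change variances** (below 1e−10) make r_ch and the rph
  components NaN rather than ±inf.

The likelihood-ratio test compares nested fits: chi2 = 2·(logL_full −
logL_constrained), clipped at zero, with df = difference in free-parameter
counts (1 per scalar constraint).

## Hormone preprocessing

Urinary hormone levels (LH, FSH, estradiol) are divided by same-day
creatinine to correct for urine dilution; salivary testosterone passes
through.  The phenotype is the mean of the two assay days; a day below the
assay detection limit is unusable, a single usable day stands alone, and
an occasion with both days censored is missing (left to FIML downstream —
an optional limit/√2 imputation exists but is off by default, since the
treatment of doubly-censored children is a data-analytic choice, and
missing is the conservative one).  The combined level is natural-log
transformed; the base only rescales paths, leaving correlations and
likelihood ratios unchanged.  Order of operations is normalize → average →
log; the one-day rule is applied after creatinine correction.  Mardia's
multivariate skewness (n·b1p/6 against chi-square with p(p+1)(p+2)/6 df)
and kurtosis (b2p standardised against mean p(p+2), variance 8p(p+2)/n)
check normality after transformation.

## Synthetic cohorts

The generator draws the latent factors explicitly (never from the implied
covariance matrix, so it doubles as an independent oracle for the
covariance algebra) and emulates:

* the twin design — default 21 MZ + 16 DZ complete same-sex pairs plus 19
  singletons per stratum, with 34% occasion-2 dropout (MCAR), matching a
  cohort of 190 baseline / 125 follow-up children;
* log-normal, left-skewed raw hormone levels: the model operates on the
  log scale, observed levels are exponentiated, split into two assay days
  with independent log-scale noise (sd 0.10 by default; the true assay
  repeatability is not published, so this is configurable), multiplied by
  a log-normal creatinine excretion (sd 0.30), and censored at the assay
  detection limit (0.11 U/l FSH, 0.1 U/l LH, 150 pmol/l estradiol,
  11 pmol/l testosterone);
* voxel maps on a 3-D grid: A and C contributions are constant within the
  coupling cluster and constant (from independent factors) outside it, so
  the cluster is the only locus of true hormone–density association; the E
  contribution is a per-voxel field, Gaussian-smoothed (default FWHM 2
  voxels) and rescaled to preserve each voxel's marginal variance, so
  per-voxel fits see exactly the configured path model while neighbouring
  voxels are spatially correlated;
* twins share assessment dates, so co-twins have identical ages (age 9.2 ±
  0.11, age 12.1 ± 0.24 across pairs).

Default ground truth ("FSH-in-girls-like"): hormone log-scale variance
0.30 with (a², c², e²) = (0.5, 0.1, 0.4) and means log 0.47 → log 0.92
U/mmol creatinine; density variance 0.01 with (0.5, 0.15, 0.35) and means
0.60 → 0.55; cross-age factor correlations r_g = 0.6/0.8 (hormone/density),
r_c = 0.5, r_e = 0.15.  `plant_coupling` solves in closed form for the
same-occasion cross-trait factor correlation of one component that yields
a requested change correlation (the cross-trait correlations do not enter
the change variances, so the equation is linear).  Feasibility note: for a
planted component, PSD of its correlation matrix requires |cross-trait ρ| +
|cross-age r| ≤ 1; a pure-E planted change correlation of 0.5 needs
ρ ≈ 0.71 under the defaults and is comfortably feasible, whereas the same
correlation through C would require correlations outside the PSD cone
unless C variance shares are enlarged (the `c_heavy` variant exists for
that, and the 2-phenotype age-12 ground truth carries a pure-C cross-trait
correlation with no cross-age constraint at all).

What the generator does **not** emulate: real spatial covariance of grey
matter, registration/segmentation error, MAR-vs-MNAR attrition,
menstrual-cycle variation, assay drift, age effects on means (available in
the model but off in the generator), or opposite-sex-pair modelling.
Passing tests therefore demonstrate the *estimator and pipeline* are
correct under the declared generative assumptions, not that the biological
conclusions transfer to any particular real data set.

## Voxel-wise inference

The scan fits the full and constrained models per voxel, records r_ch (or
the age-12 cross-trait correlation), the 1-df chi-square and its p-value,
and the rph components of the full fit.  Non-converging voxels are
flagged, logged with their indices and excluded from the FDR pool
(reducing m), never silently dropped.  Per-voxel restart seeds derive from
the master seed and the voxel's flat index, and the warm start is
mask-independent, so results are bit-identical regardless of processing
order or partition.

Multiple comparisons use the Benjamini–Hochberg step-up rule at FDR 0.05
with the independence constant c(V)=1 (the variant recommended for
imaging); the conservative c(V)=Σ1/i variant is available behind a flag.
The largest rejected p maps to a "critical chi-square" on 1 df for
reporting.  Component attribution mirrors the within-significant-voxels
convention: each significant voxel gets three component-zeroing LRTs, each
component's p-values get their own FDR pass within the significant set,
and a voxel is attributed to a component only when that component's test
alone survives; voxels where none (or several) survive are reported as
undetermined.  Clusters are 6-connected components of the significance
mask.

## Test design and problem sizes

The test suite verifies every layer against an independent oracle: the
printed change-algebra expansions against contrast-vector quadratic forms
of the 8×8 covariance (1e−12, 1000 random models); the rph identity
(1e−10); FIML against closed-form complete-data and marginalised densities
(1e−9); the generator against the implied covariance of 10⁶ draws for 10
random models (Monte-Carlo error bound with the 3σ budget split across all
360 comparisons); step-up FDR against a brute-force evaluation of its
definition and against the statsmodels implementation; and Mardia's
statistics against univariate moment formulas and a normal-theory
calibration.

Simulation-based checks run at sizes chosen to finish on one CPU in
minutes: parameter recovery uses 20 replicates of 500+500 pairs (mean
absolute error of variance fractions < 0.1); LRT null calibration uses 200
replicates of 200+200 pairs (rejection rate inside the exact binomial 95%
region around 0.05); the end-to-end pipeline uses a 5×5×5 grid with a
3×3×3 planted pure-E cluster (change correlation 0.5), 300+300 pairs and
34% dropout over 3 seeds, requiring ≥80% cluster recovery per seed and
majority unique-environment attribution.  `scripts/acceptance.py` re-runs
these computations from scratch with a user-supplied seed.

## Known limitations

* A/C separation is weakly identified at realistic twin-cohort sizes;
  single-replicate a²/c² errors of 0.15 are within sampling error, which
  is why recovery is asserted as a mean over replicates.
* No sex-limitation, dominance (ADE) or opposite-sex-pair models; sexes
  are analysed as separate strata.
* LRT p-values ignore the boundary (chi-bar-square) issue, as is standard
  reporting practice for these models.
* The FDR m equals the synthetic mask size; no cluster-extent or
  permutation inference.
* OpenMx-style saturated-model comparisons and fit indices are not
  implemented; only the constraint LRTs needed by the hypotheses.
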