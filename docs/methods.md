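# Methods

## Data model

The unit of analysis is the subject-day curve: activity counts per minute
over the 24-hour local-clock interval, 1440 values. Input is long-format
minute records (optionally built from 5-second epochs by summation, with a
minute marked unobserved when any of its 12 epochs is absent), a
subject-level covariate table (age, sex, education years, partner, BMI,
chronic diseases, cigarettes/day, drinks/day, diagnostic group ∈
{none, remitted, current}, symptom score, antidepressant and benzodiazepine
flags) and a day-level table (work/school-day flag, date).

### Preprocessing rules

* A day is valid with ≥ 960 observed minutes (16 h). The boundary is
  inclusive, and the criterion is applied once per 24-h day; no separate
  night-window threshold is imposed.
* A subject is included with ≥ 1 valid weekday and ≥ 1 valid weekend day
  (weekend = Saturday/Sunday from the date).
* Missing minutes on valid days are imputed with the subject's activity at
  the same minute averaged over their *other* valid days. Because donors
  are always the originally observed values, the operation is idempotent
  and never alters an observed minute. A minute observed on no valid day
  falls back to linear interpolation of the subject's mean daily profile
  across the minute grid (logged as a warning).
* Season is assigned from the date with fixed boundaries on the 21st
  (Dec 21–Mar 20 winter, Mar 21–Jun 20 spring, Jun 21–Sep 20 summer,
  Sep 21–Dec 20 autumn).

## Fourier pre-smoothing and fPCA

The basis is the orthonormal Fourier system on [0, 1440]: 1/√T and
√(2/T)·sin/cos(2πkt/T) for k = 1..4 (nine functions). On the minute-midpoint
grid with unit spacing the discrete Gram matrix is the identity to machine
precision, so least-squares projection equals inner products, and PCA of
the 9-dimensional coefficient vectors is *numerically identical* to PCA of
the 1440-point discretized smooth curves. The package computes fPCA in
coefficient space (exact and fast); the discretized-curve PCA is retained
as an independent test oracle only.

Fitting pools all valid subject-days into one day-level analysis: mean
coefficients are column means, eigenvalues/eigenfunctions come from the
eigendecomposition of the centered coefficient covariance (ddof = 1),
sorted descending. Sign is fixed by orienting each eigenfunction so its
largest-magnitude Fourier coefficient is positive (the sign of an
eigenvector is otherwise arbitrary). The number of retained components is
the smallest K whose cumulative variance proportion reaches the threshold
(default 0.75). Variance proportions are reported over all nine
eigenvalues of the centered covariance; on degenerate inputs the trailing
eigenvalues are zero, so the proportions always sum to one.

Scores are the coordinates of centered coefficient vectors on the retained
eigenfunctions. For regression they are standardized by the pooled SD over
all subject-days, and continuous covariates are z-scored on the analysis
sample, so coefficients read as per-SD effects.

## GEE association models

Day-level standardized scores are regressed on determinants with Gaussian
identity-link GEE, cluster = subject, exchangeable working correlation
(an independence option exists), and robust sandwich covariance — the
estimator statsmodels provides, used behind the package's model surface.
The exchangeable structure matches the generative score model
ξ = Γ·z + b_i + e_ij, whose within-subject day-to-day correlation is
τ_b²/(τ_b²+τ_e²).

Each model adjusts for the full sociodemographic, lifestyle and sampling
blocks; clinical characteristics (group dummies with "none" reference,
symptom score, antidepressant use, optionally benzodiazepine use) enter
one at a time because they are strongly intercorrelated. Season enters as
three winter-referenced dummies; reference levels appear in the results
table as "Ref" rows. Rank deficiency raises an error naming the dependent
columns; covariate missingness is handled complete-case per model with the
dropped count logged.

FDR control is Benjamini–Hochberg within each (component × clinical-spec)
model's family of non-reference tests; the family scope is recorded in the
output so users can re-pool p-values across components if they prefer a
wider family.

## Function-on-scalar regression

Outcomes are one curve per subject: minutes are averaged into 144
ten-minute bins and over the subject's valid days. Day-varying covariates
are collapsed to the subject level — work/school day becomes the
proportion of valid days, season the modal season. Each coefficient
function is expanded in a fixed 10-function cubic B-spline basis on
[0, 24 h] and fitted by unpenalized stacked least squares; because the
stacked design is X ⊗ B, the normal equations factor into two small
solves. A second-difference ridge penalty with GCV selection is available
when smoother estimates are wanted. With the coefficient basis set to the
grid size the fit reduces exactly to independent pointwise OLS.

Pointwise variances use a subject-level sandwich covariance of the basis
coefficients; 95% bands are β̂(t) ± 1.96·SE(t). The per-covariate global
test is a Wald test on the covariate's full basis-coefficient block. Its
default calibration uses the across-grid residual covariance in a
Hotelling-style F(d, n−q−d+1) reference, which is exact under Gaussian
errors with arbitrary correlation across the grid; the plain sandwich
Wald χ²_d is available but noticeably anticonservative at cohort-scale n
(its estimated 10×10 block is noisy), and a subject-resampling bootstrap
(default 500 draws) is provided as the robust alternative.

## Synthetic generator

Curves follow X_ij(t) = max(0, μ(t) + Σ_k ξ_ijk φ_k(t) + ε_ij(t)) with
scores ξ_ijk = Γ_k·z_ij + b_ik + e_ijk. Defaults, chosen once to emulate a
two-week adult-cohort wear protocol:

* n days/subject = 14 as a consecutive calendar block with a random start
  date; work/school days Bernoulli(0.4); season from the date.
* Subject covariates loosely match an adult outpatient cohort: age
  N(50, 12), BMI N(26.5, 5), ≈63% female, education N(13, 3) years,
  group multinomial (0.25 current / 0.49 remitted / 0.26 none), symptom
  scores and antidepressant use elevated in affected groups.
* The mean curve is low at night (~60 counts/min) with a broad daytime
  plateau (~340 at peak), built from the first two harmonics so its basis
  projection is exact.
* True components are unit coordinate vectors in coefficient space
  (orthonormality exact by construction): overall level (constant),
  morningness (sin₁), biphasic (cos₂), biphasic timing (sin₂), plus five
  low-variance "fine-structure" directions spanning the remaining basis.
  The fine-structure floor is essential: real daily variation is never
  confined to four directions, and with a strictly 4-dimensional truth the
  75% rule could never retain four components (the cumulative share of
  three of four descending eigenvalues is always ≥ 3/4). Default
  eigenvalues (272k, 160k, 144k, 120k, 5×36k activity-units²) put the
  cumulative share over 0.75 exactly at K = 4, mirroring the typical
  ~34/18/15/13% + remainder split of cohort data.
* Score variance splits evenly between a subject random effect and a day
  effect (ICC 0.5) by default — cohort day-to-day score correlation is not
  reported anywhere, so this is a free design choice, exposed via the
  `with_eigenvalues(..., icc=...)` constructor.
* The default effect matrix Γ reproduces the sign/magnitude structure of
  multivariable per-SD estimates in comparable cohorts (lower overall
  activity with age, BMI, smoking and current disorder; workday- and
  season-driven timing shifts; a strong workday effect on the biphasic
  mode).
* Minute noise is white N(0, 25²); non-wear is a Poisson(1)/day number of
  geometric(mean 45 min) gaps. Activity is floored at zero; with the
  default mean curve fewer than 0.1% of minutes truncate, keeping the
  linear score model effectively exact.

What the generator does **not** emulate: autocorrelated minute-level noise,
bout structure and zero-inflation of real counts, informative non-wear
(gaps correlated with activity), weekday/weekend mean differences beyond
the covariate effects, and device calibration drift. Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated model, not robustness to every artifact of field recordings.

## Validation problem sizes

The acceptance experiments use: 50 noiseless days for the fPCA/discretized
oracle identity; 20 studies of 100 subjects × 14 days (eigenvalues 4:2:1,
minute noise SD 10, flat mean 500 so truncation never binds) for
eigenstructure recovery; 200 studies of 200×14 (effect recovery), 1000 of
250×3 (null type-I) and 500 of 100×14 (CI coverage) for the GEE; 1000
random p-vectors for BH; and 40 studies of 150 subjects for FoSR recovery
plus 500 of 100 for its null calibration. FoSR pointwise band coverage is
averaged over replicates because the covered fraction of a single
replicate is highly variable (errors are correlated across the grid).

## Numerical notes and limitations

* Projection solves the normal equations even though the Gram matrix is
  the identity to ~1e-12, so results are exact least squares under any
  basis size.
* Eigenvalues are clipped at zero; ties in the eigendecomposition make
  individual eigenfunctions non-identifiable (only the spanned subspace
  is), which the sign convention cannot repair — relevant only for exactly
  equal eigenvalues.
* Daylight-saving transition days are handled by the generic validity
  rule; the package does not infer time zones.
* GEE uses no small-sample SE correction; with < ~150 clusters and many
  covariates the robust Wald test is mildly liberal. Mixed-effects
  alternatives, penalized fPCA and function-on-function regression are out
  of scope.
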