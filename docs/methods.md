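# Methods

`chronomodes` implements a supervised pattern-learning protocol for
discovering latent subtypes of a binary chronotype trait (morningness vs
eveningness) from multimodal brain features, together with the synthetic
cohort machinery needed to exercise every stage without access-restricted
population data. This note records the model, the statistical procedures,
the tunable parameters, and the design decisions taken where the protocol
left genuine freedom.

## The latent model

Let `X` (n x p) be the concatenated brain feature matrix — regional grey
matter volumes (GMV), white-matter tract fractional anisotropy (FA), and
functional coupling (FC) link strengths — and `y` in {-1, +1}^n the binary
chronotype (-1 early bird, +1 night owl). Partial least squares regression
with a single response (PLS1) extracts components sequentially by NIPALS:
the weight vector `w_j` maximizes covariance between the current
(deflated) feature matrix and the centered target, scores are
`t_j = X_j w_j`, x-loadings are `p_j = X_j' t_j / t_j' t_j`, and `X` is
deflated by the rank-one fit before the next component. Scores are
mutually orthogonal by construction, and the rotation

    R = W (P' W)^{-1},   T = X_c R

reproduces the training scores exactly from the centered/scaled training
matrix — the identity every fit is checked against (tolerance 1e-8).

Numerical choices: features are centered and scaled to unit variance
inside the fit (the three blocks are on incommensurate scales — mm^3
volumes, unitless FA in [0,1], correlation strengths — and PLS covariance
maximization is scale-sensitive); the centering/scaling vectors are stored
in the model so transformation and projection are self-contained. The
NIPALS inner loop is initialized from the cross-covariance direction
`X'y`, which for a single response is already the fixed point, so fitting
is deterministic (tolerance 1e-10, cap 500 iterations, never reached in
practice). Component signs are fixed by making the largest-magnitude
weight entry positive; the morning/evening orientation of a component is
then read off a pooled two-sample t-test of its scores between the target
groups (df = n1 + n2 - 2).

The per-component *latent correlation* is the Pearson correlation between
a score column and the target. With a single response this equals the
score/y-score correlation up to sign, so the simpler definition is used.

## Permutation significance: two null schemes

The target vector is shuffled across participants B times while the brain
features stay fixed; per shuffle the per-component correlation magnitude
is recorded positionally (component j against component j, no
max-statistic pooling), and the p-value uses the add-one estimator
`p_j = (1 + #{|rho_null| >= |rho_obs|}) / (1 + B)`, whose floor 1/(1+B)
reproduces the "stronger than every null model" decision rule at B=1000
and threshold 0.001. Comparison is on |rho| because the component sign is
arbitrary under the sign convention.

Two null schemes are implemented because they answer different questions
and behave very differently at realistic n/p:

* **projection** (default, the protocol scheme): the trained model's score
  columns are held fixed and correlated with each shuffled target. Under
  the null of no brain-target association the draws concentrate at scale
  1/sqrt(n). This matches the common applied practice of testing
  associations "in the derived embedding space" of an already-trained
  model. It is the right test of "is this fixed projection associated
  with the target?", but it is **anti-conservative as a test of
  model-level significance**, because the observed in-sample correlation
  is inflated by the fit itself while the null draws are not.
* **refit**: the PLS model is refit from scratch on every shuffled target
  and the null correlation comes from the refit model's own scores. This
  is the exchangeable, exactly calibrated test (its p-values are uniform
  under the null — verified by a KS check in the test suite, and its
  type-I error sits at the nominal level). Its cost is power: a refit
  null component chases noise freely in the full feature space, so its
  in-sample correlation concentrates near sqrt(p/(n+p)) (about 0.41 at
  n=2000, p=397), and only planted signals stronger than that can ever be
  declared significant in-sample. Users doing model selection should
  prefer this scheme and expect it to be conservative at desk scale.

Both schemes share the estimator, the positional comparison, and the
reporting surface; the pipeline default is the projection scheme because
it is the one that reproduces the reference protocol's behavior,
including significance of components whose observed correlations are far
below the refit-null scale.

## Bootstrap loading inference

Participants are resampled with replacement (same n, single-class
resamples redrawn and counted), the model is refit, and the refit
components are matched back to the reference components with the
Hungarian algorithm on a correlation similarity matrix between the two
x-loading matrices; the cost is -|corr| so orientation flips are handled
by the sign of the matched correlation after assignment (the assignment
provably attains the exhaustive-search maximum; tested against brute
force for k <= 6). After B aligned draws, a loading is flagged robust
when its two-sided 5-95% percentile interval excludes zero. Note the
interval is 90% two-sided, so genuinely zero loadings are flagged at
roughly a 10% rate by construction; the flag is a screening device, not
a familywise-corrected test.

## Phenome-wide association scans

Brain scores are correlated with every phenotype of each family
(behavioral PheWAS, diagnosis DiaWAS, medication MedWAS) by Pearson
correlation on pairwise-complete rows; binary phenotypes enter as 0/1
numerics (point-biserial). p-values come from the t transform of r with
df = n_used - 2; underflow is capped at the smallest positive double so
the reported -log10 p stays finite. Bonferroni control is strictly
within-family (`0.05/m_family`), never pooled across families, with
`m_family` the number of phenotypes actually tested; zero-variance
phenotypes and those with fewer than `min_n = 50` complete pairs are
emitted flagged rather than silently dropped, and do not count toward
the family size. An optional pre-filter drops phenotypes observed in
fewer than 80% of participants, mirroring common phenome curation.
Missingness in one phenotype cannot perturb another's statistics
(pairwise-complete by construction).

## Cross-cohort projection and age stratification

An external cohort measured only on a feature subset (the GMV block in
the study design) is mapped into the trained latent space by restricting
`W` and `P` to the subset rows and applying
`scores = X_sub W_sub (P_sub' W_sub)^{-1}`. The inverse is computed by
linear solve; a condition number above 1e12 is a hard failure rather than
a silent pseudo-inverse, because the formula presumes invertibility.
External features are residualized against the external cohort's own
covariates (intracranial volume, site, sleep battery) and standardized
with the external cohort's own statistics — the cohorts' acquisition
scales differ and each is preprocessed independently. This is a
documented interpretation: the projection formula's centering is
underdetermined, and `standardize="training"` is available to reuse the
training statistics instead.

Age stratification reports mean, sample SD (ddof=1) and n of each score
column within age brackets — adults 40-50/50-55/55-60/60-65/65-70 years,
children 100-110/110-120/120-130/130-140 months. The printed bracket
lists share endpoints, so a deterministic convention is required:
brackets are left-closed right-open, with the final bracket right-closed.
Participants outside every bracket are counted and reported.

## Preprocessing

The six-level questionnaire response is collapsed to -1 (both morning
levels) / +1 (both evening levels); "do not know" and "prefer not to
answer" drop the participant. Shift workers are excluded, as are
participants whose *coded* chronotype differs between the initial and
imaging visits (a change within the same pole, or a non-codable response
at either visit, is not a disparity). Brain features are residualized by
per-feature OLS (intercept included) on nuisance covariates — site
(one-hot, reference level dropped), head motion, and the five-item sleep
battery (duration, napping, insomnia, snoring, dozing). Age and sex are
deliberately not residualized: they are study variables. Rows with
missing covariates are dropped from fit and output (complete-case) and
reported; rank-deficient designs are rejected naming the collinear
columns. Nuisance regression is fit within the analysis sample.

## The synthetic cohort generator

The generator is first-class, tested code: it defines the conditions
every downstream claim is evaluated under.

Latent scores `Z` (n x k) are i.i.d. standard normal. The brain matrix is
`X = Z diag(c) V' + C G + sigma E` with unit-norm sparse loading columns
`V` (random +/- entries of equal magnitude, support restricted to a
configurable subset of blocks per mode, default 10% of each block),
covariate leakage `C G` (random coefficients, SD 0.2), and i.i.d. noise
`E`. The binary target comes from a liability threshold: the liability
`L = sum_j rho_j Z_j + (residual) eps` is standard normal and is cut at
the quantile of `1 - target_balance`; `rho_j` is chosen in closed form,
`rho_j = r_j sqrt(pi(1-pi)) / phi(tau)`, so the point-biserial
correlation between `Z_j` and the +/-1 target equals the configured
`mode_strengths[j]` exactly in expectation (verified by Monte Carlo).
Ages are uniform on the configured range and rank-coupled to a
latent-weighted Gaussian propensity, which plants sign-controlled
age-latent associations while leaving `Z` exactly Gaussian. The external
cohort shares the source's GMV loading rows verbatim and reverses the
sign of every age-latent association, so the reversed age-distribution
analysis has a known answer.

Default conditions: n=2000 participants; 139 GMV + 48 FA + 210 FC
features (210 = 21*20/2 coupling pairs); five modes with latent-target
correlations (0.30, 0.25, 0.20, 0.15, 0.10) — the reference analysis
does not report its latent correlations, so these are chosen for
testability, decreasing as extraction order; signal amplitude c = 3.0
per mode, which at noise SD 1 gives planted features a signal share of
variance large enough to be recovered at n=2000 but far from noiseless;
target balance 0.334 night owls; 54.44% female; ages 40-70 years
(external: 107-133 months); phenome of 977 behavioral (continuous),
1,396 diagnosis (binary, prevalence 5%) and 133 medication (binary,
prevalence 10%) phenotypes, with three planted associations per mode per
family and all remaining columns pure noise; 2% non-codable chronotype
responses, 2% shift workers, 1% visit-inconsistent responders, so the
exclusion paths are always exercised.

What the generator does **not** emulate: spatial autocorrelation between
neighboring brain regions, realistic phenotype marginals beyond type and
sparsity, site- or scanner-specific feature distributions, and
non-linear brain-age structure. Passing tests therefore demonstrate that
the machinery is correct and calibrated under the stated generative
model, not that real cohorts contain such modes.

## Degenerate inputs and tie-breaks

Zero-variance features survive standardization (scale forced to 1) but a
zero-variance score column or target is an error; constant loading
columns make the Hungarian similarity undefined and are rejected;
single-class targets are rejected at fit time and redrawn in the
bootstrap; rank exhaustion (k beyond the informative subspace) is
detected by a relative threshold on the residual cross-covariance. Ties
in the sign convention resolve to the first largest-magnitude entry; hit
rankings break p-value ties by |r|, then name.

## Problem sizes used in the checks

The shipped tests and the acceptance script run at desk scale, chosen as
the package's own working sizes: cohorts of n=2000 (or smaller for unit
tests), B=1000 shuffles for the planted-mode significance check, B=200
bootstrap draws over 10 seeds for the loading-recovery study, 200
replicates at B=99 for the calibration KS check, and 200 replicates of an
m=500 all-null phenome for the familywise-error check.

## Known limitations

* The projection null is anti-conservative for model-level claims (see
  above); the refit null is exact but has little in-sample power below
  the sqrt(p/(n+p)) scale. There is no in-sample correlation-based
  permutation test that is both; out-of-sample validation is the honest
  alternative and is out of scope here.
* Bootstrap percentile intervals are screening flags at their nominal
  10% two-sided rate, not corrected inference.
* No harmonization across sites, no regularized/sparse PLS, no
  longitudinal modeling; associations are unadjusted Pearson scans by
  design.
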