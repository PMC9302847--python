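# Methods

## Model and statistic

A population response to one trial of condition *c* is a length-N vector
of spike counts in a fixed analysis window. Responses are modeled as
multivariate Gaussian,

    X_c ~ N(mu_c, Sigma + eps_indep * I),

with a condition-specific mean and a condition-independent covariance
composed of a *shared* part Sigma (correlated variability, built from a
parametric eigenspectrum) and an *independent* per-neuron variance
eps_indep. Responses are real-valued; spike-count discreteness is not
modeled, because every quantity of interest here is a function of first-
and second-order statistics only.

Discriminability of two conditions is the squared d-prime

    d'2 = dmu' Sigma_pooled^{-1} dmu,   dmu = mu_a - mu_b,

with Sigma_pooled the unweighted average of the two per-condition sample
covariances (unbiased, k−1 denominator, regardless of unequal trial
counts). d'2 is invariant under joint invertible linear maps of means and
covariance, which is the basis of several exactness tests (a reduction to
a rotated full-dimensional basis must not change it).

## The dDR construction

Given trials of two conditions:

1. signal axis s = dmu / |dmu| from the per-condition trial means;
2. e1 = leading eigenvector of the pooled covariance of per-condition
   mean-centered trials; noise axis n1 = normalize(e1 − (e1·s)s).
   A printed formula in circulation for this step is an outer-product
   expression that is dimensionally inconsistent with its stated purpose;
   the Gram–Schmidt remainder is the unique realization of "the axis
   orthogonal to dmu in the plane spanned by dmu and e1" and is what this
   package implements.
3. further noise axes by deflation: project the centered data off the
   span of all chosen axes, take the top principal component of the
   residual, re-orthogonalize against every prior axis, normalize.
   Orthogonal projection is the only deflation operator consistent with
   returning an orthonormal basis; a final modified Gram–Schmidt sweep
   pins pairwise orthogonality at ~1e−15.

Eigenvector signs are fixed by making the largest-magnitude entry
positive; all similarity comparisons use |cosine|. Degenerate inputs are
errors, not warnings: |dmu| below 1e−12 times the mean per-neuron
standard deviation (scale-aware zero test) is a degenerate signal, and e1
parallel to dmu (residual norm ≤ 1e−8) is degenerate noise. By default
the noise covariance pools the two decoded conditions; pooling across any
condition set is supported for global-noise-axis workflows.

## Decoding and cross-validation

The estimation/validation split is stratified per condition (default
50–50, seeded). The reducer and the decoding axis w_opt = Sigma^{-1} dmu
are fit on estimation trials only; the validation statistic projects
held-out trials onto the *frozen* w_opt and computes
(mean_a − mean_b)² / pooled projected variance with unbiased
per-condition variances. Refitting on validation data would not measure
overfitting, which is the quantity of interest.

Singular covariances (inevitable for full-rank decoding when trials <
neurons) are inverted with the Moore–Penrose pseudo-inverse at relative
cutoff 1e−10. No shrinkage is applied by default — the full-rank
baseline is *supposed* to fail by overfitting at small k, and
regularizing it away would hide the effect the package exists to
quantify. A diagonal-loading parameter exists for users who want it.

## Baselines

* taPCA: PCA on the S×N condition-mean matrix (centered by the grand
  mean of condition means). For S = 2 exactly one component exists and it
  equals the normalized dmu — identical to the dDR signal axis; requests
  for more components raise a rank error rather than silently padding.
* stPCA: PCA on pooled single trials, centered by the grand mean over
  all trials. Grand-mean (not per-condition) centering is deliberate:
  per-condition centering would turn stPCA into the dDR noise estimator,
  whereas stPCA's defining property is that its components mix
  across-condition and trial-to-trial variance. By default it is fit on
  the two decoded conditions (a switch allows all conditions).
* Component counts are always explicit; no cumulative-variance
  thresholding.

## Simulator

Shared-covariance eigenspectrum families: rank_one, rank_m (eigenvalues
proportional to 1/i by default, or caller-specified), power_law
(eigenvalues proportional to 1/n over all N dimensions), independent
(flat). Eigenvectors are Haar-random orthonormal (QR of a Gaussian
matrix with sign correction) except for the independent family, where
the basis is arbitrary by symmetry. The signal direction can be given
*exact* cosines with the leading shared eigenvectors, with the remainder
drawn uniformly from their orthocomplement; this is how aligned- and
orthogonal-noise geometries are constructed without random leakage of
the signal onto structured noise axes.

Reference scales, chosen once as a realistic regime and used as the
package defaults: N = 100 neurons, total shared variance 20 (mean shared
variance 0.2 per neuron, the order of magnitude implied by weak pairwise
spike-count correlations), default eps_indep = 10% of the mean shared
variance per neuron — small enough that shared modes dominate, nonzero
so the covariance is full rank.

What the simulator emulates: two-condition Gaussian responses with
low-dimensional shared covariability plus private noise, N ≈ 50–100,
k ≈ 10–500 — the statistical structure of awake-cortex population
recordings. What it does not emulate: Poisson/count discreteness,
stimulus tuning curves beyond a mean-vector difference,
condition-dependent covariance, or non-stationarity across trials.
Passing tests therefore demonstrate correct behaviour of the estimators
under the stated second-order model, not robustness to those departures.

## Experiments and their parameters

* overfit-gap: N = 2, unit variances, covariance 0.4, dmu = (1, 1);
  500 replicates per k over {10, 20, 50, 100, 200, 500}. Reports the
  variance of the sample-covariance entry (empirical vs. the closed form
  (s11 s22 + s12²)/(k−1)) and the mean train-minus-validation d'2 gap,
  both of which must decay toward zero as k grows.
* eig-recovery: for rank-1, 1/n and independent spectra at N = 100,
  the mean |cosine| between the PCA estimate and the true e1 per k in
  {5, 10, 25, 50, 100, 250}, 100 replicates. For the 1/n spectrum at
  k = 50 this lands near 0.9; rank-1 recovery is near-perfect from a few
  trials, independent noise is unrecoverable by construction.
* convergence: rank-1 and rank-2 (and 1/n) shared covariance at N = 100,
  eps_indep = 0.45, |dmu| = 4 with cosine 0.3 on e1 and exact zero
  overlap with e2; cross-validated d'2 for dDR with 1–3 noise dimensions
  and full-rank decoding, 100 fresh datasets per k in
  {20, 50, 110, 200, 500}, normalized by the mean full-rank validation
  d'2 at k = 5000 (5 replicates). Parameter rationale: with the signal's
  e2-overlap exactly zero, the one-noise-dimension variant converges to
  the full asymptote, and the advantage of a second noise dimension at
  finite k comes solely from what sampling noise in the estimated dmu
  leaks onto e2 — the eps_indep and |dmu| scales were chosen (analysis
  of the leakage term, confirmed by simulation during design) so that
  this advantage is clearly resolvable at large k while the
  one-dimensional variant still reaches within ~10% of the asymptote.
* regime-compare: bootstrap relative d'2 (taPCA and stPCA vs. dDR) on a
  single 50-trial-per-condition synthetic dataset per regime, rank-3
  shared covariance (total 20). Fine-discrimination analog: |dmu| = 4
  with cosine 0.8 on e1, eps_indep = 0.02 — a small signal buried in a
  dominant, partly aligned shared mode; here taPCA (projection onto dmu
  alone) cannot discount the aligned noise and underestimates d'2, and
  stPCA's top components track noise rather than signal. Coarse-
  discrimination analog: |dmu| = 12 orthogonal to all three shared
  axes, eps_indep = 0.5; here the decoding axis is unaffected by the
  shared modes and taPCA matches dDR. The private-noise floors differ
  between regimes by design: with a negligible floor, contamination of
  the estimated dmu by e1 at small estimation sizes makes the
  one-dimensional projection genuinely inferior even for an orthogonal
  signal, so a "similar performance" regime requires private noise
  comparable to the per-axis shared noise.

## Resampling

* Permutation null for a pairwise covariance: 500 shuffles of one
  neuron's values by default; reports the null sample and the two-sided
  tail fraction. Calibration: with independent inputs the tail fraction
  is uniform.
* Bootstrap relative d'2: 15 validation trials per condition held out
  once; estimation sets of size k − 15 drawn with replacement from the
  remaining pool (never from validation trials); 200 bootstraps per k.
  The comparison's validation d'2 is normalized by the across-bootstrap
  mean dDR validation d'2 at the same k. The reported SE is the
  bootstrap SD rescaled by sqrt(n_est/n_pool) when the estimation set
  undersamples the pool (standard m-out-of-n correction; the uncorrected
  SD is also reported). The literature contains more elaborate
  corrections; the rescaling is documented as an approximation.

## Numerical choices

* Covariance symmetric-part enforcement after every estimate and
  projection; PSD checks with relative tolerance 1e−8.
* Pseudo-inverse cutoff 1e−10 (relative); d'2 clamped at zero against
  −1e−18-scale round-off.
* Basis orthonormality asserted at 1e−9 on construction (achieved at
  ~1e−15).
* All randomness flows through numpy Generators; experiments derive
  per-component generators from a SeedSequence, so every table is
  byte-reproducible from (config, seed).

## Known limitations

* Strictly pairwise: multi-class decoding is expressed as an iterator
  over condition pairs, not a joint model.
* The noise axes come from PCA; latent-variable models of shared
  variability can be substituted only by passing their axis through the
  pooled-conditions hook, not as a fitted component.
* The m-out-of-n SE correction is an approximation (see above).
* Gaussianity is assumed throughout; for strongly non-Gaussian count
  data at low rates the d'2 statistic remains defined but loses its
  signal-detection interpretation.
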