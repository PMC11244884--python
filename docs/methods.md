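# Methods

## Model

`spafac` factorizes spot-level expression counts from M tissue sections
("samples") that need not share a coordinate system.  For sample m with
N_m spots at 2-D locations X_m and G genes,

    Y[m,g,i] ~ NB( lambda[m,g,i] * sz[m,i],  phi_m ),
    lambda[m,g,i] = sum_{l=1..L} W[g,l] * exp(F[m,i,l]),

where

- **W** (genes x L, non-negative) are gene loadings **shared across all
  samples** — this is what ties the samples together and makes factors
  comparable across sections without any spatial alignment;
- **F[m,:,l]** is the l-th spatial factor of sample m on the log scale,
  with a sample-specific Gaussian-process prior
  F_l ~ GP(beta0 + X beta1, k) and exponential (Matern-1/2) kernel
  k(a,b) = alpha * exp(-||a-b|| / B);
- **sz** are known per-spot size factors (library size divided by its
  mean, so mean(sz) = 1);
- **phi_m** is the NB dispersion with Var = mu + mu^2/phi, so large phi
  approaches Poisson noise.  phi is fixed (default 1.0, configurable),
  not estimated; published sensitivity analyses for this model family
  report stable factors across phi in roughly [0.001, 10].

Because the scale split between W and exp(F) is arbitrary, after
fitting each loading column is normalized to unit sum and the log of
the scale is absorbed into the corresponding factor's intercept and
variational mean.

## Inference

Each factor is handled with a sparse inducing-point construction: the
factor's values U at n_m locations Z_m (k-means centroids of the spot
coordinates; `inducing_fraction` default 0.35) carry a Gaussian
variational posterior q(U) = N(delta, Omega) with a full lower-Cholesky
parameterization of Omega.  The objective for one sample is

    ELBO_m = E_{q(U)}[ log p(Y_m | F(U)) ] - sum_l KL( q(U_l) || p(U_l) ),

where F(U) is the exact GP conditional mean given U (the conditional
densities cancel between the joint and the variational family).  The
expectation is estimated with a small number of Monte-Carlo draws of U
(`n_mc`, default 3 during training; use >= 100 for reported ELBO
values).  Samples are independent, so the joint ELBO is the sum of the
per-sample ELBOs — the identity that justifies the distributed update
scheme below, and which the test suite asserts to 1e-10.

All gradients of this objective are closed-form and implemented
directly in NumPy: the NB score chain through the rate, the linear maps
of the GP conditional mean, Cholesky-based Gaussian KL derivatives, and
exponential-kernel derivatives with respect to log-amplitude and
log-lengthscale.  Every gradient path is verified against central
finite differences in the test suite (tolerance 1e-5).

### Distributed fitting

Each iteration:

1. For every sample, one Adam step (shared step size, default 0.01,
   beta1 = 0.9, beta2 = 0.999) on that sample's ELBO with respect to
   all sample-specific parameters *and* a sample-local copy of W.
2. The local loading candidates are averaged across samples and
   negative entries are set to zero; the projected average becomes the
   shared W for the next iteration.

With a common step size this follows the same gradient field as a
monolithic ascent on the joint ELBO, while only one sample's data is
touched at a time.  Iteration stops when the relative change of the
total ELBO over a 5-iteration window falls below `convergence_tol`
(default 1e-4) or after `max_iterations` (default 1000).  The ELBO
trace is stochastic, so monotonicity per step is not guaranteed and not
asserted; the tests check that the final ELBO exceeds the initial one.

### Chunking

For large samples the spots can be partitioned into `n_chunks` random
near-equal blocks.  Blocks share the sample's inducing grid and
variational parameters; block likelihood contributions are summed and
the KL term is counted once, so the chunked gradient equals the
unchunked gradient at every parameter point (asserted to 1e-6) — the
benefit is purely memory: only one block's kernel cross-covariance is
materialized at a time.

### Initialization

Optimization is warm-started from a seeded multiplicative-update NMF
with KL divergence on the depth-normalized counts Y/sz (200
iterations).  This is the natural warm start because the model's mean
is exactly a non-negative factorization of Y/sz with activities exp(F);
an NMF of log-transformed counts was tried and discarded — it is
model-mismatched and recovers the loading structure far less cleanly.
Per-spot activities are column-normalized to mean one and
log-transformed to initialize F; delta is set to the F value at the
spot nearest each inducing point; Omega starts at 0.01 I; the GP mean
at zero; the kernel at amplitude 1 and lengthscale 0.1 on unit-box
coordinates.  Per sample, coordinates are affinely rescaled so the
bounding box fits [0,1]^2 (aspect preserved) before any kernel
evaluation, which keeps lengthscales comparable across samples of
different physical size; the transform is stored for back-mapping.

### Numerical choices

- Kernel sign: the implemented covariance is alpha * exp(-d/B); a
  kernel increasing with distance is not positive definite.
- Jitter 1e-6 * alpha on diagonal kernel blocks, escalated tenfold up
  to 1e-4 * alpha on Cholesky failure, then a hard error reporting the
  conditioning problem.
- Kernel hyperparameters, the Cholesky diagonal of Omega, and nothing
  else are optimized in log space; W non-negativity is enforced by
  projection (negatives to zero) after averaging, never by a softplus
  reparameterization, so exact zeros are representable.
- Per-sample Monte-Carlo streams are seeded `seed + sample_index`;
  every advertised path (fit, simulation, k-means, NMF) is
  deterministic given the seed.
- Gene ranking ties are broken by ascending original index; spots with
  zero total counts are rejected, not dropped.

### The non-spatial variant

`mpnmf_elbo` evaluates the same NB observation model with i.i.d.
N(mu_l, sigma2_l) priors on the factor entries (shared across samples)
in place of the GPs.  Whether those prior parameters should be
estimated is left open in the source material; the function evaluates
the objective at user-supplied values.  By construction the
multi-sample objective equals the single-sample objective on the
column-concatenated matrix [Y_1 ... Y_M], which the tests assert
exactly, so fitting this variant is ordinary probabilistic NMF on the
concatenation and no separate fitting loop is shipped.

## Synthetic data

The generator emulates a multi-sample Visium-like study at desk scale:
per-sample rectangular spot grids (default 15 x 15), L_true = 4 binary
spatial primitives (quadrant block, horizontal band, vertical band,
center disc) whose supports are made pairwise disjoint by priority
masking, gamma(1,1) gene loadings with a `loading_sparsity` fraction
(default 0.3) of entries zeroed per column (every gene keeps at least
one nonzero loading), lognormal per-spot library-size multipliers
(sigma = 0.3, mean one), and NB counts with mean
sz_i * sum_l W[g,l] * exp(c * f[i,l]) and per-sample dispersion
(default phi = 1).  The factor contrast c defaults to 1.5, i.e.
activities in {1, e^1.5 ~ 4.5}, and loadings are rescaled so the
expected per-spot total is `library_size_mean` (default 2000 over a
500-gene panel — a realistic depth for a top-gene subset).

Two design points matter and are deliberate:

- **Disjoint pattern supports.**  With overlapping supports and the
  activity floor exp(0) = 1, the non-negative factorization admits
  likelihood-equivalent mixed solutions, and even per-spot NB maximum
  likelihood with the *true* loadings cannot separate the factors
  (verified during development).  Disjoint block-like patterns — the
  design used in the simulation studies this generator emulates — make
  recovery well-posed.
- **Known size factors.**  The model treats sz as known, and the
  generator hands the true generating library-size multipliers to the
  fitting stage.  Size factors re-estimated from observed totals absorb
  part of the factor signal (spots where a factor is "on" have larger
  totals) and measurably cap the recovery ceiling.

Scenarios: `rotated` (sample 2's patterns are sample 1's rotated 90
degrees anticlockwise — exact image rotation, so four rotations are the
identity), `absent_factor` (additionally factor 1 is identically zero
in sample 2), `size_diff` (sample 2's grid scaled by `size_ratio`),
`distorted` (sample 2's coordinates smoothly warped before pattern
evaluation), `noise_diff` (identical factors, different dispersions).

What the generator does **not** emulate: platform geometry (hexagonal
Visium lattices, Slide-seq bead placement), segmentation artifacts,
zero inflation beyond NB, gene-gene correlation beyond the low-rank
mean, batch effects in the loadings, or continuous (non-binary) spatial
gradients.  Passing the recovery studies therefore demonstrates that
the estimator identifies shared low-rank structure with sample-specific
smooth spatial organization under NB noise — not that it handles every
artifact of real spatial platforms.

## Evaluation statistics

- **Moran's I** with symmetrized binary k-nearest-neighbor weights
  (default k = 6, the Visium neighborhood size; the weight scheme is
  exposed).  Constant fields return 0 by convention.  Checked against a
  dense double-sum oracle to 1e-12.
- **Factor matching**: Pearson correlation on the concatenation of all
  samples' spots, one-to-one assignment maximizing total correlation
  (exhaustive for <= 8 estimated factors, Hungarian otherwise).
- **patternMarkers-style ranking**: loading rows scaled to unit
  maximum; a gene is assigned to the factor whose unit vector is
  nearest (ties to the lowest factor index) and ranked by that
  distance.  This is this package's reading of the approach; the
  original statistic lives in external software.
- **Annotation association**: in-sample multinomial logistic regression
  of discrete labels on the factors (lbfgs, L2 ridge 1e-6 for
  separation), reporting accuracy and residual deviance.  In-sample by
  design — the statistic is used as an association measure, not a
  claim about out-of-sample prediction.
- **Domain clustering**: seeded k-means on the factor matrix (the
  dependency-light, deterministic stand-in for graph-based clustering
  used in some published analyses), scored by the adjusted Rand index.
- **Goodness of fit**: total Poisson deviance between observed counts
  and fitted NB means.

## Study sizes and reproduction

`scripts/acceptance.py` re-runs the simulation studies from scratch at
desk scale: 2 samples, 15 x 15 grids, 4 true factors, 200 genes,
phi = 1, 500 Adam iterations per fit, training defaults otherwise
(inducing fraction 0.35, n_mc 3, step size 0.01).  These sizes keep a
full run to a few minutes on one CPU while leaving the recovery
behavior intact.  Reported quantities: matched-factor correlations for
the rotated scenario (with and without 2-chunk fitting), Moran's I of
the sample-specific factor in both samples for the absent-factor
scenario, and the goodness-of-fit deviance across L in {2, 4, 6, 8}.

## Known limitations

- The collapsed objective evaluates the factor at the GP conditional
  mean given each Monte-Carlo draw of U and omits the conditional
  variance of F | U.  Consequences observed on synthetic data: learned
  lengthscales are biased short (interpolation uncertainty is free),
  and a truly absent factor's estimate can absorb smooth residual
  structure driven by shared-loading error — its Moran's I settles
  around 0.2-0.3 rather than near zero, even though absence is clearly
  signaled by the collapse of the factor's kernel amplitude (~40x) and
  spot-level standard deviation (~10x) relative to the present sample.
- Dispersion is per-sample and fixed, not gene-specific or estimated.
- The multinomial association fit is in-sample; no cross-validation.
- Factors interpolated far outside the inducing-point hull revert to
  the linear GP mean; extrapolation is not meaningful.
- Runtime scales as O(L n_m^2 N_m) per iteration from the kernel
  solves; very large samples need chunking and a moderate inducing
  fraction.
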