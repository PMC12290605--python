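# Methods

`tvfc` estimates time-varying functional connectivity (TVFC): the
correlation between node time series as a function of scan time. This note
documents the models, the synthetic-data generator, and the numerical and
design choices behind them.

## Estimators

### Static functional connectivity (sFC)

Observations `y_n ∈ R^D` (volumes `1 ≤ n ≤ N`) are assumed zero-mean; the
unbiased covariance estimator is `Σ̂ = (1/(N-1)) Σ_n y_n y_nᵀ` (columns are
demeaned first), and the correlation divides each element by the product of
the corresponding standard deviations. The sFC estimate is the null model
for everything else: a method that cannot beat it on dynamic data has not
detected dynamics.

### Sliding window with cross-validated window length (SW-CV)

A rectangular window of length `ω` seconds slides with a step of one volume.
Before windowing, the series is high-pass filtered (zero-phase 5th-order
Butterworth) at `1/ω` Hz to remove components slower than the window, and
`⌊w/2⌋` zero volumes are padded at each end so an estimate exists at every
volume. Window covariances use the same zero-mean convention as sFC.

The window length is selected by cross-validation: for each candidate `ω`
(default grid: 20 s to 180 s in steps of `2·TR`), each evaluation volume in
the interior (`N_e = N − w_max` points, so every candidate window fits
without padding) is scored under a zero-mean Gaussian whose covariance is
estimated from the surrounding window *excluding* that volume; the `ω`
maximizing the mean log likelihood wins, ties (within 1e-9) going to the
smallest window to favor responsiveness. The CV score is computed on the
raw z-scored series (no per-candidate high-pass): filtering changes the
marginal variance of the data being scored, which would make the Gaussian
likelihoods incomparable across candidates. The filter applies in the final
estimation pass at the chosen window.

### DCC(1,1)-GARCH(1,1)

The standard two-stage quasi-maximum-likelihood scheme. Stage one fits a
GARCH(1,1) volatility model per node, `h_n = ω₀ + a y²_{n-1} + b h_{n-1}`,
giving standardized residuals `z_n = y_n/√h_n`. On conditionally
homoskedastic data the `(a, b)` ridge is unidentified (as `a → 0` any `b`
fits equally well), so the constant-variance solution is preferred unless
the GARCH terms improve the log likelihood by more than one nat. Stage two
maximizes the correlation-targeted DCC likelihood over `(a, b)` of

    Q_n = (1 − a − b) Q̄ + a z_{n-1} z_{n-1}ᵀ + b Q_{n-1},
    R_n = diag(Q_n)^{-1/2} Q_n diag(Q_n)^{-1/2},

with `Q̄` the sample correlation of the residuals. `joint` mode fits one
model over all `D` nodes; `bivariate_loop` fits all `D(D-1)/2` pairs and
assembles the estimates edgewise. Edgewise assembly can break positive
semidefiniteness; raw edgewise values are kept for RMSE and summary
measures (which are edgewise anyway), and a Higham-style nearest-correlation
projection (via statsmodels) is applied only where a joint Gaussian
likelihood is evaluated, with the projection count reported.

### Wishart process (WP)

The covariance process is built from `ν·D` latent Gaussian processes
`f_{d,k} ~ GP(0, k(·,·))` over scan time normalized to `[0, 1]`:

    Σ_n = A F_n F_nᵀ Aᵀ + Λ,

where `F_n` is the `D×ν` matrix of GP evaluations at volume `n`, `A` is a
trained lower-triangular factor (so `A Aᵀ` is the Wishart scale matrix),
and `Λ` is a trained diagonal noise matrix that stabilizes inference. With
`F_n` standard normal, `A F_n F_nᵀ Aᵀ` is Wishart-distributed with `ν`
degrees of freedom; `ν = D` by default. Observations are modeled as
`y_n ~ N(0, Σ_n)`.

The kernel is Matérn 5/2, `k(x,x') = σ²(1 + √5 r + (5/3)r²)e^{-√5 r}` with
`r = |x−x'|/l`; the lengthscale `l` (in units of the normalized scan) plays
the role the window length plays for SW methods.

Inference is sparse variational: each GP carries `M` inducing points on a
uniform grid over `[0, 1]` with a Gaussian variational posterior in the
whitened parameterization (`u = L_z v`, `q(v) = N(μ, S)`, `S` stored via its
Cholesky factor). The evidence lower bound

    ELBO = Σ_n E_q[log p(y_n | F_n)] − Σ_{d,k} KL(q(U_{d,k}) ‖ p(U_{d,k}))

is maximized with Adam. The expectation is estimated by the
reparameterization trick; gradients are analytic for all parameters except
the two kernel hyperparameters, which use forward finite differences
(h = 1e-4 on the unconstrained scale) sharing the same reparameterization
draw — in the whitened parameterization the KL term does not depend on the
kernel, so the difference isolates the likelihood term. Positivity
(diagonals of `A` and the variational Cholesky factors, `Λ`, kernel
parameters) is enforced by softplus transforms.

Optimizer schedule: learning rate 0.01, single-sample gradients for the
first 600 iterations, then gradients averaged over 3 MC draws until a
100-iteration moving average of the ELBO stops improving (relative
tolerance 1e-4). The two-phase schedule matters: persistent single-sample
gradient noise measurably inflates `Λ` (the noise parameter absorbs
optimizer stochasticity) and shrinks the correlation amplitude. Antithetic
sampling is deliberately *not* used: at the symmetric initialization
`μ = 0` the expected gradient of the variational means vanishes, and it is
the odd-order sampling noise that breaks this saddle — cancelling it makes
fits collapse to a static solution.

The TVFC estimate at query locations draws `F` from the variational
marginals (3000 samples by default), maps each draw through
`A F Fᵀ Aᵀ + Λ`, converts to correlation, and reports the elementwise mean
with a mean ± 2 SD band. `Λ` stays inside the correlation: it is part of
the model's covariance of `y`, and removing it makes the rank-`ν` sample
correlations saturate near ±1. Because the GPs are continuous in time, the
posterior can be queried between (or beyond) training volumes, which is how
the WP handles the imputation benchmark without interpolation.

Defaults follow the reference configuration (`ν = D`, `M = min(200, N)`, up
to 5000 iterations). The benchmark drivers and tests use 16–24 inducing
points and 1500–3000 iteration caps — at the simulation sizes used here
(`N = 400`, `D ≤ 3`, slow structures) this reaches the same optima at
roughly 5–25 s per fit; for noisy (SNR-2) data the fully averaged schedule
(`n_mc = 3` throughout) is used because the likelihood surface is noisier.
Measured recovery at `N = 400`: constant-0.8 RMSE ≈ 0.03, null ≈ 0.03,
slow periodic ≈ 0.15 noiseless and ≈ 0.10–0.18 at SNR 2.

## Synthetic data

Seven deterministic covariance profiles `σ(n)` define how the coupling
varies: null (0), constant (0.8), slow and fast periodic (one and three
full sine periods, amplitude 0.8), stepwise (0 → 0.8 → −0.6 on thirds,
two change points), state transitions (eight equal segments cycling through
{0.1, 0.5, −0.3, 0.7}), and boxcar (square wave of period N/4 convolved
with a canonical double-gamma HRF — peak 6 s, undershoot 16 s, ratio 1/6 —
renormalized to peak 0.8). The exact amplitudes and change-point locations
of the stepwise/state/boxcar shapes are package choices; only the shapes
are canonical. All are overridable.

Profiles expand into matrix trajectories: bivariate (`D = 2`, unit
diagonal, `σ(n)` off-diagonal), dense (`D ≥ 3`, all off-diagonals share
`σ(n)`), and sparse (only nodes 0 and 1 coupled). The dense equicorrelation
matrix is PSD iff `σ ≥ −1/(D−1)`, so negative profile values are shrunk by
the factor that maps the profile minimum onto that bound (5/8 for `D = 3`),
leaving non-negative values — in particular the null and constant anchors —
untouched.

Observations are independent Gaussian draws `y_n ~ N(0, Σ_n)`, columns then
z-scored. Noise is mixed as `y* = α y + (1−α) ε` with SNR `= α/(1−α)`
(SNR 2 ⇒ α = 2/3). The noise source is AR(1) with lag-1 autocorrelation
0.4 and unit marginal variance, columns independent — a synthetic stand-in
that reproduces the temporal autocorrelation of BOLD noise but none of its
spatial structure, spectral content, or nonstationarity; passing tests on
this noise therefore says nothing about robustness to scanner artifacts or
physiological confounds. Under signal/noise independence the observable
correlation shrinks to

    ρ*_ij = α² σ_ij / √((α² σ_ii + (1−α)² v_i)(α² σ_jj + (1−α)² v_j)),

which is the ground truth used for scoring noisy trials (verified by Monte
Carlo in the tests). Default TR is 2 s; benchmark defaults are N = 400
volumes and 20 trials per condition (a desk-scale choice; the trial count
is a parameter).

## Benchmarks

Recovery is scored as the RMSE between estimated and true correlations —
over the single off-diagonal for bivariate data, over all matrix elements
for `D ≥ 3`. The imputation benchmark splits a scan leave-every-other-out
(odd volumes train, even volumes test, both keeping their original time
stamps), fits each method on the training half, and scores the mean
zero-mean Gaussian log likelihood of the test volumes under the method's
covariance estimates at the test locations — the WP queries its posterior
there directly, all other methods are interpolated elementwise linearly
between their training-location estimates. Scoring uses correlation-scale
matrices for every method (the data are z-scored, so correlation and
covariance coincide up to sampling error), keeping scores comparable.
Method comparisons are two-tailed t-tests on per-trial scores with
Bonferroni correction over method pairs, plus Cohen's D.

Summary measures per edge: mean, variance (population convention, `1/N`),
and rate-of-change — the mean absolute relative difference between
subsequent estimates. The rate-of-change divides by the previous estimate,
which can be near zero on null edges; terms with `|previous| < 1e-3` are
skipped, the denominator reduced accordingly, and the skipped fraction
reported.

## Downstream statistics

- **Morphometricity**: the linear mixed model `y = Xβ + a + ε` with
  `a ~ N(0, σ_a² K)` and a Gaussian similarity kernel
  `K[s,s'] = exp(−‖x_s − x_s'‖²)` on column-standardized subject feature
  vectors (bandwidth 1 on the standardized scale; a median-heuristic
  bandwidth is available behind a flag). REML estimation profiles the fixed
  effects and residual scale and maximizes over the variance ratio
  `γ = σ_a²/σ_e²` by bounded scalar search on `log γ` (tolerance 1e-8)
  after a single eigendecomposition of `K`; `m² = γ/(1+γ)` clipped to
  [0, 1].
- **ICC** per edge: one-way random-effects ANOVA (ICC(1,1) convention);
  negative between-subject moment estimates are clipped to zero.
- **I2C2**: whole-image reliability `tr(K_X)/tr(K_X + K_U)` from
  method-of-moments trace estimates (within-subject error covariance from
  session deviations, between-subject covariance of subject means minus
  `K_U/J`), clipped at zero.
- **Brain states**: k-means (k = 3 by default, 10 restarts, seeded) on
  pooled lower-triangular correlation vectors; a switch is a change of
  state label between consecutive volumes of one scan.
- **Stimulus GLM**: each TVFC edge series is regressed on an HRF-convolved
  stimulus boxcar plus Legendre polynomial drift regressors of order
  `round(TR·N/150)` (round half up, minimum 1 — at order 1 the design has
  the three-regressor form: stimulus, offset, linear trend; the order
  formula can exceed 1 for long scans, in which case the drift basis grows
  accordingly). One-sided p-values (default direction: negative coupling,
  the expected stimulus-induced decorrelation) are Bonferroni-corrected
  over edges.

Synthetic cohort generators plant known values of every quantity these
statistics estimate (variance components for ICC/I2C2, a kernel-linked
phenotype with known `m²`, state sequences with known switch counts), so
each statistic is tested as a recovery problem.

## Numerical notes and limitations

- All PSD checks tolerate eigenvalues down to −1e-10; variational and
  kernel Gram matrices carry a 1e-6·σ² jitter.
- The WP fit is non-convex and MC-noisy; different optimizer seeds give
  correlation trajectories differing by a few hundredths RMSE. Fits roll
  back to the last finite state if the loss diverges.
- Degenerate inputs are rejected loudly (constant columns for correlation,
  non-monotone time stamps, windows shorter than two volumes, cutoffs at or
  above Nyquist, non-stationary AR coefficients).
- Bivariate-loop DCC and state-transition-style covariance remain hard for
  every estimator here; sudden change points are smoothed over by the WP's
  Matérn prior, and that is expected behavior, not a defect.
- The generator draws volumes independently given `Σ_n`; real BOLD has
  temporal autocorrelation in the *signal*, not only in the added noise,
  and no motion artifacts, drifts, or non-Gaussian tails. Conclusions from
  these benchmarks transfer to real data only as directional expectations.
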