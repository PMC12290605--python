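# tvfc — time-varying functional connectivity with Wishart processes

Functional connectivity (FC) summarizes the statistical coupling between
brain-region time series — in fMRI, the correlation between BOLD signals.
Classical FC assumes one correlation matrix per scan; *time-varying* FC
(TVFC) estimates the correlation as a function of scan time, which is where
the interesting neuroscience (state switching, task-induced coupling,
subject differences in dynamics) lives, and where estimation methods
disagree the most.

`tvfc` implements a Wishart-process estimator alongside the standard
baselines, plus the benchmarking framework needed to compare them when the
true covariance is unobservable:

- **WP** (`tvfc.wishart`): a Wishart process built from ν·D sparse
  variational Gaussian processes with a Matérn 5/2 kernel,
  `Σ_n = A F_n F_nᵀ Aᵀ + Λ`, fitted by maximizing a Monte-Carlo ELBO with
  Adam. Posterior TVFC can be queried at *any* time point, with uncertainty
  bands.
- **sFC** (`tvfc.baselines.static_fc`): the whole-scan estimate
  `Σ̂ = (1/(N−1)) Σ_n y_n y_nᵀ` — the null model every dynamic method must
  beat.
- **SW-CV** (`tvfc.baselines.sw_cv_tvfc`): sliding-window correlation whose
  window length is selected by maximizing held-out Gaussian log likelihood
  over a 20–180 s grid.
- **DCC** (`tvfc.baselines.dcc_tvfc`): DCC(1,1)-GARCH(1,1) dynamic
  conditional correlation, trained jointly or pairwise.
- **Benchmarks** (`tvfc.simkit`, `tvfc.benchmarks`): seven synthetic
  covariance structures (null, constant, slow/fast periodic, stepwise,
  state transitions, HRF-convolved boxcar), AR(1) surrogate noise mixed at
  a chosen SNR with the ground truth adjusted accordingly, RMSE recovery
  scoring, a leave-every-other-out imputation benchmark, and per-edge
  summary measures (mean, variance, rate-of-change).
- **Downstream statistics** (`tvfc.downstream`): morphometricity (REML
  variance components on a subject-similarity kernel), edgewise ICC and
  whole-image I2C2 reliability, k-means brain states with switch counts,
  and a stimulus-prediction GLM.

See `docs/methods.md` for the models, assumptions, and numerical choices.

## Worked example

Simulate a bivariate scan whose coupling follows a slow sine wave
(amplitude 0.8), mixed with AR(1) surrogate noise at SNR 2, and compare all
estimators against the noise-adjusted ground truth:

```python
from tvfc import simkit, wishart, benchmarks

data, truth = simkit.simulate_dataset("periodic_slow", n=400, d=2, snr=2.0, seed=1)

cfg = wishart.WPConfig(m=24, max_iter=3000, n_mc=3, seed=0)
ests = {
    "sFC": benchmarks.estimate_tvfc(data, "sfc"),
    "SW-CV": benchmarks.estimate_tvfc(data, "sw_cv"),
    "DCC-J": benchmarks.estimate_tvfc(data, "dcc_joint"),
    "WP": benchmarks.estimate_tvfc(data, "wp", wp_config=cfg),
}
print("chosen window (s):", ests["SW-CV"].meta["omega_hat_s"])
for name, est in ests.items():
    print(f"{name:6s} RMSE vs adjusted truth: {benchmarks.rmse_corr(est, truth):.3f}")
print(f"imputation test log-lik: WP {benchmarks.impute_with_method(data, 'wp', wp_config=cfg):.3f}"
      f"  sFC {benchmarks.impute_with_method(data, 'sfc'):.3f}")
```

Output:

```
chosen window (s): 160.0
sFC    RMSE vs adjusted truth: 0.463
SW-CV  RMSE vs adjusted truth: 0.113
DCC-J  RMSE vs adjusted truth: 0.176
WP     RMSE vs adjusted truth: 0.129
imputation test log-lik: WP -2.740  sFC -2.809
```

Reading the numbers: the static estimate cannot track the oscillation, so
its RMSE (~0.46) is near the RMS of the sine itself; the dynamic methods
track it to within 0.11–0.18. The imputation benchmark tells the same story
without needing the ground truth — the WP predicts held-out volumes ~0.07
nats per volume better than the static model. On *null* data all methods
score alike and the WP stays flat where sliding windows see spurious
dynamics; that contrast is what the test suite checks end to end.

## Command line

```sh
tvfc simulate --kind periodic_slow --n 400 --d 2 --snr 2 --seed 1 --out run/
tvfc estimate run/periodic_slow_timeseries.tsv --method sw_cv --out run/est.tsv
tvfc benchmark impute --methods sfc,sw_cv --structures null,periodic_slow \
     --trials 5 --seed 1 --out run/bench
tvfc summarize run/est.tsv --out run/summary.tsv
```

All formats are TSV (time series: `time` + node columns; trajectories:
long-format `n, i, j, value`) with JSON sidecars carrying the resolved
configuration, seed, and package version; identical seeds reproduce
identical outputs.

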