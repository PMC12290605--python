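"""Synthetic covariance structures and fMRI-like observation generators.

Seven deterministic covariance profiles sigma(n) (null, constant, slow and
fast periodic, stepwise, state transitions, HRF-convolved boxcar) define how
the coupling between nodes varies over a scan. Observations are drawn
independently per volume from a zero-mean Gaussian with the corresponding
covariance matrix, optionally mixed with autocorrelated surrogate noise at a
chosen signal-to-noise ratio; the ground truth is adjusted to the
correlations actually present in the mixed data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from tvfc.datatypes import CovTrajectory, TimeSeriesData

PROFILE_KINDS = (
    "null",
    "constant",
    "periodic_slow",
    "periodic_fast",
    "stepwise",
    "state_transition",
    "boxcar",
)

TOPOLOGIES = ("bivariate", "dense", "sparse")

#: default coupling amplitude shared by the non-null profiles
DEFAULT_AMPLITUDE = 0.8
#: default repetition time in seconds for synthetic scans
DEFAULT_TR = 2.0


@dataclass
class CovProfile:
    """A scalar covariance term sigma(n) over N volumes, in [-1, 1]."""

    kind: str
    n: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.n,):
            raise ValueError("values must have length N")
        if np.any(np.abs(self.values) > 1 + 1e-12):
            raise ValueError("profile values must lie in [-1, 1]")


@dataclass
class NoiseModel:
    """Signal/noise mixing weights and the noise matrix itself.

    The mixture y* = alpha * y + (1 - alpha) * eps has signal-to-noise ratio
    SNR = alpha / (1 - alpha).
    """

    alpha: float
    snr: float
    e: np.ndarray
    ar_coef: float

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if abs(self.snr - self.alpha / (1.0 - self.alpha)) > 1e-12:
            raise ValueError("snr must equal alpha / (1 - alpha)")

    @classmethod
    def from_snr(cls, snr: float, e: np.ndarray, ar_coef: float) -> "NoiseModel":
        if snr <= 0:
            raise ValueError("snr must be positive")
        alpha = snr / (1.0 + snr)
        return cls(alpha=alpha, snr=snr, e=e, ar_coef=ar_coef)


def hrf_double_gamma(tr: float, duration: float = 32.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response sampled every TR seconds.

    Response peak at 6 s, undershoot peak at 16 s, undershoot ratio 1/6;
    normalized to unit peak.
    """
    t = np.arange(0.0, duration, tr)
    h = stats.gamma.pdf(t, 6.0) - stats.gamma.pdf(t, 16.0) / 6.0
    return h / h.max()


def covariance_profile(
    kind: str,
    n: int,
    amplitude: float = DEFAULT_AMPLITUDE,
    tr: float = DEFAULT_TR,
) -> CovProfile:
    """Build one of the named sigma(n) profiles over ``n`` volumes.

    Profiles (index ``m`` runs 0..N-1):

    - ``null``: 0 everywhere (uncorrelated series).
    - ``constant``: the amplitude (default 0.8) everywhere.
    - ``periodic_slow`` / ``periodic_fast``: amplitude * sin(2 pi p m / N)
      with one (slow) or three (fast) full periods over the scan.
    - ``stepwise``: two large change points — 0, then 0.8, then -0.6 on
      equal thirds.
    - ``state_transition``: eight equal segments cycling through the four
      levels {0.1, 0.5, -0.3, 0.7}.
    - ``boxcar``: a square wave (period N/4, levels {0, amplitude})
      convolved with the canonical double-gamma HRF, renormalized so its
      peak equals the amplitude.
    """
    if kind not in PROFILE_KINDS:
        raise ValueError(f"unknown profile kind {kind!r}; valid kinds: {PROFILE_KINDS}")
    if n < 2:
        raise ValueError("need at least two time steps")
    m = np.arange(n)
    if kind == "null":
        values = np.zeros(n)
    elif kind == "constant":
        values = np.full(n, amplitude)
    elif kind in ("periodic_slow", "periodic_fast"):
        periods = 1 if kind == "periodic_slow" else 3
        values = amplitude * np.sin(2.0 * np.pi * periods * m / n)
    elif kind == "stepwise":
        values = np.where(m < n / 3, 0.0, np.where(m < 2 * n / 3, 0.8, -0.6))
    elif kind == "state_transition":
        levels = np.array([0.1, 0.5, -0.3, 0.7])
        segment = np.minimum((8 * m) // n, 7)
        values = levels[segment % 4]
    else:  # boxcar
        period = max(n // 4, 2)
        square = np.where((m % period) < period / 2, amplitude, 0.0)
        h = hrf_double_gamma(tr)
        conv = signal.convolve(square, h, mode="full")[:n]
        peak = np.abs(conv).max()
        values = conv / peak * amplitude if peak > 0 else conv
    return CovProfile(kind=kind, n=n, values=values)


def assemble_trajectory(
    profile: CovProfile, d: int = 2, topology: str = "bivariate"
) -> CovTrajectory:
    """Expand a scalar profile into a sequence of D x D covariance matrices.

    - ``bivariate`` (D=2): unit diagonal, sigma(n) off-diagonal.
    - ``dense`` (D>=3): all off-diagonals share sigma(n). Negative profile
      values are shrunk into [-1/(D-1), 0] so every matrix stays PSD (the
      equicorrelation matrix is PSD iff sigma >= -1/(D-1)); non-negative
      values are unchanged.
    - ``sparse`` (D>=3): only nodes 0 and 1 are coupled by sigma(n), the
      remaining nodes are independent.
    """
    if topology not in TOPOLOGIES:
        raise ValueError(f"unknown topology {topology!r}; valid: {TOPOLOGIES}")
    if topology == "bivariate" and d != 2:
        raise ValueError("bivariate topology requires D=2")
    if topology in ("dense", "sparse") and d < 3:
        raise ValueError(f"{topology} topology requires D>=3")

    values = profile.values
    n = profile.n
    sigmas = np.tile(np.eye(d), (n, 1, 1))
    if topology == "dense":
        bound = 1.0 / (d - 1)
        scale = bound / max(np.abs(values.min()), bound) if values.min() < 0 else 1.0
        adj = np.where(values < 0, values * scale, values)
        off = ~np.eye(d, dtype=bool)
        sigmas[:, off] = adj[:, None]
    else:
        sigmas[:, 0, 1] = values
        sigmas[:, 1, 0] = values

    traj = CovTrajectory(sigmas=sigmas, topology=topology, meta={"kind": profile.kind})
    traj.require_psd()
    return traj


def _matrix_sqrt_factors(sigmas: np.ndarray) -> np.ndarray:
    """Cholesky factors, falling back to eigendecomposition if singular."""
    try:
        return np.linalg.cholesky(sigmas)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(sigmas)
        if w.min() < -1e-10:
            raise ValueError("covariance trajectory is not PSD")
        return v * np.sqrt(np.clip(w, 0.0, None))[:, None, :]


def sample_timeseries(
    traj: CovTrajectory,
    seed: int,
    tr: float = DEFAULT_TR,
    zscore: bool = True,
) -> TimeSeriesData:
    """Draw y_n ~ N(0, Sigma_n) independently across volumes.

    Columns are then individually normalized to zero mean and unit standard
    deviation (the convention used throughout the benchmarks); pass
    ``zscore=False`` for raw draws. Deterministic given the seed.
    """
    traj.require_psd()
    rng = np.random.default_rng(seed)
    factors = _matrix_sqrt_factors(traj.sigmas)
    eps = rng.standard_normal((traj.n, traj.d))
    y = np.einsum("nij,nj->ni", factors, eps)
    data = TimeSeriesData(y=y, tr=tr, seed=seed)
    return data.zscored() if zscore else data


def surrogate_noise(n: int, d: int, ar_coef: float = 0.4, seed: int | None = None) -> np.ndarray:
    """Mutually independent AR(1) noise columns with unit marginal variance.

    A stand-in noise source with BOLD-like temporal autocorrelation
    (lag-1 autocorrelation ``ar_coef``); columns are uncorrelated in
    expectation so no covariance structure beyond the simulated ground
    truth is introduced.
    """
    if not 0 <= ar_coef < 1:
        raise ValueError("ar_coef must lie in [0, 1) for stationarity")
    rng = np.random.default_rng(seed)
    w = rng.standard_normal((n, d))
    if ar_coef == 0:
        return w
    # x_t = phi x_{t-1} + sqrt(1-phi^2) w_t, started from stationarity
    x0 = rng.standard_normal(d)
    innov = np.sqrt(1.0 - ar_coef**2) * w
    innov[0] += 0.0
    x = signal.lfilter([1.0], [1.0, -ar_coef], innov, axis=0, zi=(ar_coef * x0)[None, :])[0]
    return x


def mix_noise(y: np.ndarray, e: np.ndarray, snr: float) -> tuple[np.ndarray, float]:
    """Mix signal and noise as y* = alpha y + (1 - alpha) e, SNR = alpha/(1-alpha)."""
    y = np.asarray(y, dtype=float)
    e = np.asarray(e, dtype=float)
    if y.shape != e.shape:
        raise ValueError(f"signal shape {y.shape} != noise shape {e.shape}")
    if snr <= 0:
        raise ValueError("snr must be positive")
    alpha = snr / (1.0 + snr)
    return alpha * y + (1.0 - alpha) * e, alpha


def adjust_ground_truth(
    traj: CovTrajectory,
    alpha: float,
    noise_variances: np.ndarray | float = 1.0,
) -> CovTrajectory:
    """Ground-truth correlations of the signal/noise mixture.

    With independent signal and noise, Cov(y*) = alpha^2 Sigma + (1-alpha)^2
    diag(v), so the observable correlation of edge (i, j) shrinks to

        rho*_ij(n) = alpha^2 sigma_ij(n) /
                     sqrt((alpha^2 sigma_ii + (1-alpha)^2 v_i)
                          (alpha^2 sigma_jj + (1-alpha)^2 v_j)).

    Returns a correlation-scale trajectory (unit diagonal).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    v = np.broadcast_to(np.asarray(noise_variances, dtype=float), (traj.d,))
    if np.any(v <= 0):
        raise ValueError("noise variances must be positive")
    sig_diag = np.diagonal(traj.sigmas, axis1=1, axis2=2)
    total_var = alpha**2 * sig_diag + (1.0 - alpha) ** 2 * v  # (N, D)
    denom = np.sqrt(total_var[:, :, None] * total_var[:, None, :])
    adjusted = alpha**2 * traj.sigmas / denom
    idx = np.arange(traj.d)
    adjusted[:, idx, idx] = 1.0
    meta = dict(traj.meta, alpha=alpha)
    return CovTrajectory(sigmas=adjusted, x=traj.x, topology=traj.topology, meta=meta)


def simulate_dataset(
    kind: str,
    n: int = 400,
    d: int = 2,
    topology: str = "bivariate",
    snr: float | None = None,
    ar_coef: float = 0.4,
    tr: float = DEFAULT_TR,
    seed: int | None = None,
) -> tuple[TimeSeriesData, CovTrajectory]:
    """Generate one synthetic scan plus its (noise-adjusted) ground truth.

    Convenience wrapper: profile -> trajectory -> Gaussian sampling ->
    optional SNR mixing with AR(1) surrogate noise. The returned truth is on
    the correlation scale, adjusted for the mixing when ``snr`` is given.
    """
    profile = covariance_profile(kind, n, tr=tr)
    traj = assemble_trajectory(profile, d=d, topology=topology)
    data = sample_timeseries(traj, seed=seed, tr=tr)
    truth = traj.to_corr()
    if snr is not None:
        rng = np.random.default_rng(seed)
        noise_seed = int(rng.integers(0, 2**31 - 1)) + 1
        e = surrogate_noise(n, d, ar_coef=ar_coef, seed=noise_seed)
        mixed, alpha = mix_noise(data.y, e, snr)
        data = TimeSeriesData(y=mixed, tr=tr, x=data.x, seed=seed).zscored()
        truth = adjust_ground_truth(traj, alpha, noise_variances=1.0)
    truth = CovTrajectory(
        sigmas=truth.sigmas, x=truth.x, topology=topology,
        meta=dict(truth.meta, snr=snr, seed=seed),
    )
    return data, truth
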