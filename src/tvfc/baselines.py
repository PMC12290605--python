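"""Baseline TVFC estimators: static FC, sliding window, and DCC-GARCH.

The sliding-window estimator uses a rectangular window with a step of one
volume, a 5th-order zero-phase Butterworth high-pass at 1/window before
estimation, and zero padding at the scan edges; its window length can be
chosen by cross-validation (maximizing the held-out zero-mean Gaussian log
likelihood of evaluation volumes). The DCC(1,1)-GARCH(1,1) estimator follows
the standard two-stage quasi-maximum-likelihood form with correlation
targeting, and can be trained jointly over all nodes or as a loop over all
node pairs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, signal

from tvfc.datatypes import CovTrajectory, TimeSeriesData, cov_to_corr

#: default cross-validation window bounds, seconds
OMEGA_MIN_S = 20.0
OMEGA_MAX_S = 180.0


# ---------------------------------------------------------------------------
# static FC

def static_fc(y: np.ndarray | TimeSeriesData) -> tuple[np.ndarray, np.ndarray]:
    """Whole-scan covariance and Pearson correlation.

    Columns are demeaned, then Sigma = (1/(N-1)) sum_n y_n y_n^T (the
    unbiased zero-mean-convention estimator); the correlation divides each
    element by the product of the standard deviations.
    """
    y = y.y if isinstance(y, TimeSeriesData) else np.asarray(y, dtype=float)
    if y.shape[0] < 2:
        raise ValueError("need at least two time steps")
    yc = y - y.mean(axis=0)
    cov = yc.T @ yc / (y.shape[0] - 1)
    if np.any(np.diag(cov) <= 0):
        bad = np.flatnonzero(np.diag(cov) <= 0)
        raise ValueError(f"constant column(s) {bad.tolist()}: correlation undefined")
    return cov, cov_to_corr(cov)


# ---------------------------------------------------------------------------
# sliding window

def highpass_filter(y: np.ndarray, cutoff_hz: float, tr: float) -> np.ndarray:
    """Zero-phase 5th-order Butterworth high-pass, applied per column."""
    y = np.atleast_2d(np.asarray(y, dtype=float))
    nyquist = 0.5 / tr
    if cutoff_hz >= nyquist:
        raise ValueError(f"cutoff {cutoff_hz:.4g} Hz >= Nyquist {nyquist:.4g} Hz")
    sos = signal.butter(5, cutoff_hz, btype="highpass", fs=1.0 / tr, output="sos")
    return signal.sosfiltfilt(sos, y, axis=0)


def _window_volumes(omega_s: float, tr: float) -> int:
    return int(round(omega_s / tr))


def sw_tvfc(
    data: TimeSeriesData,
    omega_s: float,
    filter_highpass: bool = True,
) -> CovTrajectory:
    """Sliding-window correlation with a rectangular window of ``omega_s`` seconds.

    The series is high-passed at 1/omega (skipped when the cutoff would meet
    the Nyquist frequency), zero-padded by half a window on both sides, and
    the zero-mean-convention covariance is computed in each window with a
    step of one volume, yielding one correlation matrix per volume.
    """
    w = _window_volumes(omega_s, data.tr)
    if w < 2:
        raise ValueError(f"window of {omega_s} s is shorter than 2 volumes at TR={data.tr}")
    y = np.asarray(data.y, dtype=float)
    cutoff = 1.0 / omega_s
    if filter_highpass and cutoff < 0.95 * (0.5 / data.tr):
        y = highpass_filter(y, cutoff, data.tr)
    pad = w // 2
    padded = np.pad(y, ((pad, pad), (0, 0)))
    outer = padded[:, :, None] * padded[:, None, :]
    csum = np.concatenate([np.zeros((1, data.d, data.d)), np.cumsum(outer, axis=0)])
    # window starting at padded index n covers original volumes centred at n
    starts = np.arange(data.n)
    sums = csum[starts + w] - csum[starts]
    cov = sums / (w - 1)
    # guard against all-zero edge windows
    idx = np.arange(data.d)
    cov[:, idx, idx] = np.maximum(cov[:, idx, idx], 1e-12)
    return CovTrajectory(
        sigmas=cov_to_corr(cov), x=data.x, meta={"method": "sw", "omega_s": omega_s}
    )


def cv_window_length(
    data: TimeSeriesData,
    grid_s: np.ndarray | None = None,
    omega_min_s: float = OMEGA_MIN_S,
    omega_max_s: float = OMEGA_MAX_S,
) -> tuple[float, pd.DataFrame]:
    """Choose the window length by leave-one-volume-out likelihood.

    For each candidate window, every evaluation volume n in the interior
    (all n such that the longest candidate window fits, N_e = N - w_max
    points) is scored under a zero-mean Gaussian whose covariance is
    estimated from the surrounding window *excluding* volume n; the window
    maximizing the mean log likelihood wins. Ties within 1e-9 go to the
    smallest window (favors responsiveness).

    Returns the chosen window length (seconds) and the full score table.
    """
    if grid_s is None:
        grid_s = np.arange(omega_min_s, omega_max_s + 1e-9, 2.0 * data.tr)
    grid_s = np.asarray(grid_s, dtype=float)
    if np.any((grid_s < omega_min_s - 1e-9) | (grid_s > omega_max_s + 1e-9)):
        raise ValueError("candidate grid outside [omega_min, omega_max]")
    y = np.asarray(data.y, dtype=float)
    n, d = y.shape
    wmax = _window_volumes(grid_s.max(), data.tr)
    n_eval = n - wmax
    if n_eval <= 0:
        raise ValueError(f"series too short (N={n}) for the longest window ({wmax} volumes)")
    lo = wmax // 2
    eval_idx = np.arange(lo, lo + n_eval)

    outer = y[:, :, None] * y[:, None, :]
    csum = np.concatenate([np.zeros((1, d, d)), np.cumsum(outer, axis=0)])
    scores = np.empty(grid_s.shape[0])
    const = -0.5 * d * math.log(2.0 * math.pi)
    for gi, omega in enumerate(grid_s):
        w = _window_volumes(omega, data.tr)
        starts = eval_idx - w // 2
        sums = csum[starts + w] - csum[starts] - outer[eval_idx]
        cov = sums / (w - 2)  # w - 1 samples after excluding n, unbiased
        sign, logdet = np.linalg.slogdet(cov)
        quad = np.einsum(
            "ni,nij,nj->n", y[eval_idx], np.linalg.inv(cov), y[eval_idx]
        )
        ll = const - 0.5 * logdet - 0.5 * quad
        ll[sign <= 0] = -np.inf
        scores[gi] = ll.mean()
    table = pd.DataFrame({"omega_s": grid_s, "mean_loglik": scores})
    best = scores.max()
    omega_hat = float(grid_s[scores >= best - 1e-9].min())
    return omega_hat, table


def sw_cv_tvfc(data: TimeSeriesData, grid_s: np.ndarray | None = None, **kwargs) -> CovTrajectory:
    """Sliding-window estimate at the cross-validated window length."""
    omega_hat, table = cv_window_length(data, grid_s=grid_s, **kwargs)
    traj = sw_tvfc(data, omega_hat)
    traj.meta.update(method="sw_cv", omega_hat_s=omega_hat,
                     window_scores=table.to_dict("list"))
    return traj


# ---------------------------------------------------------------------------
# GARCH(1,1) / DCC(1,1)

@dataclass
class GarchParams:
    """Univariate GARCH(1,1) quasi-maximum-likelihood estimates."""

    omega0: float
    a_arch: float
    b_garch: float
    uncond_var: float
    loglik: float
    at_boundary: bool


def _garch_variance_path(y2: np.ndarray, omega0: float, a: float, b: float, h0: float) -> np.ndarray:
    # h_n = omega0 + a y^2_{n-1} + b h_{n-1}, started at h_0 = h0
    c = omega0 + a * np.concatenate([[0.0], y2[:-1]])
    c[0] = h0
    return signal.lfilter([1.0], [1.0, -b], c, zi=[0.0])[0]


def garch11_fit(y: np.ndarray) -> tuple[GarchParams, np.ndarray]:
    """Fit a GARCH(1,1) volatility model by quasi-maximum likelihood.

    Returns the parameters and the standardized residuals z_n = y_n / sqrt(h_n).
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.shape[0]
    if n < 10:
        raise ValueError("series too short for GARCH estimation")
    hbar = float(np.var(y))
    if hbar <= 1e-12:
        raise ValueError("degenerate (constant) series: variance undefined")
    y2 = y**2

    def nll(theta):
        omega0, a, b = theta
        if omega0 <= 0 or a < 0 or b < 0 or a + b >= 0.999:
            return 1e10 * (1.0 + max(a + b - 0.999, 0.0))
        h = _garch_variance_path(y2, omega0, a, b, hbar)
        if np.any(h <= 0):
            return 1e10
        return 0.5 * float(np.sum(np.log(h) + y2 / h))

    best = None
    for a0, b0 in ((0.05, 0.85), (0.1, 0.5)):
        x0 = np.array([hbar * (1 - a0 - b0), a0, b0])
        res = optimize.minimize(
            nll, x0, method="Nelder-Mead",
            options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    omega0, a, b = best.x
    # on conditionally homoskedastic data the (a, b) ridge is unidentified;
    # prefer the constant-variance model unless GARCH terms earn >1 nat
    if nll(np.array([hbar, 0.0, 0.0])) - best.fun < 1.0:
        omega0, a, b = hbar, 0.0, 0.0
    a, b = max(a, 0.0), max(b, 0.0)
    h = _garch_variance_path(y2, omega0, a, b, hbar)
    z = y / np.sqrt(h)
    at_boundary = a + b > 0.995
    if at_boundary:
        warnings.warn("GARCH(1,1) estimate at the stationarity boundary (a+b ~ 1)")
    params = GarchParams(
        omega0=float(omega0), a_arch=float(a), b_garch=float(b),
        uncond_var=float(omega0 / max(1.0 - a - b, 1e-6)),
        loglik=-float(best.fun) - 0.5 * n * math.log(2 * math.pi),
        at_boundary=at_boundary,
    )
    return params, z


@dataclass
class DccParams:
    """DCC(1,1) stage-two estimates on GARCH-standardized residuals."""

    a: float
    b: float
    qbar: np.ndarray
    mode: str
    loglik: float


def dcc_recursion(z: np.ndarray, a: float, b: float, qbar: np.ndarray) -> np.ndarray:
    """Conditional correlation path R_n of the DCC(1,1) recursion.

    Q_n = (1 - a - b) Qbar + a z_{n-1} z_{n-1}^T + b Q_{n-1}, started at
    Q_0 = Qbar, then R_n = diag(Q_n)^{-1/2} Q_n diag(Q_n)^{-1/2}.
    """
    z = np.atleast_2d(np.asarray(z, dtype=float))
    n, d = z.shape
    outer = z[:, :, None] * z[:, None, :]
    c = (1.0 - a - b) * qbar[None] + a * np.concatenate([np.zeros((1, d, d)), outer[:-1]])
    c[0] = qbar
    q = signal.lfilter([1.0], [1.0, -b], c.reshape(n, d * d), axis=0, zi=np.zeros((1, d * d)))[0]
    q = q.reshape(n, d, d)
    sd = np.sqrt(np.diagonal(q, axis1=1, axis2=2))
    r = q / (sd[:, :, None] * sd[:, None, :])
    idx = np.arange(d)
    r[:, idx, idx] = 1.0
    return r


def _dcc_nll(z: np.ndarray, a: float, b: float, qbar: np.ndarray) -> float:
    r = dcc_recursion(z, a, b, qbar)
    sign, logdet = np.linalg.slogdet(r)
    if np.any(sign <= 0):
        return 1e10
    quad = np.einsum("ni,nij,nj->n", z, np.linalg.inv(r), z)
    return 0.5 * float(np.sum(logdet + quad - np.sum(z**2, axis=1)))


def dcc_fit(z: np.ndarray) -> DccParams:
    """Stage-two DCC(1,1) QML with correlation targeting (Qbar = sample corr)."""
    z = np.atleast_2d(np.asarray(z, dtype=float))
    qbar = np.corrcoef(z, rowvar=False)
    qbar = np.atleast_2d(qbar)

    def nll(theta):
        a, b = theta
        if a < 0 or b < 0 or a + b >= 0.999:
            return 1e10 * (1.0 + max(a + b - 0.999, 0.0))
        return _dcc_nll(z, a, b, qbar)

    best = None
    for x0 in ((0.05, 0.9), (0.02, 0.5)):
        res = optimize.minimize(
            nll, np.asarray(x0), method="Nelder-Mead",
            options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 1000},
        )
        if best is None or res.fun < best.fun:
            best = res
    a, b = np.maximum(best.x, 0.0)
    return DccParams(a=float(a), b=float(b), qbar=qbar, mode="joint", loglik=-float(best.fun))


def dcc_tvfc(data: TimeSeriesData, mode: str = "joint") -> CovTrajectory:
    """DCC(1,1)-GARCH(1,1) conditional correlation trajectory.

    ``joint`` fits one DCC model over all D standardized series;
    ``bivariate_loop`` fits D(D-1)/2 pairwise models and assembles the
    estimates edgewise (which can break positive semidefiniteness — the
    result is flagged in ``meta['psd']``; likelihood-based consumers should
    project, see :func:`tvfc.benchmarks.project_to_correlation`).
    """
    if mode not in ("joint", "bivariate_loop"):
        raise ValueError("mode must be 'joint' or 'bivariate_loop'")
    y = np.asarray(data.y, dtype=float)
    n, d = y.shape
    if d < 2:
        raise ValueError("DCC needs at least two nodes")
    z = np.empty_like(y)
    garch_params = []
    for j in range(d):
        pj, z[:, j] = garch11_fit(y[:, j])
        garch_params.append(pj)

    if mode == "joint":
        par = dcc_fit(z)
        r = dcc_recursion(z, par.a, par.b, par.qbar)
        meta = {"method": "dcc_joint", "a": par.a, "b": par.b, "psd": True}
    else:
        r = np.tile(np.eye(d), (n, 1, 1))
        pair_params = {}
        for i in range(d):
            for j in range(i + 1, d):
                par = dcc_fit(z[:, [i, j]])
                rij = dcc_recursion(z[:, [i, j]], par.a, par.b, par.qbar)[:, 0, 1]
                r[:, i, j] = rij
                r[:, j, i] = rij
                pair_params[(i, j)] = (par.a, par.b)
        psd = bool(np.linalg.eigvalsh(r).min() >= -1e-10)
        if not psd:
            warnings.warn("bivariate-loop DCC assembly produced non-PSD matrices")
        meta = {"method": "dcc_bl", "pair_params": pair_params, "psd": psd}
    meta["garch"] = garch_params
    return CovTrajectory(sigmas=r, x=data.x, meta=meta)


def simulate_dcc(
    n: int, qbar: np.ndarray, a: float, b: float, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate from a DCC(1,1) model with unit conditional variances.

    Returns (y, r_true) where r_true[n] is the conditional correlation that
    generated y[n]. Used to validate parameter/path recovery.
    """
    qbar = np.asarray(qbar, dtype=float)
    d = qbar.shape[0]
    rng = np.random.default_rng(seed)
    q = qbar.copy()
    y = np.empty((n, d))
    r_true = np.empty((n, d, d))
    z_prev = np.zeros(d)
    for t in range(n):
        if t > 0:
            q = (1 - a - b) * qbar + a * np.outer(z_prev, z_prev) + b * q
        sd = np.sqrt(np.diag(q))
        r = q / np.outer(sd, sd)
        r_true[t] = r
        z_prev = np.linalg.cholesky(r) @ rng.standard_normal(d)
        y[t] = z_prev
    return y, r_true
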