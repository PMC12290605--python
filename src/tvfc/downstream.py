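"""Downstream statistics on TVFC summary measures across synthetic cohorts.

- morphometricity: fraction of phenotype variance explained by a
  subject-similarity kernel in a one-kernel linear mixed model, fitted by
  restricted maximum likelihood (REML);
- edgewise test-retest reliability (ICC, one-way random-effects ANOVA) and
  whole-image reliability (I2C2, method-of-moments trace ratio);
- k-means brain states over vectorized correlation matrices with switch
  counts;
- a GLM relating TVFC edge series to an HRF-convolved task stimulus.

Cohort generators with planted variance components close the loop for
testing without any external data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.polynomial import legendre
from scipy import optimize, signal, stats
from sklearn.cluster import KMeans

from tvfc import simkit
from tvfc.datatypes import CovTrajectory


# ---------------------------------------------------------------------------
# similarity kernel + morphometricity

def similarity_kernel(features: np.ndarray, bandwidth: str = "unit") -> np.ndarray:
    """Gaussian similarity between subjects: K[s,s'] = exp(-||x_s - x_s'||^2 / h).

    Feature columns are standardized first (zero-variance columns dropped
    with a warning). ``bandwidth='unit'`` fixes h = 1 on the standardized
    scale; ``'median'`` uses the median squared pairwise distance.
    """
    x = np.atleast_2d(np.asarray(features, dtype=float))
    if x.shape[0] < 2:
        raise ValueError("need at least two subjects")
    sd = x.std(axis=0)
    keep = sd > 0
    if not np.all(keep):
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance feature column(s)")
        x = x[:, keep]
        sd = sd[keep]
    x = (x - x.mean(axis=0)) / sd
    sq = np.sum(x**2, axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * x @ x.T, 0.0)
    if bandwidth == "median":
        h = float(np.median(d2[np.triu_indices_from(d2, k=1)]))
        h = h if h > 0 else 1.0
    elif bandwidth == "unit":
        h = 1.0
    else:
        raise ValueError("bandwidth must be 'unit' or 'median'")
    k = np.exp(-d2 / h)
    return (k + k.T) / 2.0


@dataclass
class MorphometricityResult:
    m2: float
    sigma_a2: float
    sigma_e2: float
    beta: np.ndarray
    reml: float
    converged: bool


def morphometricity(
    y: np.ndarray, x_design: np.ndarray | None, k_sim: np.ndarray
) -> MorphometricityResult:
    """REML fit of y = X beta + a + e with a ~ N(0, sigma_a^2 K).

    The restricted likelihood is profiled over the fixed effects and the
    residual scale and maximized over the variance ratio gamma =
    sigma_a^2 / sigma_e^2 by bounded scalar search; m^2 = gamma/(1+gamma),
    clipped to [0, 1].
    """
    y = np.asarray(y, dtype=float).ravel()
    s = y.shape[0]
    x = np.ones((s, 1)) if x_design is None else np.atleast_2d(np.asarray(x_design, float))
    if x.shape[0] != s or k_sim.shape != (s, s):
        raise ValueError("inconsistent shapes")
    c = x.shape[1]
    if s <= c + 2:
        raise ValueError("too few subjects for the design")
    w_eig, u = np.linalg.eigh((k_sim + k_sim.T) / 2.0)
    w_eig = np.clip(w_eig, 0.0, None)
    yt = u.T @ y
    xt = u.T @ x

    def neg_reml(log_gamma: float) -> float:
        gamma = np.exp(log_gamma)
        wv = gamma * w_eig + 1.0  # eigenvalues of gamma K + I
        xtwx = (xt / wv[:, None]).T @ xt
        beta = np.linalg.solve(xtwx, (xt / wv[:, None]).T @ yt)
        r = yt - xt @ beta
        rss = float(np.sum(r**2 / wv))
        sign, logdet_xtwx = np.linalg.slogdet(xtwx)
        return 0.5 * (
            float(np.sum(np.log(wv))) + logdet_xtwx + (s - c) * np.log(rss / (s - c))
        )

    res = optimize.minimize_scalar(
        neg_reml, bounds=(-12.0, 12.0), method="bounded",
        options={"xatol": 1e-8},
    )
    gamma = float(np.exp(res.x))
    wv = gamma * w_eig + 1.0
    xtwx = (xt / wv[:, None]).T @ xt
    beta = np.linalg.solve(xtwx, (xt / wv[:, None]).T @ yt)
    r = yt - xt @ beta
    sigma_e2 = float(np.sum(r**2 / wv) / (s - c))
    sigma_a2 = gamma * sigma_e2
    m2 = float(np.clip(sigma_a2 / (sigma_a2 + sigma_e2), 0.0, 1.0))
    return MorphometricityResult(
        m2=m2, sigma_a2=sigma_a2, sigma_e2=sigma_e2, beta=beta,
        reml=-float(res.fun), converged=bool(res.success),
    )


# ---------------------------------------------------------------------------
# test-retest reliability

def icc_edgewise(measure: np.ndarray) -> np.ndarray:
    """One-way random-effects ICC per edge.

    ``measure`` is (subjects, sessions) or (subjects, sessions, edges);
    ICC = sigma_X^2 / (sigma_X^2 + sigma_U^2) from the ANOVA moment
    estimates (between-subject MSB, within-subject MSW), clipped to [0, 1].
    """
    x = np.asarray(measure, dtype=float)
    if x.ndim == 2:
        x = x[:, :, None]
    s, j, p = x.shape
    if s < 3 or j < 2:
        raise ValueError("need >=3 subjects and >=2 sessions")
    subj_mean = x.mean(axis=1)  # (S, P)
    msb = j * subj_mean.var(axis=0, ddof=1)
    msw = ((x - subj_mean[:, None, :]) ** 2).sum(axis=(0, 1)) / (s * (j - 1))
    sigma_x2 = np.clip((msb - msw) / j, 0.0, None)
    denom = sigma_x2 + msw
    with np.errstate(invalid="ignore"):
        icc = np.where(denom > 0, sigma_x2 / np.maximum(denom, 1e-300), 0.0)
    if np.any(denom == 0):
        warnings.warn("degenerate (zero-variance) edges: ICC set to 0")
    out = np.clip(icc, 0.0, 1.0)
    return float(out[0]) if np.asarray(measure).ndim == 2 else out


def i2c2(features: np.ndarray) -> float:
    """Whole-image reliability: tr(K_X) / tr(K_X + K_U).

    ``features`` is (subjects, sessions, edges). K_U is the within-subject
    (measurement error) covariance, K_X the between-subject covariance of
    the error-free measure; both enter through method-of-moments trace
    estimates, with negative moment estimates clipped at 0.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim != 3:
        raise ValueError("features must be (subjects, sessions, edges)")
    s, j, p = x.shape
    if s < 3 or j < 2:
        raise ValueError("need >=3 subjects and >=2 sessions")
    subj_mean = x.mean(axis=1)
    tr_ku = float(((x - subj_mean[:, None, :]) ** 2).sum() / (s * (j - 1)))
    tr_between = float(((subj_mean - subj_mean.mean(axis=0)) ** 2).sum() / (s - 1))
    tr_kx = max(tr_between - tr_ku / j, 0.0)
    if tr_kx + tr_ku == 0:
        warnings.warn("degenerate features: I2C2 set to 0")
        return 0.0
    return float(np.clip(tr_kx / (tr_kx + tr_ku), 0.0, 1.0))


# ---------------------------------------------------------------------------
# brain states

@dataclass
class BrainStates:
    states: np.ndarray  # (k, D, D) centroid correlation matrices
    labels: list[np.ndarray]  # per-scan label sequences
    switch_counts: np.ndarray  # per scan
    inertia: float


def brain_states(trajs: list[CovTrajectory], k: int = 3, seed: int = 0) -> BrainStates:
    """k-means brain states over pooled vectorized correlation matrices.

    All scans' lower-triangular correlation vectors are concatenated and
    clustered; a switch is any volume whose state label differs from the
    previous volume's within the same scan.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    vecs = [t.lower_triangular() for t in trajs]
    pooled = np.vstack(vecs)
    if pooled.shape[0] < k:
        raise ValueError("fewer pooled time points than states")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    flat_labels = km.fit_predict(pooled)
    d = trajs[0].d
    i, j = np.tril_indices(d, k=-1)
    states = np.tile(np.eye(d), (k, 1, 1))
    states[:, i, j] = km.cluster_centers_
    states[:, j, i] = km.cluster_centers_
    labels, switches, offset = [], [], 0
    for t in trajs:
        lab = flat_labels[offset: offset + t.n]
        offset += t.n
        labels.append(lab)
        switches.append(int(np.sum(lab[1:] != lab[:-1])))
    return BrainStates(
        states=states, labels=labels,
        switch_counts=np.asarray(switches), inertia=float(km.inertia_),
    )


# ---------------------------------------------------------------------------
# stimulus-prediction GLM

@dataclass
class StimulusGlmResult:
    beta: np.ndarray  # (G,) stimulus weights
    p_values: np.ndarray  # one-sided, Bonferroni-corrected over edges
    t_values: np.ndarray
    design: np.ndarray  # (N, R)
    residuals: np.ndarray  # (N, G)
    drift_order: int


def convolve_hrf(stimulus: np.ndarray, tr: float) -> np.ndarray:
    """Convolve a boxcar stimulus with the canonical double-gamma HRF."""
    stimulus = np.asarray(stimulus, dtype=float).ravel()
    h = simkit.hrf_double_gamma(tr)
    return signal.convolve(stimulus, h, mode="full")[: stimulus.shape[0]]


def drift_order(tr: float, n: int) -> int:
    """Polynomial drift order: TR * N / 150, rounded half up."""
    return int(np.floor(tr * n / 150.0 + 0.5))


def stimulus_glm(
    tvfc_edge_series: np.ndarray,
    stimulus_boxcar: np.ndarray,
    tr: float,
    alternative: str = "less",
) -> StimulusGlmResult:
    """OLS regression of TVFC edge series on an HRF-convolved stimulus.

    The design holds the convolved stimulus plus Legendre polynomial drift
    regressors of order ``drift_order(tr, n)`` (orders 0..q, so q=1 gives
    the three-regressor setup: stimulus, offset, linear trend). One-sided
    p-values (default direction: negative task coupling, the expected
    stimulus-induced decorrelation) are Bonferroni-corrected over edges.
    """
    y = np.asarray(tvfc_edge_series, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    n, g = y.shape
    if stimulus_boxcar.shape[0] != n:
        raise ValueError("stimulus and series lengths differ")
    reg = convolve_hrf(stimulus_boxcar, tr)
    q = max(drift_order(tr, n), 1)
    t_norm = np.linspace(-1.0, 1.0, n)
    drift = np.stack([legendre.Legendre.basis(p)(t_norm) for p in range(q + 1)], axis=1)
    design = np.column_stack([reg, drift])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError(
            f"rank-deficient design (rank {rank} < {design.shape[1]}): "
            "stimulus regressor collinear with the drift basis"
        )
    beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    dof = n - design.shape[1]
    mse = np.sum(resid**2, axis=0) / dof
    xtx_inv = np.linalg.inv(design.T @ design)
    se = np.sqrt(np.maximum(mse * xtx_inv[0, 0], 1e-300))
    t_vals = beta[0] / se
    if alternative == "less":
        p = stats.t.cdf(t_vals, dof)
    elif alternative == "greater":
        p = stats.t.sf(t_vals, dof)
    elif alternative == "two-sided":
        p = 2.0 * stats.t.sf(np.abs(t_vals), dof)
    else:
        raise ValueError("alternative must be 'less', 'greater', or 'two-sided'")
    p_adj = np.minimum(1.0, g * p)
    return StimulusGlmResult(
        beta=beta[0], p_values=p_adj, t_values=t_vals,
        design=design, residuals=resid, drift_order=q,
    )


# ---------------------------------------------------------------------------
# synthetic cohorts (no external data)

def cohort_features(
    s_subjects: int,
    j_sessions: int,
    p_edges: int,
    sigma_x2: float = 1.0,
    sigma_u2: float = 1.0,
    seed: int | None = None,
) -> np.ndarray:
    """Subject x session x edge summary features with planted variance components.

    w_isp = mu_p + x_sp + u_isp with between-subject variance sigma_x2 and
    within-subject (session) variance sigma_u2, i.i.d. across edges; the
    population ICC of every edge is sigma_x2 / (sigma_x2 + sigma_u2).
    """
    rng = np.random.default_rng(seed)
    mu = rng.normal(0.0, 0.5, size=p_edges)
    x = rng.normal(0.0, np.sqrt(sigma_x2), size=(s_subjects, 1, p_edges))
    u = rng.normal(0.0, np.sqrt(sigma_u2), size=(s_subjects, j_sessions, p_edges))
    return mu + x + u


def cohort_phenotype(
    k_sim: np.ndarray, m2: float, seed: int | None = None
) -> np.ndarray:
    """Phenotype with planted morphometricity: y = a + e, a ~ N(0, m2 K)."""
    if not 0 <= m2 <= 1:
        raise ValueError("m2 must lie in [0, 1]")
    s = k_sim.shape[0]
    rng = np.random.default_rng(seed)
    w, u = np.linalg.eigh((k_sim + k_sim.T) / 2.0)
    a = u @ (np.sqrt(np.clip(w, 0, None)) * rng.standard_normal(s))
    return np.sqrt(m2) * a + np.sqrt(1.0 - m2) * rng.standard_normal(s)


def planted_state_scans(
    n_scans: int,
    n: int,
    k: int = 3,
    transitions: int = 4,
    d: int = 3,
    jitter: float = 0.02,
    seed: int | None = None,
) -> tuple[list[CovTrajectory], list[np.ndarray]]:
    """Scans that hop between k well-separated correlation matrices.

    Each scan has exactly ``transitions`` state changes at random change
    points; a small jitter is added to the off-diagonals (clipped to keep
    matrices valid). Returns the trajectories and true label sequences.
    """
    rng = np.random.default_rng(seed)
    i, j = np.tril_indices(d, k=-1)
    base = np.linspace(-0.4, 0.6, k)  # keeps D>=3 equicorrelation matrices PSD
    trajs, labels = [], []
    for _ in range(n_scans):
        cps = np.sort(rng.choice(np.arange(1, n), size=transitions, replace=False))
        lab = np.zeros(n, dtype=int)
        state = int(rng.integers(k))
        prev = 0
        for cp in np.append(cps, n):
            lab[prev:cp] = state
            nxt = int(rng.integers(k - 1))
            state = nxt if nxt < state else nxt + 1  # guarantee a real switch
            prev = cp
        sig = np.tile(np.eye(d), (n, 1, 1))
        vals = base[lab][:, None] + rng.normal(0.0, jitter, size=(n, i.size))
        vals = np.clip(vals, -0.45, 0.7)
        sig[:, i, j] = vals
        sig[:, j, i] = vals
        trajs.append(CovTrajectory(sigmas=sig))
        labels.append(lab)
    return trajs, labels
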