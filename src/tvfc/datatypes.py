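"""Core containers shared by all estimators and benchmarks.

Time series live on normalized index locations in [0, 1] (scan time divided
by scan duration); covariance trajectories are stacks of D x D symmetric
positive-semidefinite matrices, one per scanning volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: eigenvalue slack below zero still accepted as PSD (numerical round-off)
PSD_TOL = 1e-10


def cov_to_corr(sigma: np.ndarray) -> np.ndarray:
    """Convert covariance matrices to correlation matrices.

    Divides each element by the product of the standard deviations of the
    corresponding variables. Works on a single ``(D, D)`` matrix or a stack
    ``(..., D, D)``.

    Raises
    ------
    ValueError
        If any diagonal entry is not strictly positive.
    """
    sigma = np.asarray(sigma, dtype=float)
    diag = np.diagonal(sigma, axis1=-2, axis2=-1)
    if np.any(diag <= 0):
        raise ValueError("cov_to_corr requires strictly positive diagonal entries")
    inv_sd = 1.0 / np.sqrt(diag)
    corr = sigma * inv_sd[..., :, None] * inv_sd[..., None, :]
    # enforce exact unit diagonal despite round-off
    idx = np.arange(sigma.shape[-1])
    corr[..., idx, idx] = 1.0
    return corr


def normalized_locations(n: int) -> np.ndarray:
    """Index locations (n-1)/(N-1) mapping volumes 1..N onto [0, 1]."""
    if n < 2:
        raise ValueError("need at least two time steps")
    return np.linspace(0.0, 1.0, n)


@dataclass
class TimeSeriesData:
    """An ``N x D`` multivariate observation matrix with scan metadata.

    Attributes
    ----------
    y : ndarray, shape (N, D)
        Node time series (BOLD-like signal, arbitrary units).
    tr : float
        Repetition time: seconds between consecutive rows.
    x : ndarray, shape (N,)
        Index locations in [0, 1], strictly increasing. Defaults to the
        uniform grid (n-1)/(N-1); subsets (e.g. a leave-every-other-out
        training half) retain their original locations.
    seed : int or None
        Seed used to generate the data, if synthetic.
    """

    y: np.ndarray
    tr: float = 2.0
    x: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.y = np.atleast_2d(np.asarray(self.y, dtype=float))
        if self.y.ndim != 2:
            raise ValueError("y must be an N x D matrix")
        if self.tr <= 0:
            raise ValueError("TR must be positive")
        if self.x is None:
            self.x = normalized_locations(self.n)
        else:
            self.x = np.asarray(self.x, dtype=float)
            if self.x.shape != (self.n,):
                raise ValueError("x must have one location per row of y")
            if np.any(np.diff(self.x) <= 0):
                raise ValueError("index locations must be strictly increasing")

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def d(self) -> int:
        return self.y.shape[1]

    def zscored(self) -> "TimeSeriesData":
        """Columns individually normalized to zero mean, unit SD."""
        sd = self.y.std(axis=0, ddof=0)
        if np.any(sd == 0):
            raise ValueError("cannot z-score a constant column")
        return replace(self, y=(self.y - self.y.mean(axis=0)) / sd)


@dataclass
class CovTrajectory:
    """A sequence of ``D x D`` covariance (or correlation) matrices over time.

    Used both for simulation ground truths and for estimates returned by the
    TVFC estimators.
    """

    sigmas: np.ndarray  # (N, D, D)
    x: np.ndarray | None = None
    topology: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sigmas = np.asarray(self.sigmas, dtype=float)
        if self.sigmas.ndim != 3 or self.sigmas.shape[1] != self.sigmas.shape[2]:
            raise ValueError("sigmas must have shape (N, D, D)")
        if self.x is None:
            self.x = normalized_locations(self.n) if self.n >= 2 else np.zeros(self.n)
        else:
            self.x = np.asarray(self.x, dtype=float)
            if self.x.shape != (self.n,):
                raise ValueError("x must have one location per matrix")

    @property
    def n(self) -> int:
        return self.sigmas.shape[0]

    @property
    def d(self) -> int:
        return self.sigmas.shape[1]

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.sigmas).min())

    def is_psd(self, tol: float = PSD_TOL) -> bool:
        sym = np.allclose(self.sigmas, np.swapaxes(self.sigmas, 1, 2), atol=1e-10)
        return sym and self.min_eigenvalue() >= -tol

    def require_psd(self, tol: float = PSD_TOL) -> None:
        if not self.is_psd(tol):
            raise ValueError(
                f"trajectory is not PSD (min eigenvalue {self.min_eigenvalue():.3e})"
            )

    def to_corr(self) -> "CovTrajectory":
        return replace(self, sigmas=cov_to_corr(self.sigmas))

    def edge(self, i: int, j: int) -> np.ndarray:
        """The (i, j) element as a length-N series."""
        return self.sigmas[:, i, j]

    def lower_triangular(self) -> np.ndarray:
        """Strictly-lower-triangular entries as an (N, D(D-1)/2) matrix."""
        i, j = np.tril_indices(self.d, k=-1)
        return self.sigmas[:, i, j]
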