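"""Spatial covariance kernel, inducing-point selection and GP conditionals.

The spatial prior on each factor is a Gaussian process with an
exponential (Matern-1/2) kernel

    k(a, b) = amplitude * exp(-||a - b|| / lengthscale)

and a linear mean function beta0 + X @ beta1.  Large models are handled
through a sparse inducing-point construction: the factor is represented
by its values U at a reduced set of locations Z and interpolated to the
observed spots through the exact GP conditional

    F | U ~ N( m(X) + Kuf' Kuu^-1 (U - m(Z)),  Kff - Kuf' Kuu^-1 Kuf ).

All solves go through the Cholesky factor of Kuu; a small jitter
proportional to the amplitude is added to diagonal blocks and escalated
tenfold (up to 1e-4 * amplitude) if factorization fails.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

__all__ = [
    "KernelParams",
    "InducingGrid",
    "GPFactorParams",
    "exponential_kernel",
    "choose_inducing_points",
    "gp_conditional",
    "rescale_coords",
]

JITTER_DEFAULT = 1e-6
JITTER_MAX = 1e-4


@dataclass
class KernelParams:
    """Exponential-kernel hyperparameters for one factor in one sample."""

    amplitude: float = 1.0
    lengthscale: float = 0.1
    jitter: float = JITTER_DEFAULT

    def __post_init__(self):
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.lengthscale <= 0:
            raise ValueError("lengthscale must be positive")
        if self.jitter < 0:
            raise ValueError("jitter must be nonnegative")


@dataclass
class InducingGrid:
    """A set of inducing locations Z for one sample."""

    points: np.ndarray
    source: str = "kmeans"
    seed: int = 0

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[0] < 1 or self.points.shape[1] != 2:
            raise ValueError("inducing points must form an n x 2 array with n >= 1")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


@dataclass
class GPFactorParams:
    """Variational and GP parameters of one factor in one sample.

    ``q_mean`` (delta) and ``q_cov_chol`` (lower Cholesky of Omega)
    parameterize the Gaussian variational posterior over the factor
    values at the inducing points; ``beta0``/``beta1`` give the linear
    GP mean.
    """

    beta0: float = 0.0
    beta1: np.ndarray = None
    kernel: KernelParams = field(default_factory=KernelParams)
    q_mean: np.ndarray = None
    q_cov_chol: np.ndarray = None

    def __post_init__(self):
        if self.beta1 is None:
            self.beta1 = np.zeros(2)
        self.beta1 = np.asarray(self.beta1, dtype=float)
        if self.q_mean is not None:
            self.q_mean = np.asarray(self.q_mean, dtype=float)
        if self.q_cov_chol is not None:
            self.q_cov_chol = np.asarray(self.q_cov_chol, dtype=float)
            if np.any(np.diag(self.q_cov_chol) <= 0):
                raise ValueError("q_cov_chol must have strictly positive diagonal")

    def mean_at(self, X: np.ndarray) -> np.ndarray:
        return self.beta0 + np.atleast_2d(X) @ self.beta1


def exponential_kernel(A: np.ndarray, B_coords: np.ndarray,
                       params: KernelParams) -> np.ndarray:
    """Exponential covariance k(a,b) = amplitude * exp(-||a-b|| / lengthscale).

    If ``A`` and ``B_coords`` are the same array, ``jitter * amplitude``
    is added to the diagonal for numerical stability.
    """
    A_in, B_in = A, B_coords
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B_coords, dtype=float))
    if not (np.all(np.isfinite(A)) and np.all(np.isfinite(B))):
        raise ValueError("coordinates must be finite")
    D = cdist(A, B)
    K = params.amplitude * np.exp(-D / params.lengthscale)
    if A_in is B_in:
        K = K + params.jitter * params.amplitude * np.eye(A.shape[0])
    return K


def choose_inducing_points(coords: np.ndarray, fraction: float = 0.35,
                           method: str = "kmeans", seed: int = 0) -> InducingGrid:
    """Pick round(fraction * n_spots) inducing locations from spot coordinates.

    "kmeans" uses seeded k-means centroids of the coordinates (even
    spatial coverage); "random" takes a seeded uniform subsample of the
    spots.  Both are deterministic given the seed.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    n_spots = coords.shape[0]
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n = int(round(fraction * n_spots))
    if n < 1:
        raise ValueError("fraction * n_spots must be at least 1")
    if method == "random":
        rng = np.random.default_rng(seed)
        idx = rng.choice(n_spots, size=n, replace=False)
        pts = coords[idx]
    elif method == "kmeans":
        if n >= n_spots:
            pts = coords.copy()
        else:
            km = KMeans(n_clusters=n, random_state=seed, n_init=4)
            km.fit(coords)
            pts = km.cluster_centers_
    else:
        raise ValueError(f"unknown inducing-point method {method!r}")
    return InducingGrid(points=pts, source=method, seed=seed)


def chol_with_jitter(K: np.ndarray, amplitude: float,
                     jitter: float = JITTER_DEFAULT) -> tuple[np.ndarray, float]:
    """Lower Cholesky of K, escalating diagonal jitter up to JITTER_MAX * amplitude.

    Returns (lower factor, extra jitter actually added beyond what K
    already carries).  Raises on failure at the maximum jitter.
    """
    extra = 0.0
    j = jitter
    n = K.shape[0]
    while True:
        try:
            L = cholesky(K + extra * np.eye(n), lower=True)
            return L, extra
        except np.linalg.LinAlgError:
            if j > JITTER_MAX:
                raise np.linalg.LinAlgError(
                    f"Cholesky failed with jitter up to {JITTER_MAX * amplitude:.1e}; "
                    "the kernel matrix is too ill-conditioned"
                )
            extra = j * amplitude
            j *= 10.0


def gp_conditional(u_values: np.ndarray, grid: InducingGrid, X: np.ndarray,
                   params: GPFactorParams) -> tuple[np.ndarray, np.ndarray]:
    """Exact GP conditional of the factor at X given its values at the inducing points.

    Returns the conditional mean m(X) + Kuf' Kuu^-1 (u - m(Z)) and
    covariance Kff - Kuf' Kuu^-1 Kuf (symmetrized).  Solves use the
    Cholesky of Kuu; no explicit inverse is formed.
    """
    u = np.asarray(u_values, dtype=float).ravel()
    Z = grid.points
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if u.shape[0] != grid.n_points:
        raise ValueError("u_values length must match the number of inducing points")
    Kuu = exponential_kernel(Z, Z, params.kernel)
    Kuf = exponential_kernel(Z, X, params.kernel)
    Kff = exponential_kernel(X, X, params.kernel)
    L, extra = chol_with_jitter(Kuu, params.kernel.amplitude, params.kernel.jitter)
    # A = Kuu^-1 Kuf via two triangular solves
    tmp = solve_triangular(L, Kuf, lower=True)
    A = solve_triangular(L.T, tmp, lower=False)
    mz = params.mean_at(Z)
    mx = params.mean_at(X)
    mean = mx + A.T @ (u - mz)
    cov = Kff - Kuf.T @ A
    cov = 0.5 * (cov + cov.T)
    return mean, cov


def rescale_coords(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Affinely map coordinates into the unit box, preserving aspect ratio.

    Subtracts the bounding-box minimum and divides by the longest side,
    so the result lies in [0, 1]^2 and lengthscales are comparable
    across samples of different physical size.  Returns
    (scaled, offset, scale) with original = scaled * scale + offset.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    offset = coords.min(axis=0)
    extent = coords.max(axis=0) - offset
    scale = float(max(extent.max(), 1e-12))
    return (coords - offset) / scale, offset, scale
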