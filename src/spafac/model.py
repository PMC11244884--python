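"""Probabilistic model: NB likelihood, shared-loading rate, and the ELBO.

The observation model for sample m is

    Y[m,g,i] ~ NB( lambda[m,g,i] * sz[m,i], phi_m ),
    lambda[m,g,i] = sum_l W[g,l] * exp(F[m,i,l]),

with Var = mu + mu^2/phi (phi = inverse overdispersion).  The gene
loadings W are shared across samples; each factor F[m,:,l] carries a
sample-specific GP prior handled through inducing points (see
:mod:`spafac.kernels`).  Inference is variational: q(U) = N(delta, Omega)
per factor per sample, the factor is evaluated at the GP conditional
mean given a Monte-Carlo draw of U, and the conditional terms cancel
between the joint and the variational density, leaving

    ELBO_m = E_q[ log p(Y_m | F(U)) ] - sum_l KL( q(U_l) || p(U_l) ).

Because samples are independent, the joint ELBO is the sum of the
per-sample ELBOs, which is what makes distributed per-sample updates
with loading averaging valid.

All gradients of this objective are closed-form; the private
``elbo_and_grad_sample`` returns both the value and the exact gradient
(kernel hyperparameters included, via Cholesky-based chain rules), so
no autodiff framework is needed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_solve, solve_triangular
from scipy.spatial.distance import cdist
from scipy.special import gammaln

from .data import SpatialSample
from .kernels import (
    GPFactorParams,
    InducingGrid,
    chol_with_jitter,
    exponential_kernel,
)

__all__ = [
    "SampleGPParams",
    "ModelParams",
    "FittedModel",
    "rate_from_factors",
    "nb_log_likelihood",
    "elbo_single_sample",
    "elbo_multi_sample",
    "mpnmf_elbo",
]


@dataclass
class SampleGPParams:
    """All sample-specific parameters: one GPFactorParams per factor plus dispersion."""

    factors: list
    dispersion: float = 1.0
    coord_offset: np.ndarray = None
    coord_scale: float = 1.0

    def __post_init__(self):
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.coord_offset is None:
            self.coord_offset = np.zeros(2)


@dataclass
class ModelParams:
    """Shared loadings plus per-sample GP/variational parameters."""

    loadings: np.ndarray
    per_sample: list
    n_factors: int = 0
    gene_ids: np.ndarray = None

    def __post_init__(self):
        self.loadings = np.asarray(self.loadings, dtype=float)
        if np.any(self.loadings < 0):
            raise ValueError("loadings must be nonnegative")
        if self.n_factors == 0:
            self.n_factors = self.loadings.shape[1]


@dataclass
class FittedModel:
    """Fit result: parameters, realized factors per sample, and the ELBO trace."""

    params: ModelParams
    factors: list
    elbo_trace: np.ndarray
    config: object = None
    grids: list = field(default_factory=list)


def rate_from_factors(loadings: np.ndarray, factors: np.ndarray) -> np.ndarray:
    """Rate matrix Lambda[g,i] = sum_l W[g,l] * exp(F[i,l]) (genes x spots)."""
    W = np.asarray(loadings, dtype=float)
    F = np.asarray(factors, dtype=float)
    if np.any(W < 0):
        raise ValueError("loadings must be nonnegative")
    if W.shape[1] != F.shape[1]:
        raise ValueError("loadings and factors disagree on the number of factors")
    zero_rows = ~np.any(W > 0, axis=1)
    if np.any(zero_rows):
        warnings.warn(
            f"{int(zero_rows.sum())} gene(s) have all-zero loading rows; their "
            "rate is 0 and the NB mean is undefined for positive counts",
            RuntimeWarning,
        )
    return W @ np.exp(F).T


def nb_log_likelihood(Y: np.ndarray, rate: np.ndarray, size_factors: np.ndarray,
                      dispersion: float) -> float:
    """Total negative-binomial log-likelihood with mean mu = rate * sz.

    Uses the (mu, phi) parameterization with Var = mu + mu^2/phi.  The
    Poisson limit is recovered as phi -> infinity.
    """
    phi = float(dispersion)
    if not np.isfinite(phi) or phi <= 0:
        raise ValueError("dispersion must be a positive finite number")
    Y = np.asarray(Y, dtype=float)
    mu = np.asarray(rate, dtype=float) * np.asarray(size_factors, dtype=float)
    if np.any((mu <= 0) & (Y > 0)):
        raise ValueError("zero NB mean with a positive count: log-likelihood is -inf")
    mu = np.maximum(mu, 1e-300)
    ll = (gammaln(Y + phi) - gammaln(phi) - gammaln(Y + 1)
          + phi * (np.log(phi) - np.log(phi + mu))
          + Y * (np.log(mu) - np.log(phi + mu)))
    return float(ll.sum())


def _nb_dll_dmu(Y, mu, phi):
    """d(log NB)/d(mu), elementwise."""
    return Y / np.maximum(mu, 1e-300) - (Y + phi) / (phi + mu)


def _gaussian_kl(delta, Lq, mz, Kuu_chol):
    """KL( N(delta, Lq Lq') || N(mz, Kuu) ) with Kuu given by its lower Cholesky."""
    n = delta.shape[0]
    r = mz - delta
    # tr(Kuu^-1 Omega) = || Lk^-1 Lq ||_F^2
    V = solve_triangular(Kuu_chol, Lq, lower=True)
    trace_term = float(np.sum(V * V))
    w = solve_triangular(Kuu_chol, r, lower=True)
    quad = float(w @ w)
    logdet_K = 2.0 * float(np.sum(np.log(np.diag(Kuu_chol))))
    logdet_O = 2.0 * float(np.sum(np.log(np.diag(Lq))))
    return 0.5 * (trace_term + quad - n + logdet_K - logdet_O)


class _FactorGeometry:
    """Per-factor precomputation tied to a kernel-parameter value.

    Holds Kuu and its Cholesky, and per-chunk cross-covariances and
    interpolation weights A_c = Kuu^-1 Kuf_c.
    """

    def __init__(self, fp: GPFactorParams, Z: np.ndarray, X_chunks: list):
        self.fp = fp
        self.Z = Z
        kp = fp.kernel
        self.Duu = cdist(Z, Z)
        self.Kuu = kp.amplitude * np.exp(-self.Duu / kp.lengthscale) \
            + kp.jitter * kp.amplitude * np.eye(Z.shape[0])
        self.Lk, _ = chol_with_jitter(self.Kuu, kp.amplitude, kp.jitter)
        self.mz = fp.mean_at(Z)
        self.Duf = []
        self.Kuf = []
        self.A = []
        self.mx = []
        for X in X_chunks:
            D = cdist(Z, X)
            K = kp.amplitude * np.exp(-D / kp.lengthscale)
            tmp = solve_triangular(self.Lk, K, lower=True)
            A = solve_triangular(self.Lk.T, tmp, lower=False)
            self.Duf.append(D)
            self.Kuf.append(K)
            self.A.append(A)
            self.mx.append(fp.mean_at(X))

    def kuu_solve(self, b):
        return cho_solve((self.Lk, True), b)


def _zero_grads(G, L, n):
    return {
        "loadings": np.zeros((G, L)),
        "beta0": np.zeros(L),
        "beta1": np.zeros((L, 2)),
        "delta": np.zeros((L, n)),
        "q_chol": np.zeros((L, n, n)),
        "log_amplitude": np.zeros(L),
        "log_lengthscale": np.zeros(L),
    }


def elbo_and_grad_sample(chunks: list, grid: InducingGrid,
                         sample_params: SampleGPParams, loadings: np.ndarray,
                         n_mc: int, rng: np.random.Generator,
                         compute_grad: bool = True):
    """Monte-Carlo ELBO of one sample and its exact gradient.

    ``chunks`` is a list of (Y, sz, X) triples partitioning the sample's
    spots; all chunks share the inducing grid and variational
    parameters, the likelihood contributions are summed and the KL is
    counted once, so the chunked objective equals the unchunked one at
    any parameter point.

    Returns (elbo, grads) where ``grads`` maps parameter names to arrays
    (gradients of the ELBO; ``None`` when ``compute_grad`` is false).
    Kernel hyperparameter gradients are with respect to log(amplitude)
    and log(lengthscale).
    """
    W = np.asarray(loadings, dtype=float)
    G, L = W.shape
    fps = sample_params.factors
    if len(fps) != L:
        raise ValueError("number of GPFactorParams must equal loading columns")
    phi = sample_params.dispersion
    Z = grid.points
    n = grid.n_points
    X_chunks = [X for (_, _, X) in chunks]

    geoms = [_FactorGeometry(fp, Z, X_chunks) for fp in fps]

    # shared MC draws across chunks: eps[l] has shape (n_mc, n)
    eps = [rng.standard_normal((n_mc, n)) for _ in range(L)]
    u = []          # u[l][s] = delta + Lq eps
    v = []          # u - mz
    wv = []         # Kuu^-1 (u - mz)
    for l, fp in enumerate(fps):
        Lq = fp.q_cov_chol
        ul = fp.q_mean[None, :] + eps[l] @ Lq.T
        u.append(ul)
        vl = ul - geoms[l].mz[None, :]
        v.append(vl)
        if compute_grad:
            wv.append(geoms[l].kuu_solve(vl.T).T)

    grads = _zero_grads(G, L, n) if compute_grad else None
    loglik_total = 0.0

    for c, (Y, sz, X) in enumerate(chunks):
        Nc = X.shape[0]
        # factors for all draws: F[s] is (Nc, L)
        F = np.empty((n_mc, Nc, L))
        for l in range(L):
            F[:, :, l] = geoms[l].mx[c][None, :] + v[l] @ geoms[l].A[c]
        for s in range(n_mc):
            expF = np.exp(F[s])
            Lam = W @ expF.T
            mu = Lam * sz[None, :]
            mu = np.maximum(mu, 1e-300)
            ll = (gammaln(Y + phi) - gammaln(phi) - gammaln(Y + 1)
                  + phi * (np.log(phi) - np.log(phi + mu))
                  + Y * (np.log(mu) - np.log(phi + mu)))
            loglik_total += float(ll.sum()) / n_mc
            if not compute_grad:
                continue
            D = _nb_dll_dmu(Y, mu, phi) * sz[None, :]      # dll/dLambda, (G, Nc)
            grads["loadings"] += (D @ expF) / n_mc
            dF = expF * (D.T @ W)                           # (Nc, L)
            for l in range(L):
                geo = geoms[l]
                gf = dF[:, l]
                du = geo.A[c] @ gf                          # (n,)
                grads["delta"][l] += du / n_mc
                grads["q_chol"][l] += np.tril(np.outer(du, eps[l][s])) / n_mc
                grads["beta0"][l] += (gf.sum() - du.sum()) / n_mc
                grads["beta1"][l] += (X.T @ gf - Z.T @ du) / n_mc
                w_s = wv[l][s]
                kg = geo.Kuf[c] @ gf
                # d/dlog(amplitude): dKuf = Kuf, dKuu = Kuu (jitter scales with amplitude)
                grads["log_amplitude"][l] += (w_s @ kg - v[l][s] @ du) / n_mc
                # d/dlog(lengthscale): dK = K .* D / B  (jitter unaffected; diag D = 0)
                B = fps[l].kernel.lengthscale
                dkg = (geo.Kuf[c] * geo.Duf[c]) @ gf / B
                dku_du = (geo.Kuu * geo.Duu) @ du / B
                grads["log_lengthscale"][l] += (w_s @ dkg - w_s @ dku_du) / n_mc

    kl_total = 0.0
    for l, fp in enumerate(fps):
        geo = geoms[l]
        Lq = fp.q_cov_chol
        kl_total += _gaussian_kl(fp.q_mean, Lq, geo.mz, geo.Lk)
        if not compute_grad:
            continue
        r = geo.mz - fp.q_mean
        a = geo.kuu_solve(r)
        grads["delta"][l] += a            # dKL/ddelta = -a, ELBO grad adds +a
        grads["beta0"][l] -= a.sum()
        grads["beta1"][l] -= Z.T @ a
        Kinv_Lq = geo.kuu_solve(Lq)
        dKL_dLq = np.tril(Kinv_Lq)
        dKL_dLq[np.diag_indices_from(dKL_dLq)] -= 1.0 / np.diag(Lq)
        grads["q_chol"][l] -= dKL_dLq
        # dKL/dK = 0.5 (K^-1 - K^-1 (Omega + r r') K^-1)
        Kinv = geo.kuu_solve(np.eye(n))
        M = Lq @ Lq.T + np.outer(r, r)
        dKL_dK = 0.5 * (Kinv - Kinv @ M @ Kinv)
        grads["log_amplitude"][l] -= float(np.sum(dKL_dK * geo.Kuu))
        B = fp.kernel.lengthscale
        grads["log_lengthscale"][l] -= float(np.sum(dKL_dK * (geo.Kuu * geo.Duu / B)))

    elbo = loglik_total - kl_total
    return elbo, grads


def _chunks_from_sample(sample: SpatialSample) -> list:
    return [(sample.counts.astype(float), sample.size_factors, sample.coords)]


def elbo_single_sample(sample: SpatialSample, grid: InducingGrid,
                       sample_params: SampleGPParams, loadings: np.ndarray,
                       n_mc: int = 100, seed: int = 0) -> float:
    """Monte-Carlo estimate of one sample's ELBO, deterministic given the seed."""
    if n_mc < 1:
        raise ValueError("n_mc must be at least 1")
    rng = np.random.default_rng(seed)
    elbo, _ = elbo_and_grad_sample(_chunks_from_sample(sample), grid,
                                   sample_params, loadings, n_mc, rng,
                                   compute_grad=False)
    return elbo


def elbo_multi_sample(samples: list, grids: list, params: ModelParams,
                      n_mc: int = 100, seed: int = 0) -> float:
    """Joint ELBO over independent samples: the sum of per-sample ELBOs.

    Per-sample Monte-Carlo seeds are derived as seed + sample index, so
    the identity ``elbo_multi == sum_m elbo_single(seed + m)`` holds
    exactly at any parameter point.
    """
    ref = samples[0].gene_ids
    for s in samples[1:]:
        if not np.array_equal(s.gene_ids, ref):
            raise ValueError("samples have inconsistent gene universes")
    total = 0.0
    for m, (sample, grid, sp) in enumerate(zip(samples, grids, params.per_sample)):
        total += elbo_single_sample(sample, grid, sp, params.loadings,
                                    n_mc=n_mc, seed=seed + m)
    return total


def mpnmf_elbo(samples: list, loadings: np.ndarray, factors: list,
               prior_mean: np.ndarray, prior_var: np.ndarray,
               dispersions: list) -> float:
    """Objective of the non-spatial multi-sample model (iid normal factor priors).

    Evaluates  sum_m [ log NB(Y_m | W exp(F_m)', sz_m, phi_m)
                       + sum_{i,l} log N(F_m[i,l] | mu_l, sigma2_l) ].

    The factor prior parameters (mu_l, sigma2_l) are shared across
    samples, so the objective equals the single-sample objective applied
    to the column-concatenated data — fitting the multi-sample model is
    plain probabilistic NMF on the concatenation.
    """
    mu_l = np.asarray(prior_mean, dtype=float)
    s2_l = np.asarray(prior_var, dtype=float)
    if np.any(s2_l <= 0):
        raise ValueError("prior variances must be positive")
    total = 0.0
    for sample, F, phi in zip(samples, factors, dispersions):
        F = np.asarray(F, dtype=float)
        rate = rate_from_factors(loadings, F)
        total += nb_log_likelihood(sample.counts, rate, sample.size_factors, phi)
        z = (F - mu_l[None, :]) ** 2 / s2_l[None, :]
        total += float(-0.5 * (z + np.log(2 * np.pi * s2_l)[None, :]).sum())
    return total
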