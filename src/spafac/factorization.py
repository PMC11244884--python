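"""Scikit-learn-style estimator facade over the multi-sample fit."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .training import FitConfig, fit as _fit

__all__ = ["MultiSampleSpatialFactorization"]


class MultiSampleSpatialFactorization(BaseEstimator):
    """Non-negative spatial factorization across samples with shared gene loadings.

    Decomposes each sample's genes x spots count matrix as
    NB(sz * W exp(F_m)', phi) where the non-negative loadings W are one
    matrix for all samples and each factor column of F_m carries a
    sample-specific Gaussian-process spatial prior, approximated with
    inducing points and fitted by variational inference.  No spatial
    alignment between samples is needed.

    Parameters mirror :class:`spafac.training.FitConfig`.  Fitted
    attributes: ``loadings_`` (genes x L), ``factors_`` (list of
    spots x L posterior-mean factor matrices), ``elbo_trace_``,
    ``model_`` (the full :class:`spafac.model.FittedModel`).

    Examples
    --------
    >>> from spafac.simulate import simulate_dataset
    >>> samples, truth = simulate_dataset(n_genes=50, seed=0)
    >>> est = MultiSampleSpatialFactorization(n_factors=4, max_iterations=50)
    >>> est.fit(samples).loadings_.shape
    (50, 4)
    """

    def __init__(self, n_factors: int = 4, step_size: float = 0.01,
                 max_iterations: int = 1000, convergence_tol: float = 1e-4,
                 n_chunks: int = 1, inducing_fraction: float = 0.35,
                 inducing_method: str = "kmeans", seed: int = 0,
                 dispersion: float = 1.0, n_mc: int = 3):
        self.n_factors = n_factors
        self.step_size = step_size
        self.max_iterations = max_iterations
        self.convergence_tol = convergence_tol
        self.n_chunks = n_chunks
        self.inducing_fraction = inducing_fraction
        self.inducing_method = inducing_method
        self.seed = seed
        self.dispersion = dispersion
        self.n_mc = n_mc

    def _config(self) -> FitConfig:
        return FitConfig(
            n_factors=self.n_factors, step_size=self.step_size,
            max_iterations=self.max_iterations,
            convergence_tol=self.convergence_tol, n_chunks=self.n_chunks,
            inducing_fraction=self.inducing_fraction,
            inducing_method=self.inducing_method, seed=self.seed,
            dispersion=self.dispersion, n_mc=self.n_mc)

    def fit(self, X, y=None):
        """Fit on a list of :class:`spafac.data.SpatialSample` (or a single sample)."""
        samples = X if isinstance(X, (list, tuple)) else [X]
        self.model_ = _fit(list(samples), self._config())
        self.loadings_ = self.model_.params.loadings
        self.factors_ = self.model_.factors
        self.elbo_trace_ = self.model_.elbo_trace
        self.n_samples_ = len(samples)
        return self

    def transform(self, X=None):
        """Return the per-sample posterior-mean factor matrices (spots x L)."""
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted")
        if X is None:
            return self.factors_
        from .training import interpolate_factors
        samples = X if isinstance(X, (list, tuple)) else [X]
        if len(samples) != self.n_samples_:
            raise ValueError("transform expects the fitted samples (per-sample GPs)")
        return [interpolate_factors(sp, grid, s.coords)
                for s, sp, grid in zip(samples, self.model_.params.per_sample,
                                       self.model_.grids)]

    def fit_transform(self, X, y=None):
        return self.fit(X).transform()

    def predicted_mean(self, sample_index: int, size_factors: np.ndarray):
        """NB mean matrix (genes x spots) for one fitted sample."""
        from .model import rate_from_factors
        rate = rate_from_factors(self.loadings_, self.factors_[sample_index])
        return rate * np.asarray(size_factors)[None, :]
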