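"""NB likelihood, rate construction, and the variational objective."""

import numpy as np
import pytest
from scipy.special import gammaln
from scipy.stats import nbinom, poisson

from spafac.data import SpatialSample
from spafac.kernels import GPFactorParams, InducingGrid, KernelParams
from spafac.model import (
    ModelParams,
    SampleGPParams,
    elbo_multi_sample,
    elbo_single_sample,
    mpnmf_elbo,
    nb_log_likelihood,
    rate_from_factors,
)


class TestRateFromFactors:
    def test_zero_factors_give_row_sums(self, rng):
        W = rng.uniform(0.5, 2.0, size=(4, 3))
        F = np.zeros((6, 3))
        np.testing.assert_allclose(rate_from_factors(W, F),
                                   np.tile(W.sum(1)[:, None], (1, 6)))

    def test_scalar_case(self):
        np.testing.assert_allclose(
            rate_from_factors(np.array([[2.0]]), np.array([[np.log(3.0)]])),
            [[6.0]])

    def test_linear_in_loadings(self, rng):
        W = rng.uniform(0.1, 1.0, size=(5, 2))
        F = rng.normal(size=(7, 2))
        W2 = W.copy()
        W2[:, 0] *= 2
        diff = rate_from_factors(W2, F) - rate_from_factors(W, F)
        np.testing.assert_allclose(diff, np.outer(W[:, 0], np.exp(F[:, 0])),
                                   rtol=1e-12)

    def test_zero_loading_row_flagged(self):
        with pytest.warns(RuntimeWarning, match="all-zero"):
            rate_from_factors(np.array([[0.0, 0.0]]), np.zeros((2, 2)))


class TestNBLogLikelihood:
    def test_zero_count_closed_form(self):
        # y=0, mu=1, phi=1 -> log(1/2)
        ll = nb_log_likelihood(np.array([[0]]), np.array([[1.0]]),
                               np.ones(1), 1.0)
        assert ll == pytest.approx(np.log(0.5), rel=1e-12)

    def test_matches_scipy_nbinom(self, rng):
        Y = rng.poisson(3.0, size=(3, 4))
        mu = rng.uniform(0.5, 5.0, size=(3, 4))
        phi = 2.3
        ours = nb_log_likelihood(Y, mu, np.ones(4), phi)
        # scipy parameterization: n=phi, p=phi/(phi+mu)
        ref = nbinom.logpmf(Y, phi, phi / (phi + mu)).sum()
        assert ours == pytest.approx(ref, rel=1e-10)

    def test_entrywise_additivity(self, rng):
        Y = rng.poisson(2.0, size=(2, 2))
        mu = rng.uniform(0.5, 3.0, size=(2, 2))
        total = nb_log_likelihood(Y, mu, np.ones(2), 1.5)
        parts = sum(
            nb_log_likelihood(Y[i:i + 1, j:j + 1], mu[i:i + 1, j:j + 1],
                              np.ones(1), 1.5)
            for i in range(2) for j in range(2))
        assert total == pytest.approx(parts, rel=1e-12)

    def test_poisson_limit(self, rng):
        Y = rng.poisson(3.0, size=(4, 5))
        mu = rng.uniform(0.5, 6.0, size=(4, 5))
        ours = nb_log_likelihood(Y, mu, np.ones(5), 1e6)
        ref = poisson.logpmf(Y, mu).sum()
        assert ours == pytest.approx(ref, abs=1e-3)

    def test_invalid_dispersion(self):
        with pytest.raises(ValueError, match="dispersion"):
            nb_log_likelihood(np.array([[1]]), np.array([[1.0]]), np.ones(1), 0.0)

    def test_zero_mean_positive_count(self):
        with pytest.raises(ValueError, match="zero NB mean"):
            nb_log_likelihood(np.array([[2]]), np.array([[0.0]]), np.ones(1), 1.0)


def _toy_model(rng, n_spots=6, n_genes=3, L=2, n_ind=3, seed_counts=5):
    X = rng.uniform(0, 1, size=(n_spots, 2))
    Y = rng.poisson(seed_counts, size=(n_genes, n_spots))
    s = SpatialSample("m", Y, X)
    Z = rng.uniform(0, 1, size=(n_ind, 2))
    grid = InducingGrid(points=Z)
    fps = []
    for _ in range(L):
        Lq = np.tril(rng.uniform(-0.1, 0.1, size=(n_ind, n_ind)))
        np.fill_diagonal(Lq, rng.uniform(0.2, 0.4, size=n_ind))
        fps.append(GPFactorParams(
            beta0=float(rng.normal(scale=0.3)), beta1=rng.normal(size=2) * 0.2,
            kernel=KernelParams(amplitude=1.0, lengthscale=0.3),
            q_mean=rng.normal(size=n_ind) * 0.5, q_cov_chol=Lq))
    sp = SampleGPParams(factors=fps, dispersion=1.2)
    W = rng.uniform(0.5, 2.0, size=(n_genes, L))
    return s, grid, sp, W


class TestELBOSingleSample:
    def test_point_mass_q_removes_seed_spread(self, rng):
        s, grid, sp, W = _toy_model(rng)
        for fp in sp.factors:
            fp.q_cov_chol = 1e-8 * np.eye(grid.n_points)
        vals = [elbo_single_sample(s, grid, sp, W, n_mc=5, seed=k)
                for k in range(8)]
        assert np.std(vals) < 1e-6

    def test_matches_gauss_hermite_oracle(self):
        """1 gene, 2 spots, 1 factor, 1 inducing point vs dense quadrature over U."""
        rng = np.random.default_rng(11)
        X = np.array([[0.2, 0.3], [0.7, 0.6]])
        Y = np.array([[4, 7]])
        s = SpatialSample("m", Y, X)
        Z = np.array([[0.4, 0.5]])
        grid = InducingGrid(points=Z)
        kp = KernelParams(amplitude=1.0, lengthscale=0.5)
        delta, omega = 0.4, 0.3
        b0, b1 = 0.1, np.array([0.2, -0.1])
        fp = GPFactorParams(beta0=b0, beta1=b1, kernel=kp,
                            q_mean=np.array([delta]),
                            q_cov_chol=np.array([[omega]]))
        sp = SampleGPParams(factors=[fp], dispersion=1.0)
        W = np.array([[1.5]])
        phi = 1.0

        # oracle: E_{u~N(delta, omega^2)}[loglik(F(u))] - KL, scalar algebra only
        kuu = kp.amplitude * (1 + kp.jitter)
        kuf = kp.amplitude * np.exp(
            -np.linalg.norm(X - Z, axis=1) / kp.lengthscale)
        mz = b0 + Z @ b1
        mx = b0 + X @ b1

        def loglik(u):
            f = mx + kuf / kuu * (u - mz[0])
            mu = W[0, 0] * np.exp(f)
            return np.sum(gammaln(Y[0] + phi) - gammaln(phi) - gammaln(Y[0] + 1)
                          + phi * (np.log(phi) - np.log(phi + mu))
                          + Y[0] * (np.log(mu) - np.log(phi + mu)))

        nodes, weights = np.polynomial.hermite.hermgauss(80)
        e_lik = sum(w / np.sqrt(np.pi) * loglik(delta + np.sqrt(2) * omega * x)
                    for x, w in zip(nodes, weights))
        kl = 0.5 * (omega ** 2 / kuu + (mz[0] - delta) ** 2 / kuu - 1
                    + np.log(kuu) - np.log(omega ** 2))
        oracle = e_lik - kl

        est = elbo_single_sample(s, grid, sp, W, n_mc=10_000, seed=0)
        assert est == pytest.approx(oracle, abs=0.05)

    def test_elbo_is_a_lower_bound_on_the_evidence(self):
        """On a tiny instance the ELBO stays below the quadrature evidence."""
        rng = np.random.default_rng(21)
        X = np.array([[0.1, 0.2], [0.8, 0.7]])
        Y = np.array([[3, 6]])
        s = SpatialSample("m", Y, X)
        Z = np.array([[0.5, 0.4]])
        grid = InducingGrid(points=Z)
        kp = KernelParams(amplitude=1.0, lengthscale=0.5)
        fp = GPFactorParams(beta0=0.2, beta1=np.array([0.1, 0.0]), kernel=kp,
                            q_mean=np.array([0.3]),
                            q_cov_chol=np.array([[0.4]]))
        sp = SampleGPParams(factors=[fp], dispersion=1.0)
        W = np.array([[2.0]])
        phi = 1.0
        kuu = kp.amplitude * (1 + kp.jitter)
        kuf = kp.amplitude * np.exp(
            -np.linalg.norm(X - Z, axis=1) / kp.lengthscale)
        mz = fp.beta0 + Z @ fp.beta1
        mx = fp.beta0 + X @ fp.beta1

        def lik(u):
            f = mx + kuf / kuu * (u - mz[0])
            mu = W[0, 0] * np.exp(f)
            return np.exp(np.sum(
                gammaln(Y[0] + phi) - gammaln(phi) - gammaln(Y[0] + 1)
                + phi * (np.log(phi) - np.log(phi + mu))
                + Y[0] * (np.log(mu) - np.log(phi + mu))))

        nodes, weights = np.polynomial.hermite.hermgauss(80)
        evidence = np.log(sum(
            w / np.sqrt(np.pi) * lik(mz[0] + np.sqrt(2 * kuu) * x)
            for x, w in zip(nodes, weights)))
        elbo = elbo_single_sample(s, grid, sp, W, n_mc=2000, seed=0)
        assert elbo <= evidence + 0.05

    def test_true_loadings_beat_perturbed(self, small_two_sample):
        """ELBO evaluated at generating loadings exceeds a shuffled perturbation."""
        samples, truth = small_two_sample
        rng = np.random.default_rng(2)
        s = samples[0]
        X01 = (s.coords - s.coords.min(0)) / (s.coords.max(0) - s.coords.min(0)).max()
        Z = X01[rng.choice(s.n_spots, size=40, replace=False)]
        grid = InducingGrid(points=Z)
        c = truth.spec.factor_scale
        nearest = ((Z[:, None, :] - X01[None, :, :]) ** 2).sum(-1).argmin(1)
        fps = [GPFactorParams(
            beta0=0.0, beta1=np.zeros(2),
            kernel=KernelParams(amplitude=1.0, lengthscale=0.3),
            q_mean=c * truth.true_factors[0][nearest, l],
            q_cov_chol=0.05 * np.eye(40)) for l in range(4)]
        sp = SampleGPParams(factors=fps, dispersion=1.0)
        s01 = SpatialSample(s.sample_id, s.counts, X01,
                            size_factors=s.size_factors)
        W_true = truth.true_loadings
        W_bad = W_true[rng.permutation(W_true.shape[0])]
        e_true = elbo_single_sample(s01, grid, sp, W_true, n_mc=30, seed=0)
        e_bad = elbo_single_sample(s01, grid, sp, W_bad, n_mc=30, seed=0)
        assert e_true > e_bad


class TestELBOMultiSample:
    def _two_sample_setup(self, rng):
        samples, grids, per_sample = [], [], []
        W = rng.uniform(0.5, 2.0, size=(3, 2))
        for m in range(2):
            s, grid, sp, _ = _toy_model(rng)
            samples.append(s)
            grids.append(grid)
            per_sample.append(sp)
        params = ModelParams(loadings=W, per_sample=per_sample)
        return samples, grids, params

    def test_single_sample_reduction(self, rng):
        samples, grids, params = self._two_sample_setup(rng)
        joint = elbo_multi_sample(samples[:1], grids[:1],
                                  ModelParams(loadings=params.loadings,
                                              per_sample=params.per_sample[:1]),
                                  n_mc=7, seed=3)
        single = elbo_single_sample(samples[0], grids[0], params.per_sample[0],
                                    params.loadings, n_mc=7, seed=3)
        assert joint == single

    def test_additivity_identity(self, rng):
        samples, grids, params = self._two_sample_setup(rng)
        joint = elbo_multi_sample(samples, grids, params, n_mc=5, seed=9)
        parts = sum(
            elbo_single_sample(samples[m], grids[m], params.per_sample[m],
                               params.loadings, n_mc=5, seed=9 + m)
            for m in range(2))
        assert joint == pytest.approx(parts, abs=1e-10)

    def test_duplicated_sample_doubles_contribution(self, rng):
        samples, grids, params = self._two_sample_setup(rng)
        dup = ModelParams(loadings=params.loadings,
                          per_sample=[params.per_sample[0]] * 2)
        joint = elbo_multi_sample([samples[0], samples[0]], [grids[0]] * 2,
                                  dup, n_mc=5, seed=4)
        s0 = elbo_single_sample(samples[0], grids[0], params.per_sample[0],
                                params.loadings, n_mc=5, seed=4)
        s1 = elbo_single_sample(samples[0], grids[0], params.per_sample[0],
                                params.loadings, n_mc=5, seed=5)
        assert joint == pytest.approx(s0 + s1, abs=1e-10)


class TestMPNMF:
    def test_identical_samples_double_objective(self, rng):
        Y = rng.poisson(4.0, size=(3, 5))
        s = SpatialSample("a", Y, rng.uniform(size=(5, 2)))
        W = rng.uniform(0.5, 2.0, size=(3, 2))
        F = rng.normal(size=(5, 2)) * 0.3
        one = mpnmf_elbo([s], W, [F], np.zeros(2), np.ones(2), [1.0])
        two = mpnmf_elbo([s, s], W, [F, F], np.zeros(2), np.ones(2), [1.0, 1.0])
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_concatenation_equivalence(self, rng):
        """Multi-sample objective equals the single-sample objective on [Y1 Y2]."""
        Y1 = rng.poisson(4.0, size=(3, 4))
        Y2 = rng.poisson(4.0, size=(3, 6))
        s1 = SpatialSample("a", Y1, rng.uniform(size=(4, 2)))
        s2 = SpatialSample("b", Y2, rng.uniform(size=(6, 2)))
        cat = SpatialSample("ab", np.concatenate([Y1, Y2], axis=1),
                            rng.uniform(size=(10, 2)),
                            size_factors=np.concatenate(
                                [s1.size_factors, s2.size_factors]))
        W = rng.uniform(0.5, 2.0, size=(3, 2))
        F1 = rng.normal(size=(4, 2)) * 0.3
        F2 = rng.normal(size=(6, 2)) * 0.3
        multi = mpnmf_elbo([s1, s2], W, [F1, F2], np.zeros(2), np.ones(2),
                           [1.0, 1.0])
        single = mpnmf_elbo([cat], W, [np.concatenate([F1, F2], axis=0)],
                            np.zeros(2), np.ones(2), [1.0])
        assert multi == pytest.approx(single, rel=1e-12)

    def test_invalid_prior_variance(self, rng):
        s = SpatialSample("a", rng.poisson(4.0, size=(2, 3)),
                          rng.uniform(size=(3, 2)))
        with pytest.raises(ValueError, match="variance"):
            mpnmf_elbo([s], np.ones((2, 1)), [np.zeros((3, 1))],
                       np.zeros(1), np.zeros(1), [1.0])
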