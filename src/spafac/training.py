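"""Distributed model fitting with shared-loading averaging and data chunking.

Each iteration performs one Adam step per sample on that sample's ELBO
with respect to all sample-specific parameters *and* a sample-local
copy of the gene loadings W; the local W candidates are then averaged
across samples and projected to non-negativity (negatives set to zero),
and the projected matrix becomes the shared W for the next iteration.
Because the joint ELBO of independent samples is the sum of per-sample
ELBOs, this distributed scheme follows the same gradient field as a
monolithic fit with a shared step size.

Chunking partitions each sample's spots into random near-equal blocks
that share the sample's inducing grid and variational parameters; block
likelihood gradients are summed and the KL term is counted once, so the
chunked gradient equals the unchunked gradient at any parameter point
while only one block's kernel cross-covariance is held at a time.

Optimization is warm-started from a non-spatial NMF of log1p-scaled
counts and run for up to ``max_iterations`` Adam steps, stopping when
the relative change of the total ELBO over a 5-iteration window falls
below ``convergence_tol``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, asdict, field, replace

import numpy as np
import pandas as pd
from sklearn.decomposition import NMF

from .data import SpatialSample, compute_size_factors
from .kernels import (
    GPFactorParams,
    InducingGrid,
    KernelParams,
    choose_inducing_points,
    rescale_coords,
)
from .model import (
    FittedModel,
    ModelParams,
    SampleGPParams,
    elbo_and_grad_sample,
)

__all__ = [
    "FitConfig",
    "ChunkPlan",
    "chunk_sample",
    "per_sample_update",
    "aggregate_loadings",
    "fit",
    "fit_single_sample",
    "interpolate_factors",
    "initialize_params",
    "save_model",
    "load_model",
    "AdamState",
]

CONVERGENCE_WINDOW = 5


@dataclass
class FitConfig:
    """Tunable fitting settings.

    ``step_size`` is the Adam learning rate, shared across all
    parameters and samples (a requirement for the averaging scheme to
    track the joint gradient).  ``inducing_fraction`` defaults to 0.35
    of the spots; ``n_chunks`` defaults to 1 (no chunking).
    ``dispersion`` is the fixed NB dispersion phi per sample.
    """

    n_factors: int = 4
    step_size: float = 0.01
    max_iterations: int = 1000
    convergence_tol: float = 1e-4
    n_chunks: int = 1
    inducing_fraction: float = 0.35
    inducing_method: str = "kmeans"
    seed: int = 0
    dispersion: float = 1.0
    n_mc: int = 3

    def __post_init__(self):
        if self.n_factors < 1:
            raise ValueError("n_factors must be >= 1")
        if self.step_size < 0:
            raise ValueError("step_size must be nonnegative")
        if not 0 < self.inducing_fraction <= 1:
            raise ValueError("inducing_fraction must be in (0, 1]")
        if self.n_chunks < 1:
            raise ValueError("n_chunks must be >= 1")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.n_mc < 1:
            raise ValueError("n_mc must be >= 1")


@dataclass
class ChunkPlan:
    """Partition of each sample's spot indices into disjoint near-equal blocks."""

    blocks: list
    seed: int = 0


def chunk_sample(sample: SpatialSample, n_chunks: int, seed: int = 0) -> list:
    """Seeded random partition of a sample's spots into near-equal chunks.

    Block sizes differ by at most one; n_chunks = 1 returns a single
    chunk with the original spot order.
    """
    N = sample.n_spots
    if n_chunks > N:
        raise ValueError(f"n_chunks={n_chunks} exceeds the {N} spots of the sample")
    if n_chunks == 1:
        return [sample.subset_spots(np.arange(N))]
    rng = np.random.default_rng(seed)
    perm = rng.permutation(N)
    sizes = np.full(n_chunks, N // n_chunks)
    sizes[: N % n_chunks] += 1
    out, start = [], 0
    for sz in sizes:
        out.append(sample.subset_spots(np.sort(perm[start:start + sz])))
        start += sz
    return out


# ---------------------------------------------------------------------------
# flat parameter vectors for Adam

_SCALAR_KEYS = ("beta0", "log_amplitude", "log_lengthscale")


def _pack(sample_params: SampleGPParams, W: np.ndarray) -> dict:
    """Structured -> raw (unconstrained) parameter dict.

    The variational Cholesky diagonal is stored in log space; kernel
    amplitude and lengthscale in log space; everything else as-is.
    """
    fps = sample_params.factors
    L = len(fps)
    n = fps[0].q_mean.shape[0]
    raw = {
        "loadings": np.asarray(W, dtype=float).copy(),
        "beta0": np.array([fp.beta0 for fp in fps]),
        "beta1": np.stack([fp.beta1 for fp in fps]),
        "delta": np.stack([fp.q_mean for fp in fps]),
        "q_chol_raw": np.zeros((L, n, n)),
        "log_amplitude": np.array([np.log(fp.kernel.amplitude) for fp in fps]),
        "log_lengthscale": np.array([np.log(fp.kernel.lengthscale) for fp in fps]),
    }
    for l, fp in enumerate(fps):
        C = np.tril(fp.q_cov_chol, -1)
        C[np.diag_indices(n)] = np.log(np.diag(fp.q_cov_chol))
        raw["q_chol_raw"][l] = C
    return raw


def _unpack(raw: dict, template: SampleGPParams) -> tuple:
    """Raw dict -> (SampleGPParams, W)."""
    L, n, _ = raw["q_chol_raw"].shape
    fps = []
    for l in range(L):
        C = raw["q_chol_raw"][l]
        Lq = np.tril(C, -1)
        Lq[np.diag_indices(n)] = np.exp(np.diag(C))
        fps.append(GPFactorParams(
            beta0=float(raw["beta0"][l]),
            beta1=raw["beta1"][l].copy(),
            kernel=KernelParams(
                amplitude=float(np.exp(raw["log_amplitude"][l])),
                lengthscale=float(np.exp(raw["log_lengthscale"][l])),
                jitter=template.factors[l].kernel.jitter,
            ),
            q_mean=raw["delta"][l].copy(),
            q_cov_chol=Lq,
        ))
    sp = SampleGPParams(
        factors=fps,
        dispersion=template.dispersion,
        coord_offset=template.coord_offset,
        coord_scale=template.coord_scale,
    )
    return sp, raw["loadings"].copy()


def _grads_to_raw(grads: dict, raw: dict) -> dict:
    """Chain structured ELBO gradients through the raw parameterization."""
    out = {
        "loadings": grads["loadings"],
        "beta0": grads["beta0"],
        "beta1": grads["beta1"],
        "delta": grads["delta"],
        "log_amplitude": grads["log_amplitude"],
        "log_lengthscale": grads["log_lengthscale"],
    }
    g = grads["q_chol"].copy()
    L, n, _ = g.shape
    for l in range(L):
        diag_L = np.exp(np.diag(raw["q_chol_raw"][l]))
        g[l][np.diag_indices(n)] *= diag_L
    out["q_chol_raw"] = g
    return out


class AdamState:
    """First/second-moment accumulators for one sample's raw parameter dict."""

    def __init__(self, raw: dict, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.m = {k: np.zeros_like(v) for k, v in raw.items()}
        self.v = {k: np.zeros_like(v) for k, v in raw.items()}
        self.t = 0
        self.beta1, self.beta2, self.eps = beta1, beta2, eps

    def step(self, raw: dict, grads_raw: dict, step_size: float) -> dict:
        """One Adam ascent step; returns the updated raw dict."""
        self.t += 1
        out = {}
        for k, p in raw.items():
            g = grads_raw[k]
            if not np.all(np.isfinite(g)):
                raise FloatingPointError(f"non-finite gradient for parameter {k!r}")
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / (1 - self.beta1 ** self.t)
            vhat = self.v[k] / (1 - self.beta2 ** self.t)
            out[k] = p + step_size * mhat / (np.sqrt(vhat) + self.eps)
        return out


def _chunk_triples(chunks: list) -> list:
    return [(c.counts.astype(float), c.size_factors, c.coords) for c in chunks]


def per_sample_update(sample_chunks: list, grid: InducingGrid,
                      sample_params: SampleGPParams, shared_W: np.ndarray,
                      step_size: float, seed: int = 0,
                      adam_state: AdamState | None = None,
                      n_mc: int = 3,
                      rng: np.random.Generator | None = None):
    """One Adam step on one sample's ELBO (summed over its chunks).

    Updates all sample-specific parameters and a sample-local copy of
    the shared loadings, starting from ``shared_W``.  The returned
    loading candidate is *not* projected; projection happens after
    cross-sample averaging (see :func:`aggregate_loadings`).

    Returns (updated SampleGPParams, candidate W, AdamState, elbo value).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    raw = _pack(sample_params, shared_W)
    if adam_state is None:
        adam_state = AdamState(raw)
    elbo, grads = elbo_and_grad_sample(
        _chunk_triples(sample_chunks), grid, sample_params, shared_W, n_mc, rng)
    raw_new = adam_state.step(raw, _grads_to_raw(grads, raw), step_size)
    sp_new, W_candidate = _unpack(raw_new, sample_params)
    return sp_new, W_candidate, adam_state, elbo


def aggregate_loadings(W_candidates: list) -> np.ndarray:
    """Average loading candidates across samples, then zero out negatives."""
    if not W_candidates:
        raise ValueError("no loading candidates to aggregate")
    W = np.mean([np.asarray(w, dtype=float) for w in W_candidates], axis=0)
    return np.maximum(W, 0.0)


def initialize_params(samples: list, grids: list, config: FitConfig,
                      coord_transforms: list) -> tuple:
    """Warm start from a seeded non-spatial KL-NMF of depth-normalized counts.

    The model's mean structure is exactly a non-negative factorization
    of Y/sz (with activities exp(F)), so the warm start runs
    multiplicative-update NMF with KL divergence on Y/sz.  Loadings come
    from the NMF gene basis; per-spot activities (column-normalized to
    mean one) are log-transformed to initialize F, and the variational
    means delta are set to the F value at the spot nearest each inducing
    point.  Omega starts at 0.01*I, the GP mean at zero, the kernel at
    amplitude 1 and lengthscale 0.1 on unit-box coordinates.
    """
    L = config.n_factors
    V = np.concatenate(
        [s.counts / s.size_factors[None, :] for s in samples], axis=1)
    nmf = NMF(n_components=L, init="nndsvda", solver="mu",
              beta_loss="kullback-leibler", max_iter=200,
              random_state=config.seed, tol=1e-6)
    H_spots = nmf.fit_transform(V.T)          # (total_spots, L) activities
    W0 = nmf.components_.T                    # (genes, L)
    scale = H_spots.mean(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    H_spots = H_spots / scale[None, :]
    W0 = np.maximum(W0 * scale[None, :], 1e-8)
    F0 = np.log(np.maximum(H_spots, 1e-2))

    per_sample, F0_list, start = [], [], 0
    for m, (s, grid) in enumerate(zip(samples, grids)):
        F_m = F0[start:start + s.n_spots]
        start += s.n_spots
        F0_list.append(F_m)
        offset, cscale = coord_transforms[m]
        X = (s.coords - offset) / cscale
        # nearest spot to each inducing point
        d2 = ((grid.points[:, None, :] - X[None, :, :]) ** 2).sum(-1)
        nearest = d2.argmin(axis=1)
        n = grid.n_points
        fps = []
        for l in range(L):
            fps.append(GPFactorParams(
                beta0=0.0,
                beta1=np.zeros(2),
                kernel=KernelParams(amplitude=1.0, lengthscale=0.1),
                q_mean=F_m[nearest, l].copy(),
                q_cov_chol=0.1 * np.eye(n),
            ))
        per_sample.append(SampleGPParams(
            factors=fps, dispersion=config.dispersion,
            coord_offset=offset, coord_scale=cscale))
    return W0, per_sample, F0_list


def interpolate_factors(sample_params: SampleGPParams, grid: InducingGrid,
                        X_all: np.ndarray, in_model_frame: bool = False) -> np.ndarray:
    """Posterior-mean factors at arbitrary locations (spots x L).

    Plugs the variational mean delta into the GP conditional mean.
    ``X_all`` is in the sample's original coordinate units unless
    ``in_model_frame`` is true (already rescaled to the unit box).
    """
    X = np.atleast_2d(np.asarray(X_all, dtype=float))
    if not in_model_frame:
        X = (X - sample_params.coord_offset) / sample_params.coord_scale
    from .kernels import exponential_kernel
    from scipy.linalg import solve_triangular
    from .kernels import chol_with_jitter
    Z = grid.points
    out = np.empty((X.shape[0], len(sample_params.factors)))
    for l, fp in enumerate(sample_params.factors):
        Kuu = exponential_kernel(Z, Z, fp.kernel)
        Kuf = exponential_kernel(Z, X, fp.kernel)
        Lk, _ = chol_with_jitter(Kuu, fp.kernel.amplitude, fp.kernel.jitter)
        tmp = solve_triangular(Lk, Kuf, lower=True)
        A = solve_triangular(Lk.T, tmp, lower=False)
        out[:, l] = fp.mean_at(X) + A.T @ (fp.q_mean - fp.mean_at(Z))
    return out


def _prepare_samples(samples: list) -> tuple:
    """Size factors (if unset) and unit-box coordinate rescaling."""
    prepared, transforms = [], []
    for s in samples:
        if np.allclose(s.size_factors, 1.0):
            sz = compute_size_factors(s)
            s = replace(s, size_factors=sz)
        scaled, offset, cscale = rescale_coords(s.coords)
        transforms.append((offset, cscale))
        prepared.append(replace(s, coords=scaled))
    return prepared, transforms


def _identifiability_rescale(W: np.ndarray, per_sample: list) -> np.ndarray:
    """Normalize each loading column to unit sum, absorbing log-scale into the factors."""
    W = W.copy()
    for l in range(W.shape[1]):
        s = W[:, l].sum()
        if s > 0:
            W[:, l] /= s
            shift = np.log(s)
            for sp in per_sample:
                sp.factors[l].q_mean += shift
                sp.factors[l].beta0 += shift
    return W


def fit(samples: list, config: FitConfig) -> FittedModel:
    """Fit the multi-sample model (the distributed "per-sample update + averaging" scheme).

    Each iteration: one Adam step per sample (over its chunks) updating
    the sample-specific parameters and a local loading copy, then the
    local copies are averaged and negatives zeroed to form the next
    shared W.  Stops when the relative total-ELBO change over a
    5-iteration window drops below ``convergence_tol`` or after
    ``max_iterations``.  Fully deterministic given ``config.seed``.
    """
    if not samples:
        raise ValueError("need at least one sample")
    ref = samples[0].gene_ids
    for s in samples[1:]:
        if not np.array_equal(s.gene_ids, ref):
            raise ValueError("samples must share one gene universe")

    work, transforms = _prepare_samples(samples)
    grids = [choose_inducing_points(s.coords, config.inducing_fraction,
                                    config.inducing_method, seed=config.seed + m)
             for m, s in enumerate(work)]
    chunks = [chunk_sample(s, config.n_chunks, seed=config.seed + m)
              for m, s in enumerate(work)]
    W, per_sample, _ = initialize_params(work, grids, config, transforms)

    M = len(work)
    rngs = [np.random.default_rng(config.seed + m) for m in range(M)]
    adam = [None] * M
    trace = []
    for it in range(config.max_iterations):
        candidates = []
        total = 0.0
        for m in range(M):
            per_sample[m], Wc, adam[m], elbo_m = per_sample_update(
                chunks[m], grids[m], per_sample[m], W, config.step_size,
                adam_state=adam[m], n_mc=config.n_mc, rng=rngs[m])
            candidates.append(Wc)
            total += elbo_m
        if not np.isfinite(total):
            raise FloatingPointError(f"ELBO diverged at iteration {it}")
        W = aggregate_loadings(candidates)
        trace.append(total)
        if it >= CONVERGENCE_WINDOW:
            prev = trace[-1 - CONVERGENCE_WINDOW]
            if abs(trace[-1] - prev) / (abs(prev) + 1e-12) < config.convergence_tol:
                break

    W = _identifiability_rescale(W, per_sample)
    factors = [interpolate_factors(per_sample[m], grids[m], work[m].coords,
                                   in_model_frame=True)
               for m in range(M)]
    params = ModelParams(loadings=W, per_sample=per_sample,
                         n_factors=config.n_factors, gene_ids=ref)
    return FittedModel(params=params, factors=factors,
                       elbo_trace=np.asarray(trace), config=config, grids=grids)


def fit_single_sample(sample: SpatialSample, config: FitConfig) -> FittedModel:
    """Direct single-sample fit (the one-sample spatial factorization path).

    Runs the same per-sample Adam updates without the cross-sample
    averaging step (the loading candidate is projected directly), which
    is what the multi-sample scheme degenerates to at M=1.
    """
    work, transforms = _prepare_samples([sample])
    grids = [choose_inducing_points(work[0].coords, config.inducing_fraction,
                                    config.inducing_method, seed=config.seed)]
    chunks = [chunk_sample(work[0], config.n_chunks, seed=config.seed)]
    W, per_sample, _ = initialize_params(work, grids, config, transforms)
    rng = np.random.default_rng(config.seed)
    state = None
    trace = []
    for it in range(config.max_iterations):
        per_sample[0], Wc, state, elbo = per_sample_update(
            chunks[0], grids[0], per_sample[0], W, config.step_size,
            adam_state=state, n_mc=config.n_mc, rng=rng)
        if not np.isfinite(elbo):
            raise FloatingPointError(f"ELBO diverged at iteration {it}")
        W = np.maximum(Wc, 0.0)
        trace.append(elbo)
        if it >= CONVERGENCE_WINDOW:
            prev = trace[-1 - CONVERGENCE_WINDOW]
            if abs(trace[-1] - prev) / (abs(prev) + 1e-12) < config.convergence_tol:
                break
    W = _identifiability_rescale(W, per_sample)
    factors = [interpolate_factors(per_sample[0], grids[0], work[0].coords,
                                   in_model_frame=True)]
    params = ModelParams(loadings=W, per_sample=per_sample,
                         n_factors=config.n_factors, gene_ids=sample.gene_ids)
    return FittedModel(params=params, factors=factors,
                       elbo_trace=np.asarray(trace), config=config, grids=grids)


# ---------------------------------------------------------------------------
# plain-text serialization


def save_model(model: FittedModel, out_dir: str, samples: list | None = None) -> None:
    """Write a fitted model to a directory of TSV/key=value text files."""
    os.makedirs(out_dir, exist_ok=True)
    L = model.params.n_factors
    cols = [f"factor_{l + 1}" for l in range(L)]
    pd.DataFrame(model.params.loadings, index=model.params.gene_ids,
                 columns=cols).to_csv(
        os.path.join(out_dir, "loadings.tsv"), sep="\t", index_label="gene")
    pd.DataFrame({"elbo": model.elbo_trace}).to_csv(
        os.path.join(out_dir, "elbo_trace.tsv"), sep="\t", index_label="iteration")
    if model.config is not None:
        with open(os.path.join(out_dir, "config.txt"), "w") as fh:
            for k, v in asdict(model.config).items():
                fh.write(f"{k}={v}\n")
    for m, sp in enumerate(model.params.per_sample):
        sid = samples[m].sample_id if samples else f"sample_{m}"
        spot_ids = (samples[m].spot_ids if samples
                    else [f"spot_{i}" for i in range(model.factors[m].shape[0])])
        pd.DataFrame(model.factors[m], index=spot_ids, columns=cols).to_csv(
            os.path.join(out_dir, f"factors_{sid}.tsv"), sep="\t",
            index_label="spot_id")
        rows = []
        for l, fp in enumerate(sp.factors):
            rows.append({
                "factor": l + 1, "beta0": fp.beta0,
                "beta1_x": fp.beta1[0], "beta1_y": fp.beta1[1],
                "amplitude": fp.kernel.amplitude,
                "lengthscale": fp.kernel.lengthscale,
                "dispersion": sp.dispersion,
                "coord_offset_x": sp.coord_offset[0],
                "coord_offset_y": sp.coord_offset[1],
                "coord_scale": sp.coord_scale,
            })
        pd.DataFrame(rows).to_csv(
            os.path.join(out_dir, f"gp_params_{sid}.tsv"), sep="\t", index=False)
        pd.DataFrame(
            np.column_stack([fp.q_mean for fp in sp.factors]), columns=cols
        ).to_csv(os.path.join(out_dir, f"delta_{sid}.tsv"), sep="\t", index=False)
        if m < len(model.grids):
            pd.DataFrame(model.grids[m].points, columns=["x", "y"]).to_csv(
                os.path.join(out_dir, f"inducing_{sid}.tsv"), sep="\t", index=False)


def load_loadings(model_dir: str) -> pd.DataFrame:
    return pd.read_csv(os.path.join(model_dir, "loadings.tsv"),
                       sep="\t", index_col="gene")


def load_factors(model_dir: str, sample_id: str) -> pd.DataFrame:
    return pd.read_csv(os.path.join(model_dir, f"factors_{sample_id}.tsv"),
                       sep="\t", index_col="spot_id")


def load_model(model_dir: str) -> dict:
    """Read back the serialized pieces of a fitted model as data frames."""
    out = {"loadings": load_loadings(model_dir)}
    out["elbo_trace"] = pd.read_csv(
        os.path.join(model_dir, "elbo_trace.tsv"), sep="\t")["elbo"].to_numpy()
    out["factors"] = {}
    for fname in sorted(os.listdir(model_dir)):
        if fname.startswith("factors_") and fname.endswith(".tsv"):
            sid = fname[len("factors_"):-len(".tsv")]
            out["factors"][sid] = load_factors(model_dir, sid)
    cfg_path = os.path.join(model_dir, "config.txt")
    if os.path.exists(cfg_path):
        cfg = {}
        with open(cfg_path) as fh:
            for line in fh:
                k, _, v = line.strip().partition("=")
                cfg[k] = v
        out["config"] = cfg
    return out
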