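"""Evaluation statistics for fitted spatial factorizations.

Covers the statistics used to validate the factorization: Moran's I
spatial autocorrelation per factor, automatic matching of estimated to
true factors, pattern-marker gene extraction from the loading matrix,
annotation association through multinomial regression, k-means domain
clustering with the adjusted Rand index, and Poisson-deviance goodness
of fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import adjusted_rand_score
from sklearn.neighbors import kneighbors_graph

__all__ = [
    "EvalReport",
    "morans_i",
    "match_factors",
    "pattern_markers",
    "layer_prediction",
    "cluster_factors",
    "adjusted_rand_index",
    "goodness_of_fit_deviance",
]


@dataclass
class EvalReport:
    """Bundle of evaluation statistics for one fitted model."""

    morans_i: np.ndarray = None
    matching: tuple = None
    accuracy: float = None
    model_deviance: float = None
    ari: float = None
    gof_deviance: float = None
    extras: dict = field(default_factory=dict)


def morans_i(values: np.ndarray, coords: np.ndarray, k_neighbors: int = 6,
             weights: np.ndarray | None = None) -> float:
    """Moran's I spatial autocorrelation with symmetrized binary k-NN weights.

    I = (n / S0) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2,
    with w_ii = 0 and S0 the total weight.  A constant input returns 0
    by convention.  ``weights`` overrides the k-NN construction with an
    explicit (dense or sparse) weight matrix.
    """
    x = np.asarray(values, dtype=float).ravel()
    n = x.shape[0]
    if n < 3:
        raise ValueError("Moran's I needs at least 3 spots")
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0:
        return 0.0
    if weights is None:
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        if k_neighbors >= n:
            raise ValueError("k_neighbors must be smaller than the number of spots")
        Gk = kneighbors_graph(coords, n_neighbors=k_neighbors, mode="connectivity")
        Wmat = ((Gk + Gk.T) > 0).astype(float)
        Wmat.setdiag(0)
        S0 = Wmat.sum()
        cross = float(z @ (Wmat @ z))
    else:
        Wmat = np.asarray(weights, dtype=float)
        np.fill_diagonal(Wmat, 0.0)
        S0 = Wmat.sum()
        cross = float(z @ Wmat @ z)
    return (n / S0) * cross / denom


def _corr_matrix(F_est: np.ndarray, F_true: np.ndarray) -> np.ndarray:
    """Pearson correlations between every (estimated, true) factor pair."""
    Le, Lt = F_est.shape[1], F_true.shape[1]
    C = np.zeros((Le, Lt))
    for i in range(Le):
        for j in range(Lt):
            a, b = F_est[:, i], F_true[:, j]
            sa, sb = a.std(), b.std()
            if sa == 0 or sb == 0:
                C[i, j] = 0.0
            else:
                C[i, j] = float(np.corrcoef(a, b)[0, 1])
    return C


def match_factors(F_est: list | np.ndarray, F_true: list | np.ndarray):
    """One-to-one pairing of estimated to true factors maximizing total correlation.

    ``F_est`` / ``F_true`` are per-sample (spots x L) matrices (or a
    single matrix); correlations are computed on the concatenation of
    all samples' spots.  Exhaustive search for <= 8 estimated factors,
    Hungarian assignment otherwise.  Returns (assignment, correlations)
    where assignment[j] is the estimated-factor index matched to true
    factor j and correlations[j] its Pearson r.
    """
    if isinstance(F_est, (list, tuple)):
        F_est = np.concatenate([np.asarray(f) for f in F_est], axis=0)
    if isinstance(F_true, (list, tuple)):
        F_true = np.concatenate([np.asarray(f) for f in F_true], axis=0)
    F_est, F_true = np.asarray(F_est, float), np.asarray(F_true, float)
    if F_est.shape[0] != F_true.shape[0]:
        raise ValueError("estimated and true factors must cover the same spots")
    Le, Lt = F_est.shape[1], F_true.shape[1]
    if Le < Lt:
        raise ValueError("fewer estimated factors than true factors")
    C = _corr_matrix(F_est, F_true)
    if Le <= 8:
        best, best_total = None, -np.inf
        for perm in permutations(range(Le), Lt):
            total = sum(C[perm[j], j] for j in range(Lt))
            if total > best_total:
                best_total, best = total, perm
        assignment = np.asarray(best, dtype=int)
    else:
        rows, cols = linear_sum_assignment(-C)
        inv = {j: i for i, j in zip(rows, cols)}
        assignment = np.array([inv[j] for j in range(Lt)], dtype=int)
    corrs = np.array([C[assignment[j], j] for j in range(Lt)])
    return assignment, corrs


def pattern_markers(loadings: np.ndarray, n_top: int = 10) -> list:
    """Per-factor marker genes ranked by specificity of their scaled loading row.

    Each gene's loading row is scaled to unit maximum; its distance to
    the unit vector e_l scores how exclusively it loads on factor l.  A
    gene is assigned to the factor whose e_l is nearest (ties: lowest
    factor index) and genes within each factor are ranked by ascending
    distance.  All-zero rows are excluded with a warning.
    """
    W = np.asarray(loadings, dtype=float)
    G, L = W.shape
    row_max = W.max(axis=1)
    zero = row_max == 0
    if np.any(zero):
        warnings.warn(f"{int(zero.sum())} gene(s) with all-zero loadings excluded "
                      "from marker ranking", RuntimeWarning)
    lists = [[] for _ in range(L)]
    scaled = np.where(zero[:, None], 0.0, W / np.where(row_max == 0, 1.0, row_max)[:, None])
    eye = np.eye(L)
    for g in range(G):
        if zero[g]:
            continue
        d = np.linalg.norm(scaled[g][None, :] - eye, axis=1)
        l_star = int(np.argmin(d))          # argmin takes the lowest index on ties
        lists[l_star].append((d[l_star], g))
    out = []
    for l in range(L):
        ranked = sorted(lists[l], key=lambda t: (t[0], t[1]))
        out.append([g for _, g in ranked[:n_top]])
    return out


def layer_prediction(factors: np.ndarray, labels: np.ndarray,
                     ridge: float = 1e-6, max_iter: int = 2000) -> tuple:
    """Multinomial-regression association between factors and discrete annotations.

    Fits a multinomial logistic regression of the labels on the factor
    matrix (intercept included, lbfgs, tiny L2 ridge for stability under
    separation) and returns (in-sample accuracy, residual deviance
    -2*loglik).  Spots with missing labels are excluded.
    """
    F = np.atleast_2d(np.asarray(factors, dtype=float))
    y = np.asarray(labels)
    keep = np.array([lab is not None and lab == lab for lab in y])
    F, y = F[keep], y[keep].astype(str)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least 2 label classes")
    clf = LogisticRegression(C=1.0 / ridge, solver="lbfgs", max_iter=max_iter)
    clf.fit(F, y)
    proba = clf.predict_proba(F)
    acc = float((clf.predict(F) == y).mean())
    idx = {c: j for j, c in enumerate(clf.classes_)}
    ll = float(np.sum(np.log(np.maximum(
        proba[np.arange(len(y)), [idx[c] for c in y]], 1e-300))))
    return acc, -2.0 * ll


def cluster_factors(factors: np.ndarray, n_domains: int, method: str = "kmeans",
                    seed: int = 0) -> np.ndarray:
    """Discrete spatial domains from the factor matrix (seeded k-means)."""
    F = np.atleast_2d(np.asarray(factors, dtype=float))
    if n_domains < 2:
        raise ValueError("n_domains must be >= 2")
    if n_domains > F.shape[0]:
        raise ValueError("more domains requested than spots")
    if method != "kmeans":
        raise ValueError(f"unknown clustering method {method!r}")
    km = KMeans(n_clusters=n_domains, random_state=seed, n_init=10)
    return km.fit_predict(F)


def adjusted_rand_index(a: np.ndarray, b: np.ndarray) -> float:
    """Chance-corrected agreement between two partitions (standard ARI)."""
    a, b = np.asarray(a).ravel(), np.asarray(b).ravel()
    if a.shape[0] != b.shape[0]:
        raise ValueError("partitions must have equal length")
    return float(adjusted_rand_score(a, b))


def goodness_of_fit_deviance(observed: np.ndarray,
                             predicted_mean: np.ndarray) -> float:
    """Total Poisson deviance 2*sum[y ln(y/mu) - (y - mu)] between counts and fit.

    Zero observed counts contribute -(0 - mu) = mu; a zero prediction
    with a positive count is an error (infinite deviance).
    """
    Y = np.asarray(observed, dtype=float)
    mu = np.asarray(predicted_mean, dtype=float)
    if Y.shape != mu.shape:
        raise ValueError("observed and predicted shapes differ")
    if np.any((mu <= 0) & (Y > 0)):
        raise ValueError("zero predicted mean with a positive observed count")
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(Y > 0,
                        Y * np.log(np.where(Y > 0, Y, 1.0) / np.where(mu > 0, mu, 1.0)),
                        0.0)
    return float(2.0 * np.sum(term - (Y - mu)))
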