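"""Input/output and preprocessing for multi-sample spatial count data.

A sample is a genes x spots count matrix tied to 2-D spot coordinates.
Counts are stored on disk either as a dense CSV/TSV (gene ids as row
names, spot ids as the header) or as a MatrixMarket triplet plus
``genes.tsv`` / ``spots.tsv`` id files.  Coordinates are a TSV with
columns ``spot_id``, ``x``, ``y``.

Preprocessing follows the standard count-model recipe: per-spot size
factors are library sizes normalized to mean one, and informative genes
are ranked by their Poisson deviance against a constant-rate null with
a size-factor offset, taking the maximum deviance across samples.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix

__all__ = [
    "SpatialSample",
    "GeneSelection",
    "load_sample",
    "write_sample",
    "compute_size_factors",
    "poisson_deviance_per_gene",
    "select_genes",
    "DevianceGeneSelector",
]


@dataclass
class SpatialSample:
    """One sample's counts, spot coordinates and per-spot metadata.

    Parameters
    ----------
    sample_id : str
        Identifier carried through outputs.
    counts : ndarray of shape (n_genes, n_spots)
        Non-negative integer expression counts.
    coords : ndarray of shape (n_spots, 2)
        Spatial coordinates of the spots (any physical units).
    size_factors : ndarray of shape (n_spots,)
        Positive per-spot scale factors; all ones until computed.
    labels : ndarray of shape (n_spots,), optional
        Discrete per-spot annotations (e.g. layers) for evaluation.
    gene_ids, spot_ids : sequences of str
        Unique identifiers for rows and columns of ``counts``.
    """

    sample_id: str
    counts: np.ndarray
    coords: np.ndarray
    size_factors: np.ndarray = None
    labels: np.ndarray | None = None
    gene_ids: np.ndarray = None
    spot_ids: np.ndarray = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D genes x spots matrix")
        if np.any(self.counts < 0):
            raise ValueError("counts contain negative entries")
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (self.counts.shape[1], 2):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match "
                f"{self.counts.shape[1]} spots"
            )
        if self.size_factors is None:
            self.size_factors = np.ones(self.counts.shape[1])
        self.size_factors = np.asarray(self.size_factors, dtype=float)
        if self.size_factors.shape != (self.counts.shape[1],):
            raise ValueError("size_factors length must equal the number of spots")
        if np.any(self.size_factors <= 0):
            raise ValueError("size_factors must be strictly positive")
        if self.gene_ids is None:
            self.gene_ids = np.array([f"gene_{g}" for g in range(self.n_genes)])
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if self.spot_ids is None:
            self.spot_ids = np.array([f"spot_{i}" for i in range(self.n_spots)])
        self.spot_ids = np.asarray(self.spot_ids, dtype=object)
        if len(set(self.gene_ids)) != self.n_genes:
            raise ValueError("gene_ids are not unique")
        if len(set(self.spot_ids)) != self.n_spots:
            raise ValueError("spot_ids are not unique")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if self.labels.shape != (self.n_spots,):
                raise ValueError("labels length must equal the number of spots")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_spots(self) -> int:
        return self.counts.shape[1]

    def subset_genes(self, gene_indices) -> "SpatialSample":
        """Return a copy restricted to the given gene rows (in that order)."""
        idx = np.asarray(gene_indices, dtype=int)
        return replace(
            self,
            counts=self.counts[idx].copy(),
            gene_ids=self.gene_ids[idx].copy(),
        )

    def subset_spots(self, spot_indices) -> "SpatialSample":
        """Return a copy restricted to the given spot columns (in that order)."""
        idx = np.asarray(spot_indices, dtype=int)
        return replace(
            self,
            counts=self.counts[:, idx].copy(),
            coords=self.coords[idx].copy(),
            size_factors=self.size_factors[idx].copy(),
            labels=None if self.labels is None else self.labels[idx].copy(),
            spot_ids=self.spot_ids[idx].copy(),
        )


@dataclass
class GeneSelection:
    """Result of deviance-based gene ranking.

    ``gene_indices`` index into the original gene order, sorted by
    descending max-across-samples deviance (ties broken by ascending
    original index).  ``deviances`` holds the per-gene, per-sample
    Poisson deviances for all genes.
    """

    gene_indices: np.ndarray
    deviances: np.ndarray
    criterion: np.ndarray
    n_requested: int = field(default=0)


def _read_counts_dense(path: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    sep = "\t" if path.endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    counts = df.to_numpy()
    return counts, df.index.to_numpy(dtype=object), df.columns.to_numpy(dtype=object)


def _read_counts_mtx(path: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mat = mmread(path)
    counts = np.asarray(mat.todense()) if hasattr(mat, "todense") else np.asarray(mat)
    base = os.path.dirname(path)
    genes = pd.read_csv(os.path.join(base, "genes.tsv"), header=None)[0].to_numpy(dtype=object)
    spots = pd.read_csv(os.path.join(base, "spots.tsv"), header=None)[0].to_numpy(dtype=object)
    if counts.shape != (len(genes), len(spots)):
        raise ValueError(
            f"MTX shape {counts.shape} does not match {len(genes)} genes x "
            f"{len(spots)} spots from the index files"
        )
    return counts, genes, spots


def load_sample(counts_path: str, coords_path: str, sample_id: str) -> SpatialSample:
    """Load one sample from a counts file and a coordinate table.

    Counts may be dense CSV/TSV (genes x spots, gene-id row names, spot-id
    header) or MatrixMarket ``.mtx`` with sibling ``genes.tsv``/``spots.tsv``.
    Spots are returned in the order of the coordinates file; count columns
    are reordered to match.  Size factors are left at one.
    """
    if counts_path.endswith(".mtx"):
        counts, gene_ids, spot_ids = _read_counts_mtx(counts_path)
    else:
        counts, gene_ids, spot_ids = _read_counts_dense(counts_path)
    if not np.allclose(counts, np.round(counts)) or np.any(counts < 0):
        raise ValueError("counts must be non-negative integers")
    counts = np.asarray(np.round(counts), dtype=np.int64)

    coords_df = pd.read_csv(coords_path, sep="\t")
    required = {"spot_id", "x", "y"}
    if not required.issubset(coords_df.columns):
        raise ValueError(f"coordinates file must have columns {sorted(required)}")
    coord_ids = coords_df["spot_id"].astype(str).to_numpy(dtype=object)

    pos = {s: j for j, s in enumerate(spot_ids)}
    missing = [s for s in coord_ids if s not in pos]
    if missing:
        raise ValueError(
            "spot ids in coordinates absent from counts: " + ", ".join(map(str, missing))
        )
    extra = set(spot_ids) - set(coord_ids)
    if extra:
        raise ValueError(
            "spot ids in counts absent from coordinates: "
            + ", ".join(map(str, sorted(extra)))
        )
    order = np.array([pos[s] for s in coord_ids], dtype=int)
    return SpatialSample(
        sample_id=sample_id,
        counts=counts[:, order],
        coords=coords_df[["x", "y"]].to_numpy(dtype=float),
        gene_ids=gene_ids,
        spot_ids=coord_ids,
    )


def write_sample(sample: SpatialSample, counts_path: str, coords_path: str,
                 fmt: str = "tsv") -> None:
    """Write a sample's counts and coordinates back to disk.

    ``fmt`` is "tsv"/"csv" for a dense table or "mtx" for MatrixMarket
    (with genes.tsv / spots.tsv beside the .mtx file).
    """
    if fmt == "mtx":
        mmwrite(counts_path, coo_matrix(sample.counts))
        base = os.path.dirname(counts_path)
        pd.Series(sample.gene_ids).to_csv(
            os.path.join(base, "genes.tsv"), index=False, header=False)
        pd.Series(sample.spot_ids).to_csv(
            os.path.join(base, "spots.tsv"), index=False, header=False)
    else:
        sep = "\t" if fmt == "tsv" else ","
        pd.DataFrame(sample.counts, index=sample.gene_ids,
                     columns=sample.spot_ids).to_csv(counts_path, sep=sep)
    pd.DataFrame({
        "spot_id": sample.spot_ids,
        "x": sample.coords[:, 0],
        "y": sample.coords[:, 1],
    }).to_csv(coords_path, sep="\t", index=False)


def compute_size_factors(sample: SpatialSample) -> np.ndarray:
    """Per-spot size factors: library size divided by the mean library size.

    The returned vector has mean exactly one, which keeps the factor
    scale exp(F) interpretable.  Spots with zero total counts are
    rejected rather than silently dropped.
    """
    libs = sample.counts.sum(axis=0).astype(float)
    if np.any(libs == 0):
        empty = [str(s) for s, tot in zip(sample.spot_ids, libs) if tot == 0]
        raise ValueError(
            "spots with zero total counts (remove empty spots before "
            "computing size factors): " + ", ".join(empty)
        )
    return libs / libs.mean()


def poisson_deviance_per_gene(sample: SpatialSample) -> np.ndarray:
    """Poisson deviance of each gene against the constant-rate null.

    The null fits a single rate per gene with a size-factor offset,
    mu_hat[g, i] = r_hat[g] * sz[i] with r_hat[g] = sum_i Y[g, i] / sum_i sz[i],
    and the deviance is 2 * sum_i [ y*ln(y/mu) - (y - mu) ] with the
    convention 0*ln(0/mu) = 0.  High deviance flags genes whose spatial
    expression is far from depth-only variation.
    """
    Y = sample.counts.astype(float)
    sz = sample.size_factors
    r_hat = Y.sum(axis=1) / sz.sum()
    mu = np.outer(r_hat, sz)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(Y > 0, Y * np.log(np.where(Y > 0, Y, 1.0) / np.where(mu > 0, mu, 1.0)), 0.0)
    dev = 2.0 * (term - (Y - mu)).sum(axis=1)
    # clip tiny negative round-off; the statistic is nonnegative
    return np.maximum(dev, 0.0)


def select_genes(samples: list[SpatialSample], n: int) -> GeneSelection:
    """Rank genes by the maximum Poisson deviance across samples and keep the top n.

    All samples must share the same gene universe in the same order.
    Ties are broken by ascending original gene index, so the ranking is
    deterministic.
    """
    if not samples:
        raise ValueError("no samples given")
    ref = samples[0].gene_ids
    for s in samples[1:]:
        if len(s.gene_ids) != len(ref) or not np.array_equal(s.gene_ids, ref):
            raise ValueError("samples have mismatched gene universes")
    n_genes = len(ref)
    if n > n_genes:
        raise ValueError(f"requested {n} genes but only {n_genes} available")
    dev = np.column_stack([poisson_deviance_per_gene(s) for s in samples])
    criterion = dev.max(axis=1)
    # stable sort on ascending index, then descending criterion
    order = np.lexsort((np.arange(n_genes), -criterion))
    return GeneSelection(
        gene_indices=order[:n],
        deviances=dev,
        criterion=criterion,
        n_requested=n,
    )


class DevianceGeneSelector:
    """Scikit-learn-style selector keeping the ``n_genes`` highest-deviance genes.

    Fit on a list of :class:`SpatialSample`; ``transform`` subsets each
    sample to the selected genes.  Fitted attributes: ``selection_``
    (the :class:`GeneSelection`) and ``gene_indices_``.
    """

    def __init__(self, n_genes: int = 500):
        self.n_genes = n_genes

    def get_params(self, deep: bool = True) -> dict:
        return {"n_genes": self.n_genes}

    def set_params(self, **params) -> "DevianceGeneSelector":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, samples: list[SpatialSample], y=None) -> "DevianceGeneSelector":
        self.selection_ = select_genes(samples, self.n_genes)
        self.gene_indices_ = self.selection_.gene_indices
        return self

    def transform(self, samples: list[SpatialSample]) -> list[SpatialSample]:
        if not hasattr(self, "gene_indices_"):
            raise RuntimeError("selector is not fitted")
        return [s.subset_genes(self.gene_indices_) for s in samples]

    def fit_transform(self, samples: list[SpatialSample], y=None) -> list[SpatialSample]:
        return self.fit(samples).transform(samples)
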