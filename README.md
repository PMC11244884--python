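# spafac — multi-sample non-negative spatial factorization

`spafac` extracts shared low-dimensional structure from spatially
resolved transcriptomics (SRT) experiments with **multiple tissue
sections**, without aligning the sections to a common coordinate
system.  Each sample's genes x spots count matrix is decomposed as

    Y_m ~ NB( sz_m * W exp(F_m)', phi_m ),      m = 1..M

with one **shared, non-negative gene-loading matrix W** (genes x L) and
**sample-specific spatial factors F_m** (spots x L), each factor
carrying a Gaussian-process prior over the section's own coordinates
(exponential kernel, linear mean).  Sharing W makes factors comparable
across sections — the same gene program, wherever it sits in each
tissue — while the per-sample GPs let every section organize that
program in its own geometry.  Fitting is variational (collapsed
inducing-point bound, Monte-Carlo over the variational posterior,
analytic gradients, Adam) with a distributed per-sample update scheme
and optional data chunking for memory-bounded runs.

Intended users: computational biologists analyzing multi-section
Visium / Slide-seq-style data who need cross-sample factors when
spatial alignment is impossible (different donors, disjoint anatomy) or
undesirable.

## Worked example

```python
from spafac import MultiSampleSpatialFactorization, match_factors, morans_i
from spafac.simulate import SimulationSpec, simulate_dataset

# two 15x15-grid samples, 4 binary spatial factors; sample 2's patterns
# are sample 1's rotated 90 degrees, so naive alignment would fail
samples, truth = simulate_dataset(SimulationSpec(n_genes=200, seed=1))

est = MultiSampleSpatialFactorization(
    n_factors=4, max_iterations=500, convergence_tol=0.0, seed=1)
est.fit(samples)

assignment, corrs = match_factors(est.factors_, truth.true_factors)
print("matched correlations:", corrs.round(3))
print("Moran's I, factor 1:",
      round(morans_i(est.factors_[0][:, 0], samples[0].coords), 3),
      round(morans_i(est.factors_[1][:, 0], samples[1].coords), 3))
```

Output:

```
matched correlations: [0.908 0.875 0.878 0.888]
Moran's I, factor 1: 0.769 0.766
```

Each of the four simulated factors is recovered by one estimated factor
with Pearson r ~ 0.88-0.91 across the concatenated spots of both
samples, and the recovered factors are strongly spatially organized in
*both* sections (Moran's I ~ 0.77) even though the true patterns are
rotated between them — the point of modeling the samples' spatial
processes separately under shared loadings.

Fitted attributes follow scikit-learn conventions: `loadings_`
(genes x L, non-negative, columns sum to one), `factors_` (per-sample
spots x L posterior means), `elbo_trace_`.  The same machinery is
available as plain functions (`spafac.fit`, `spafac.select_genes`,
`spafac.morans_i`, ...).

## Command line

```bash
spafac simulate --scenario rotated --seed 1 --out data/
spafac select-genes --data data/ --n-genes 500 --out filtered/
spafac fit --samples filtered/ --factors 4 --out model/
spafac evaluate --model model/ --data filtered/ --truth data/ --out eval/
```

Counts are dense TSV/CSV (genes x spots) or MatrixMarket MTX with
`genes.tsv`/`spots.tsv`; coordinates are TSV with `spot_id, x, y`.
Every command writes a `manifest.txt` (version, seed, options) beside
its outputs.

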