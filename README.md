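# spatcorr

Detection of **spatially clustered, drug-responsive cell sub-populations**
in high-content single-cell imaging data.

## The problem

High-content imaging of treated cell monolayers (for example pulmonary
artery endothelial cells, PAEC, responding to IGF-1) yields a table with
one row per segmented cell: condition metadata, the cell's centroid within
its field of view (FOV), and hundreds of morphology/intensity/texture
features. Population-level readouts can hide the interesting biology:
when only a *sub-population* of cells responds to a treatment, and those
responders sit next to each other — daughter cells, or cells sharing a
paracrine microenvironment — the signature is *spatial*: neighboring cells
are more phenotypically similar than random cell pairs.

`spatcorr` implements the statistic that detects this, for anyone analyzing
CellProfiler-style per-cell exports: image analysts, quantitative cell
biologists, and method developers who need a tested reference
implementation with a synthetic ground-truth generator.

## The method

For each cell type, with cells indexed by condition (treatment × time):

1. **Robust normalization.** Using all cells of that type at time 0 as
   reference, each feature *f* is transformed as
   x → (x − median_f) / (1.4826 · MAD_f).
   Features with MAD_f = 0 are dropped (1.4826·MAD is a consistent
   estimator of σ for Gaussian data).
2. **PCA embedding.** One PCA on the pooled normalized data; keep the
   smallest k components whose cumulative explained variance reaches 99%.
   All correlations below are between cells' k-dimensional score vectors.
3. **Resampling null.** Per condition, draw 2000 random pairs of distinct
   cells (positions ignored) and record the Pearson correlation r of each
   pair. The 95th percentile q95 of these draws is the classification
   threshold: the similarity level that random, non-spatial pairing
   already achieves 5% of the time.
4. **Neighbor scoring.** For every cell, find its 20 nearest neighbors by
   Euclidean centroid distance *within the same FOV* (FOVs are imaged as a
   non-overlapping grid, so cross-FOV adjacency is undefined) and compute
   the **median** Pearson correlation between the cell and its neighbors.
5. **Classification.** A cell is *spatially correlated* iff its median
   neighbor correlation > q95. Per condition, the percentage of
   spatially correlated cells is the headline summary.

A median of 20 correlations rarely exceeds a single-pair 95th percentile,
so under the null the flagged fraction is far *below* 5% — the classifier
is conservative by construction.

Because the procedure targets unreleased primary-cell imaging data, the
package ships a first-class synthetic generator: a multi-FOV experiment
with a baseline population (iid Gaussian features, uniform positions) and
a responder sub-population placed by a Thomas-like cluster process
(uniform cluster centers, Gaussian dispersion σ) with a mean shift of
`effect_size` baseline-SDs on a subset of features — plus ground-truth
labels, so sensitivity and specificity of the flag are measurable.

Non-spatial readouts (area-normalized marginal distributions,
Kruskal–Wallis rank tests, percent-change summaries) and presentation
surfaces (two-color spatial maps, percent-correlated bar charts, each with
a CSV twin) round out the pipeline.

## Worked example

`examples/03_spatial_scoring.py` generates a two-condition experiment
(vehicle at t=0 without responders; IGF-1 at t=1440 min with 20% planted,
clustered responders), normalizes, embeds, and scores it:

```
('normal', 'IGF-1', 1440.0): null q95 = 0.2064, 399 of 2400 cells correlated (16.6%)
  vs ground truth: sensitivity 0.875, specificity 1.000
('normal', 'vehicle', 0.0): null q95 = 0.1799, 0 of 2400 cells correlated (0.0%)
```

Reading: in the treated condition, random cell pairs exceed r = 0.206 only
5% of the time, yet 16.6% of cells have a *median* correlation with their
20 nearest neighbors above that bar — a spatially clustered responsive
sub-population (87.5% of true planted responders are recovered, with no
false positives). The vehicle condition, which satisfies the null, flags
0%.

The other examples cover simulation (`01`), normalization + embedding
(`02`), population readouts (`04`) and the one-config pipeline (`05`).
The full pipeline is also scriptable from a shell:

```bash
spatcorr run --config config.yaml      # simulate/ingest -> score -> report
spatcorr simulate|null|score|summarize|report --help
```

Every run directory contains all intermediate tables, figures with CSV
twins, a `manifest.json` (config hash, versions, seeds, all filter counts)
and a log; identical config + seed reproduces every output bit-for-bit.

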