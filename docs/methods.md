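# Methods

This note documents the statistical model behind `spatcorr`, the choices
made where the design was genuinely open, and what the synthetic-data
generator does and does not emulate.

## Model and procedure

The data model is a per-cell feature table: cells `i = 1..n` with
condition metadata (cell type, treatment, time point, replicate), a
field-of-view (FOV) id, FOV-local centroid coordinates `(x_i, y_i)` in
pixels (image convention: origin top-left, y downward), and a feature
vector `f_i ∈ R^p` (p ≈ 390 for a CellProfiler export). FOVs are tiles of
a non-overlapping grid; no global slide coordinates exist, and none are
constructed.

The question the statistic answers: *are neighboring cells more
phenotypically similar than randomly paired cells of the same condition?*
A positive answer indicates a spatially organized responsive
sub-population rather than a homogeneous population response.

Steps, per cell type:

1. **Reference and normalization.** The reference population is every
   cell of that type at time point 0, pooling whatever treatments are
   present at t = 0 (treatment cannot yet have acted). Per feature,
   location = median, scale = 1.4826 · MAD, with MAD the median of
   absolute deviations from the median (midpoint convention for even n;
   no small-sample correction). Features with MAD = 0 are removed —
   they are constant in the reference and the transform is undefined; an
   explicit name-based exclusion list handles features known to be
   uninformative for other reasons. Each cell type gets its own
   reference because baseline morphology differs between cell types.
2. **Embedding.** One PCA (full SVD) on the pooled normalized cells of
   the cell type. The retained dimensionality k is the smallest
   cumulative explained-variance ratio ≥ the threshold (default 0.99),
   with 1e-12 slack so exact subspaces round correctly. Component signs
   are fixed (largest-magnitude loading positive) to make refits
   bit-identical. Downstream correlations use the k-dimensional score
   vectors by default; a raw-feature mode (`correlation_space:
   features`) is available and used, e.g., for null calibration where the
   score dimension must be controlled exactly.
3. **Null distribution.** Per condition, 2000 draws of two distinct
   cells, uniform with replacement across draws, pooled over the whole
   condition (the non-overlapping grid gives no reason to stratify pairs
   by FOV). Each draw records the Pearson correlation of the two score
   vectors. The threshold `q95` is the 95th percentile of the draws,
   computed by linear interpolation between order statistics
   (nearest-rank available via config; with 2000 draws the difference is
   ~1e-3). The median of the draws is recorded as a location summary of
   the null but plays no role in classification.
4. **Neighbor scoring.** Neighbors are the k_nn = 20 nearest other cells
   by Euclidean centroid distance within the same FOV, distance ties
   broken by ascending cell id so results are permutation-stable. A
   cell's score is the median Pearson correlation with its neighbors.
   Cells whose score vector is constant, and neighbors with constant
   vectors, are excluded with logged counts; a cell with fewer than 5
   usable neighbors (configurable) is left unscored and excluded from
   summaries.
5. **Classification and summary.** Flag ⇔ median neighbor correlation
   strictly greater than `q95`; equality counts as uncorrelated. The
   per-condition summary is 100 · flagged / scored. No multiple-testing
   correction is applied across conditions.

### Conservatism under the null

Under the null, a single pair correlation exceeds `q95` with probability
0.05, but the flag requires the *median of ~20* correlations to exceed it.
For d-dimensional iid score vectors, pair correlations are approximately
N(0, 1/(d−1)); the median of 20 such draws (weakly dependent through the
shared center cell) has SD ≈ 0.3/√(d−1), so exceeding 1.645/√(d−1) is a
≈5σ event. The expected flagged fraction under the null is therefore
essentially 0, not 5% — by design the flag marks clear spatial structure,
not borderline noise.

## Synthetic generator

The generator emulates the statistical structure the analysis assumes,
not the imaging physics. One condition = `n_fovs` square FOVs. Baseline
cells: positions uniform in the FOV, features iid N(0, σ_b²) per
dimension. Responders (per-cell Bernoulli with probability
`responder_fraction`): assigned to one of `n_clusters_per_fov` uniformly
placed cluster centers and displaced by an isotropic Gaussian with SD
`cluster_sigma`, truncated to the FOV by rejection (a Thomas-like cluster
process — the simplest process producing clustered point patterns; the
real mechanism, lineage vs. paracrine signaling, is not modeled and the
statistic is agnostic to it). Responders additionally receive
+`effect_size`·σ_b on the *first* `n_shifted_features` features —
deterministic by index for reproducibility. An optional hard-core minimum
spacing is available (default 0). Cell areas are lognormal
(median 500 px², shape 0.35) so synthetic tables exercise the same ingest
path as real exports.

Defaults are the emulated study conditions: 100 FOVs (a 10×10 slide
grid), 1000 px FOV side, 500 cells/FOV (typical endothelial confluence),
390 features, responder fraction 0.2, 3 clusters per FOV, cluster σ = 50
px (5% of the FOV side), 2-SD shift on 30 features, baseline σ_b = 1.

What the generator does **not** emulate — and hence what passing tests do
not demonstrate about real data: correlated features (real morphology
features are strongly collinear; PCA would compress far more than it does
on iid noise), heavy-tailed or skewed feature distributions, segmentation
errors and debris, cell-density gradients, FOV-to-FOV illumination batch
effects, and partial responder penetrance. The recovery numbers
(sensitivity ≈ 0.86, specificity ≈ 1.0 at the default geometry) are
therefore a verification of the *procedure*, not a claim about power on
any particular real dataset.

## Benchmark experiments and problem sizes

`spatcorr.experiments` fixes two canned experiments, also used by
`scripts/acceptance.py`:

- **Null calibration**: 20 FOVs × 300 cells, 119 iid features, raw-feature
  correlation space, no responders. Expected: `q95 ≈ 1.645/√118 ≈ 0.151`
  and flagged fraction ≈ 0. The 119-dimensional score space matches the
  dimensionality regime the procedure typically operates in after PCA.
- **Recovery**: vehicle condition at t = 0 (no responders) supplies the
  normalization reference; a treated condition (20 FOVs × 500 cells,
  300 features, 30 shifted by 2 SD, σ = 50 px, 20% responders) is scored
  end-to-end in PCA space. Reported: sensitivity, specificity, percent
  correlated in both conditions. The vehicle-reference design matters:
  normalizing a responder-containing table against itself inflates the
  reference MAD of shifted features and shrinks the planted effect.

These sizes (6,000–10,000 cells per experiment) are large enough for
stable percentages yet run in seconds, which keeps the full test suite
fast; monotonicity scans (flagged fraction increasing in effect size,
decreasing in cluster σ) use 10 FOVs per point.

## Numerical choices and degenerate inputs

- Pearson correlations are computed as dot products of row-centered,
  unit-norm vectors; results are clipped to [−1, 1] against floating
  round-off. Constant vectors raise (scalar API) or are excluded with
  logged counts (batch paths).
- Null pair draws resample the second index on collisions, so pair
  members are always distinct; identical seed ⇒ identical draws.
- All stochastic steps derive 31-bit sub-seeds from one master seed via
  `numpy.random.SeedSequence` spawn keys (keyed by condition and FOV
  index), so any slice of the pipeline is independently replayable.
- Floats are written to CSV with 17 significant digits and read back with
  the round-trip parser: write → read reproduces tables bit-exactly.
- Ingest rejects rows with missing/non-numeric features (counted in the
  manifest) rather than imputing: downstream math assumes complete
  vectors, and segmentation-stage filtering is where incomplete cells
  should be handled.
- Empty groups are omitted from summaries with a warning; a FOV with
  fewer than 2 cells is skipped in neighbor search.

## Known limitations

- Neighborhoods are FOV-local; structure spanning tile boundaries is
  invisible to the statistic.
- The null pools the whole condition; if FOVs differ systematically
  (batch effects), the null is wider than any single FOV's and the flag
  becomes conservative in a data-dependent way.
- The threshold is a fixed percentile, not a multiplicity-corrected
  decision rule; per-condition percentages are descriptive.
- `k_sample_rank_test` relies on the chi-square approximation to the
  Kruskal–Wallis H; for very small groups an exact permutation p-value
  is preferable (the test suite cross-checks H against exhaustive
  permutation at n = 8).
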