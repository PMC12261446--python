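# Methods

## The problem

Spot-based spatial assays (transcriptomic or chromatin-accessibility) return,
per spot, the summed profile of the handful of cells the spot covers.
Deconvolution methods estimate each spot's cell-type proportion vector from
that mixture plus a dissociated single-cell reference. Benchmarking such
methods needs spatial datasets whose per-spot composition is known exactly.
`spotbench` constructs two kinds of ground-truth datasets and provides the
metric stack to score predictions against them.

## Silver standard: simulated spots from a dissociated reference

Spots are laid on a near-square regular grid over the unit square
(`ceil(sqrt(n))` columns, row-major fill, last row possibly partial; spots at
cell centers). Each spot draws:

* a distinct-type count `k ~ NB(mu_k, theta)`, clamped to
  `[1, n_types]`;
* a cell count `n ~ NB(mu_n, theta)`, clamped below at `max(1, k)`.

The Poisson-Gamma parameterization is mean/shape: `NB(mu, theta)` has
variance `mu + mu^2/theta`; the shape defaults to `theta = 20`. `k` types
are chosen uniformly without replacement; the `n` cells are split among them
by a uniform multinomial with every chosen type guaranteed at least one
cell; within a type, cells are drawn uniformly without replacement (with
replacement only when the demand exceeds the type's pool, so small
references stay usable). Spot counts are the exact elementwise sums of the
member cells' counts in each modality, and the true proportion row is the
member-type frequency vector (cell-count weighted, not transcript-weighted).

**Clamp bias.** Clamping rather than rejection keeps the draws analytically
tractable: `E[max(1, X)] = mu + P(X = 0)` with
`P(X = 0) = (theta/(theta+mu))^theta`, e.g. 5.0115 for `mu = 5, theta = 20`.
The lower clamp of the cell count at `k` exists because a spot holding `k`
distinct types necessarily holds at least `k` cells; it keeps the realized
distinct-type count equal to the drawn heterogeneity value. Its cost is a
further upward offset of the cell count, `E[max(K, N)] - E[N] =
E[(K - N)^+]`: with means 3 (types, clamped to 12 available) and 5 (cells)
the exact per-spot expectations are 3.0610 distinct types and 5.4573 cells;
with means 10 and 15 they are 9.2079 and 15.3756. The test suite checks the
simulator against these pmf-summation closed forms rather than against the
raw configured means. Rejection-based alternatives were considered and
rejected: re-drawing the pair until `n >= k` biases *both* summaries
(conditioning removes high-`k` and low-`n` mass jointly), and truncating `k`
to `n` biases the distinct-type count downward by ~13% under the sparse
configuration.

**Zonation.** `uniform` labels every spot 0. `stripes` cuts the unit square
into `n_regions` equal-width vertical bands, label = band of the spot's x.
`circles` places `n_regions - 1` disc centers equally spaced on the square's
diagonal (positions `i/n_regions`, radius `1/(2 n_regions)`); discs get
labels `1..n_regions-1` (ties to the lowest index), everything else is
background 0. Per-region mean lists map to zone labels in order. The
geometry is a fixed, documented choice; only the stripe/circle motif itself
is externally prescribed.

**Randomness.** Four named RNG substreams (type-count draws, cell-count
draws, type choice, cell choice), spawned from one seed via
`numpy.random.SeedSequence`, make the simulation a pure function of
(reference, config, seed) and keep per-spot draws stable when only the spot
count changes.

## Gold standard: pseudo spots from spatially tagged cells

Cells with per-cell coordinates are binned into half-open grid squares
`[x0, x0+s) x [y0, y0+s)` (boundary points belong to the right/upper
square). Each square with at least `min_cells` cells (default 1) becomes a
pseudo spot: counts are exact sums, the coordinate is the square centroid,
proportions come from member labels; underfilled squares are dropped and
logged. Shrinking the square side drives every spot to single-cell purity.
Square size and the minimum-cell filter are exposed as configuration since
real targeted datasets differ in density.

## Synthetic multiome reference

The generator emulates a dissociated 10x-multiome-style reference: cells are
assigned to `n_cell_types` types (balanced by default; an explicit
proportion vector is accepted), each type owns a non-overlapping block of
`markers_per_type` marker genes and marker peaks whose means are
`marker_fold_change` times the baseline, per-cell library sizes are
log-normal with unit mean (`sigma = library_size_sigma`), RNA counts are
negative binomial (`theta = rna_overdispersion`, default 20), and ATAC
counts are Poisson by default — accessibility fragment counts are commonly
well-described by a Poisson — with an optional NB mode. Spatially tagged
variants place cells uniformly in the unit square or clustered around
type-specific centers (isotropic Gaussian, configurable dispersion and
centers). A reference-expansion utility grows a base reference by factors
(e.g. 2, 4, 8, 16) with nested cell sets, sampling extra cells from a pool
without replacement, for studying reference-size sensitivity.

What the generator does *not* model: fragment-level ATAC structure (Tn5
insertion, fragment lengths), batch effects, doublets, ambient
contamination, or realistic correlation structure between genes and peaks.
Tests passing on this generator therefore validate bookkeeping, sampling
distributions and estimator mechanics — not performance claims on real
tissue.

## Feature selection

* **Highly accessible peaks** — ranked by total fragment count over all
  reference cells ("fraction of cells nonzero" available as an alternative
  criterion). Default n = 20000.
* **Highly variable peaks across clusters** — cells depth-normalized to the
  median total, `log1p`, per-cell-type mean per peak; score = variance
  (ddof 1) of the per-type means across types. Clusters are the predefined
  cell-type labels. The referenced external tooling does not publish its
  exact statistic, so this formula is a fixed, documented stand-in.
* **Highly variable genes, "seurat" flavor** — total-count normalization to
  the median depth, `log1p`; then per-gene mean and dispersion
  (variance/mean) on the expm1 scale, log dispersion z-scored within 20 bins
  of log1p mean. This reproduces Scanpy's `highly_variable_genes(flavor=
  "seurat")` statistic (verified to float32 precision in the tests); the
  only deviation is the cut: exactly `n` features are returned with ties
  broken by ascending feature index, where Scanpy's threshold rule can
  return more on ties. Default n = 4000.

Ties everywhere break by ascending feature index so selections are
reproducible on degenerate inputs. Selections fit on the reference are
applied unchanged to the spatial dataset; applying a selection re-orders
columns into rank order.

## Metrics

* **RMSE** — per-spot root mean squared error over types, averaged over
  spots (default); a globally pooled variant is exposed since the pooling
  convention is genuinely ambiguous.
* **JSD** — per-spot Jensen-Shannon divergence with base-2 logs (range
  [0, 1]), averaged over spots; rows renormalized defensively, `0 log 0 = 0`.
* **NMI** — arithmetic-mean normalization of mutual information between
  majority-type labelings; identical labelings score 1, a zero-entropy
  labeling that is not identical to the other scores 0.
* **Rare-type F1** — presence = proportion >= threshold (default 0.05,
  configurable; no canonical value exists), F1 of predicted vs true
  presence; 0 when no true or predicted positives.
* **Paired strategy test** — two-sided Wilcoxon signed-rank on paired
  per-dataset metric values, exact null for n <= 25 without ties, requiring
  n >= 5 pairs.

Majority ties break lexicographically by type label.

## Baselines

The majority baseline predicts one type per spot with probability 1. The
per-spot-oracle reading (each spot's true majority) is the default; because
the phrase "majority cell type in each spot" is ambiguous, a
global-reference-majority mode (the reference's most abundant type
everywhere) is also provided. The NNLS deconvolver normalizes each cell to
unit total, averages per type into a signature matrix, solves nonnegative
least squares per spot and renormalizes to the simplex (all-zero solutions
fall back to uniform and are logged; rank-deficient signatures trigger a
warning). It recovers exact convex mixtures to 1e-6 and exists as a
pipeline-completing reference point, not as a competitive method; external
methods plug in through the proportions-TSV adapter.

## Numerical and interface choices

* Proportion rows must sum to 1 within 1e-9; counts are validated
  nonnegative integers; modalities always share the row axis.
* Matrix Market files use the standard 1-based coordinate format on disk,
  0-based indexing internally; TSVs are tab-separated UTF-8 with '.'
  decimal; all file writes go through a temp-file-plus-rename so partial
  runs never leave corrupt outputs.
* The HDF5 container is one `.h5ad` per modality (AnnData dialect) with
  shared `obs`.
* Benchmark runs log seed, config hash and package version; reports carry
  per-cell rows plus mean ± sd aggregates recomputable from the rows.

## Problem sizes

Test and acceptance runs use 1000-spot simulations on synthetic references
of 400–3000 cells, with 20000 genes / 30000 peaks only where selection
cardinalities are exercised; these sizes give Monte-Carlo standard errors
small enough for 3-sigma checks against the closed-form expectations while
keeping the whole suite fast on a single core.

## Known limitations

* True proportions are cell-count fractions; transcript- or
  fragment-weighted ground truth would differ for types with unequal
  library sizes.
* The silver simulator draws cells independently per spot; it does not model
  spatial autocorrelation of composition beyond zone-level means, spot-size
  variation, lateral diffusion, or modality-specific capture efficiency.
* Distinct-type and cell-count summaries carry the documented clamp biases;
  configurations with type means near the number of available types are
  additionally truncated by the upper clamp (e.g. mean 10 with 12 types).
* The gold-standard aggregator supports square grids only.
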