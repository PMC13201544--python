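# Methods

## Scope and data model

`spotfuse` operates on a `SlideBundle`: an RGB histology raster, per-spot
full-resolution pixel coordinates, a non-negative count matrix on a gene
panel, and a ligand–receptor (LR) database of `(ligand subunits, receptor
subunits, pathway)` triples (multi-subunit complexes serialized with `_`).
Coordinates are 0-based `(x = column, y = row)`; all pixel windows are
half-open. The panel is restricted to LR genes (plus any user genes)
detected in at least `min_spots = 10` spots; optional preprocessing scales
each spot to a pre-log total of 10,000 and applies `ln(x + 1)`. By default
the model consumes raw counts — normalization is exposed as a flag and its
effect on the statistics stage is discussed below.

## Geometry

Each probed spot owns a `patch_px` (default 112) square patch centered on
its coordinate, split into a `grid × grid` (default 8, so l = 64 tiles of
14 px ≈ 7 µm ≈ one cell) row-major tile grid. Patches that would leave the
image are excluded with a warning; geometric tiling is an exact partition
of the patch. Gap ("between-spot") centers are generated from the lattice:
midpoints of edges to nearest neighbors on hexagonal layouts, edge
midpoints plus cell corners on square layouts, deduplicated on a half-pitch
snap grid and clipped to the convex hull of probed spots. On large interior
hexagonal regions this yields m/n ≈ 4 total-to-probed centers (3.6 on a
30×30 lattice including border effects). Nucleus tiles are 14 px windows
centered on externally supplied nuclei coordinates (this package consumes
centers; it does not segment), each assigned to its nearest probed spot,
ties to the lower index.

## Feature extraction

Tile embeddings come from a pluggable extractor. Profiles for the Virchow2
(C = 1280, 14 px tiles) and ViT256-16 (C = 384, 16 px tiles) foundation
models declare their contracts so pipelines and caches can be laid out, but
the models themselves are optional plugins. The built-in `StubExtractor`
is a deterministic featurizer: per-channel means and variances, low-order
spatial moments of the mean-centered gray image (brightness-shift
invariant by construction), and a seeded fixed random projection of the
mean-centered flattened tile. It is pure, Lipschitz in pixel values, and
carries enough color/texture signal that tiles from distinct synthetic
cell-type textures are linearly separable (> 90% held-out accuracy), which
is the signal floor the contrastive model needs. Extractor fine-tuning is
deliberately out of scope.

## The contrastive fusion model

Four two-layer perceptrons (hidden width 2h, tanh; h defaults to 128,
tests use 32) implement the image encoder/decoder `g1, f1` and expression
encoder/decoder `g2, f2`; `f2` ends in softplus so predicted expression is
non-negative. The architecture is this package's choice — the smallest
family that passes the rank-recovery and retrieval properties. Inputs are
divided column-wise by their training RMS (stored as fitted attributes) so
the tanh layers operate in their active range; cosine objectives are
unaffected by the per-row geometry this preserves and predictions are
rescaled back to count scale.

The objective is `w1·L_image + w2·L_expr + w3·L_InfoNCE + w4·L_cross`
(all weights 1):

- `L_image`, `L_expr`: mean row-wise plus mean column-wise cosine
  dissimilarity between a matrix and its reconstruction. A zero-norm row
  or column has cosine defined as 0 and contributes 1. (A mean-squared
  alternative for the expression autoencoder is available as
  `expr_loss="mse"`; the cosine form is the default.)
- `L_InfoNCE`: on L2-normalized spot projections — image side the
  normalized sum of a spot's tile latents, expression side the normalized
  spot latent — with temperature τ = 0.03 and the positive pair *excluded*
  from the denominator. This follows the defining equation of the model
  family exactly even though it deviates from the common form (the value
  can be negative); `standard_infonce=True` restores the usual
  denominator.
- `L_cross`: decode every tile latent with `f2`, sum each spot's l tiles,
  and compare to the measured spot profile with the same cosine loss. This
  weak supervision is what ties image tiles to expression.

Training samples K/2 spots per step (K = 64 for Visium, 640 for VisiumHD;
clipped with a warning when fewer training spots exist), forming K/2
positive pairs and all cross pairs as negatives. Optimization is Adam
(lr 1e-3) on a compact numpy reverse-mode autodiff core written for this
package (`_autodiff.py`); analytic gradients of every loss are verified
against central differences to 1e-4 relative in the test suite. Spots are
split 80/20 train/held-out by a seeded shuffle; the checkpoint with the
best held-out `L_cross` is kept. Everything is deterministic given the
seed.

Inference applies `f2(g1(·))` to any tile embedding — geometric,
between-spot or nucleus tiles alike.

## Imputation

The final tile expression blends the image-based prediction with
inverse-distance-weighted (IDW) smoothing of the κ nearest measured spots:
`α·prediction + (1−α)·Σ w_s Y_s`, with `w_s ∝ 1/d_s` normalized to 1 and a
zero-distance neighbor taking all weight. Defaults α = 0.5, κ = 6 (Visium)
or 4 (VisiumHD); α = 0.02 is exposed for users who want the smoothing arm
nearly off. Predictions and neighbor expression must be on the same scale
(raw counts by default); mixing scales is a hard error because the blend
would silently favor one arm. Distances are computed in full-resolution
pixels; ties at the κ-th neighbor break toward the lower spot index. The
output is a per-gene convex combination of the prediction and neighbor
values, hence bounded by them, and translation-equivariant.

## Bivariate Moran statistics

Spatial weights are a Gaussian kernel `exp(−d²/2ℓ²)` truncated to each
location's `cutoff` (default 6) nearest neighbors, symmetrized by
elementwise maximum, zero diagonal; `ℓ = auto` is 1.2× the median
nearest-neighbor distance. The kernel choice is isolated behind
`SpatialWeights` so alternatives are drop-in. Note the resulting global R
is not confined to [−1, 1] (that bound belongs to row-standardized
weights); inference is unaffected because the null moments use the same W.

For ligand field L and receptor field R (multi-subunit complexes averaged
arithmetically; min-aggregation would be a one-line change),

- global: `R = Σ w_ks (L_k−L̄)(R_s−R̄) / (‖L−L̄‖‖R−R̄‖)`, with z-score
  from analytic moments of the null in which both fields are independently
  permuted: E[R] = 0 and an exact closed-form variance derived from
  permutation second moments (the implementation carries the derivation;
  a permutation oracle backs it in tests, agreeing within Monte-Carlo
  error). One-sided upper-tail normal p.
- local: `R_k = R_k^sender + R_k^receiver` with
  `R_k^sender = (L_k−L̄)/(σ_L σ_R) Σ_s w_ks (R_s−R̄)` and the receiver term
  symmetric. Standard deviations are population (÷M), which makes
  `Σ_k R_k = 2 M R_global` exact for symmetric weights — an identity the
  suite checks to 1e-8. Per-location variances include the sender–receiver
  covariance `r_k²/(M−1)²` under the same permutation null.

Pairs with a zero-variance field are reported with p = 1 and logged.
Selection applies Benjamini–Hochberg step-up across all tested pairs
(`selected = q < 0.05`); locations with local p < 0.05 are "interacting",
and pairs interacting in fewer than `min_interacting = 3` locations are
flagged out of pattern analysis without being deleted. Local significance
is per-location and uncorrected by design; the FDR control applies to pair
selection.

## Pattern clustering

Eligible pairs enter as rows of either the binary locally-significant
matrix or the continuous `1 − p_local` matrix. The model is a mixture of
Gaussian-process pattern surfaces: `μ_c ~ N(0, K)` with squared-exponential
kernel `K(d) = exp(−d²/2ℓ²) + noise_floor·I` (noise_floor 1e-5), and
`x_g | c ~ N(μ_c, σ²I)`. Fitting is MAP expectation-maximization:
responsibilities (E), then exact coordinate updates of μ (posterior mean in
the kernel eigenbasis), mixing weights and σ² (M), so the penalized
marginal log-likelihood is non-decreasing — asserted every iteration.
Initialization is seeded k-means on the rows; label ties break toward the
lower pattern index; `n_patterns` is user-set (2–3 in typical analyses),
with no automatic model selection.

For large M the kernel is approximated block-diagonally over spatially
contiguous blocks of ≈ `group_size` (default 16) locations found by seeded
k-means on the coordinates; cross-block covariance is zero, so one EM
iteration costs O(M·group_size²) instead of O(M³). A single block recovers
the dense model exactly (log-likelihood difference < 1e-8 in tests), and
on a separable two-blob fixture with M = 400 the block-sparse labels match
the dense labels with ARI ≥ 0.9. The dense path is guarded at M ≤ 5,000.
The `low_rank_dim` parameter (the published usage exposes d = 30) caps the
per-block kernel spectrum; it is carried as a passthrough and disabled by
default. Kernel eigendecompositions are computed once per fit.

Pattern identities are arbitrary; comparisons always match labels by best
bipartite assignment first. One honest caveat: on pure-noise input the
mixture still assigns pairs confidently (M-dimensional likelihoods are
sharp even when component means barely differ); what the null guarantees
is that extra components buy almost no likelihood and the fitted surfaces
carry no spatial structure — that is what the tests assert.

## Downstream interpretation

Pathway enrichment is a one-sided (upper-tail) Fisher's exact test on the
2×2 membership table of a pattern's pairs against a pathway, with the
universe defaulting to all *tested* pairs (conditioning on the panel; a
flag switches to the full database). p-values match the exact
binomial-coefficient tail to 1e-12 over an exhaustive sweep of margins up
to 50; no multiplicity correction is applied by default (BH by flag).
Network extraction chains a pattern's deduplicated receptors through a
receptor→TF edge table (scores carried, optionally thresholded) and the
resulting TFs through a TF→target table, in that order; a receptor with no
TF edge still contributes its L→R layer. Cell-type co-localization applies
the global Moran statistic to pairs of abundance vectors; per-pattern cell
abundance weights each location by the pattern's (clipped, normalized)
mean surface and renormalizes type mass to 1 per pattern.

## Evaluation metrics

Fine-resolution predictions are summed into their parent spots
(between-spot tiles, parent −1, are excluded with a logged count); per-gene
agreement is Pearson correlation over locations and SSIM on rasterized
fields. Rasterization snaps locations to a regular grid at the median
coordinate pitch, averaging collisions and filling empty cells with the
field mean; each gene's two images are min-max scaled independently and
compared with `data_range = 1` and a uniform 7×7 window (shrunk to the
largest odd size that fits). Genes with zero variance, or constant images,
are reported as missing (NaN) — never as zero or one.

## Synthetic study conditions

The generator (`make_slide`) emulates one slide end-to-end and is the test
bed for every stage; all outputs are deterministic functions of
`(config, seed)`. Defaults: a 20×20 square lattice at 112 px pitch
(1 px = 0.5 synthetic µm), 6 cells per spot placed uniformly, 3 cell types
drawn from smooth random bump fields (types cluster spatially), 60 genes —
15 LR pairs (two receptors as two-subunit complexes), 18 type markers
(3× boost in their type), 10 flat housekeeping genes — per-cell rates of
median 2.0 counts/gene (≈ 700 panel UMIs per spot, a realistic Visium-like
panel depth), and Poisson spot counts whose pre-noise values equal the sum
of member-cell rates exactly, so true tile expression sums back to spot
values (the conservation law the aggregation tests rely on). Five planted
pairs receive a 4× rate boost to both sides inside disk hotspots of radius
2.5 pitches at distinct locations; the remaining pairs are spatially flat.
The image renders each cell as a Gaussian blob in its type's hue plus
pixel noise, so stub features genuinely carry type signal.

`make_null_slide` removes hotspots and spatially shuffles types;
`calibration_config` gives 200-spot, 500-pair null conditions for p-value
calibration. What the fixtures do *not* emulate: realistic H&E texture,
segmentation errors in nuclei centers, platform-specific artifacts, or
gene-gene correlation beyond type structure — so green tests demonstrate
correctness of the machinery and recoverability of planted signal, not
performance on real tissue.

One known behavior worth naming: after total-count normalization on a
type-structured slide, flat "null" LR genes acquire weak positive spatial
cross-correlation (both anti-correlate with the marker-rich regions through
the shared library size). This compositional effect exists in real data
too; it keeps the null selection rate on structured slides slightly above
the calibration level measured on unstructured nulls (where p-values are
calibrated to the nominal 5%).

## Numerical choices

- Zero-norm cosine convention: cosine 0, loss contribution 1, no gradient
  through the degenerate branch (guarded `sqrt`/`maximum`).
- InfoNCE uses a detached row-max shift for a stable log-sum-exp.
- IDW with an exactly-zero distance gives that neighbor weight 1.
- k-NN ties resolve by (distance rounded to 1e-9, index).
- EM stops at Δ objective < 1e-5 or 200 iterations; σ² floored at 1e-8;
  kernel eigenvalues floored at 1e-12.
- The dense-covariance guard (M ≤ 5,000) errors with a pointer to the
  block-sparse variant rather than attempting the O(M³) fit.
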