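# spotfuse

Histology-fused super-resolution spatial transcriptomics and
ligand–receptor interaction discovery.

Sequencing-based spatial transcriptomics (10x Visium and VisiumHD) measures
one transcriptome per 55 µm spot or 8–16 µm bin — too coarse and too sparse
to resolve which *cells* express a ligand and which neighboring cells
express its receptor. The matching H&E histology image, however, is
available at sub-micron resolution from the same section. `spotfuse`
exploits that: it aligns tile-level histology embeddings with spot-level
expression in a shared latent space, predicts expression for every
cell-sized tile (including the unmeasured gaps between spots and tiles
centered on segmented nuclei), and then scores ligand–receptor (LR) pairs
for spatial co-expression on the super-resolved data, clusters the
significant pairs into spatial communication patterns, and interprets the
patterns through pathway enrichment and ligand→receptor→TF→target-gene
networks.

## The model

Each spot's 112×112 px image patch is split into an 8×8 grid of 14×14 px
tiles (≈ 7 µm, one cell) and embedded by a pluggable extractor
f₀ : tile → ℝ^C (profiles for the Virchow2 and ViT256-16 foundation models
declare C = 1280 and 384; a deterministic stub extractor ships for
weight-free use). Four maps are trained jointly on the n probed spots —
an image autoencoder g₁: ℝ^C→ℝ^h, f₁: ℝ^h→ℝ^C, and an expression
autoencoder g₂: ℝ^p̂→ℝ^h, f₂: ℝ^h→ℝ^p̂₊ on the p̂ LR genes — with

    Loss = w₁·cosim(𝒳, f₁(g₁(𝒳)))        image reconstruction
         + w₂·cosim(Y, f₂(g₂(Y)))         expression reconstruction
         + w₃·InfoNCE(h^Image, h^Expr; τ) contrastive alignment
         + w₄·cosim(Y, Σᵢⱼ f₂(g₁(𝒳ᵏⁱʲ)))  trans-modality translation

where cosim is the mean row-wise plus column-wise cosine dissimilarity,
h^Image_k is the L2-normalized sum of spot k's tile latents and
h^Expr_k = g₂(Y_k)/‖·‖ (defaults K = 64 pairs per batch, τ = 0.03,
w₁..w₄ = 1). The final expression of any tile at location x is the blend

    Y(x) = α · f₂(g₁(f₀(tile at x))) + (1−α) · Σ_{s∈κNN(x)} w_s Y_s ,

with inverse-distance weights w_s over the κ nearest measured spots
(α = 0.5, κ = 6 for Visium / 4 for VisiumHD).

Spatial LR co-expression is scored with the bivariate global Moran
statistic R = Σₖₛ w_ks (L_k−L̄)(R_s−R̄) / (‖L−L̄‖·‖R−R̄‖) on Gaussian-kernel
nearest-neighbor weights, with analytic z-scores under the
double-permutation null, Benjamini–Hochberg FDR across pairs, and a
per-location sender/receiver decomposition whose significant locations
feed a Gaussian-process mixture (full covariance for small M, block-sparse
for large M) that groups pairs into communication patterns.

## Worked example

Everything below runs on a synthetic slide with known sub-spot truth
(hex/square lattice, type-clustered cells rendered into an RGB image,
planted LR co-expression hotspots, Poisson counts):

```python
import numpy as np, spotfuse
from spotfuse.pipeline import within_spot_training_inputs, run_discover
from spotfuse.imputation import ImputationConfig, impute_tiles
from spotfuse.metrics import pcc_per_gene

slide = spotfuse.make_slide(spotfuse.SlideConfig(n_rows=12, n_cols=12), seed=7)
feats, Y, tiles, kept = within_spot_training_inputs(slide.bundle, seed=7)
model = spotfuse.ContrastiveImputation(hidden_dim=32, K=64, epochs=60, seed=1).fit(feats, Y)
pred = model.predict(feats)
imputed = impute_tiles(pred, tiles.tile_center_xy, slide.bundle.spot_coords,
                       slide.bundle.counts.astype(float),
                       ImputationConfig(kappa=6, alpha=0.5))
print(np.nanmean(pcc_per_gene(slide.truth.tile_expression(tiles), imputed)))

b = spotfuse.preprocess_counts(slide.bundle, normalize=True)
res = run_discover(b.counts, b.spot_coords, b.gene_names, slide.lr_db)
print(res.pairs[res.pairs.selected].to_string(index=False))
```

Output (abridged):

```
slide: 144 spots, 60 genes, 864 cells, image (1456, 1456, 3)
best held-out cross-modal loss: 0.150
mean per-gene PCC vs sub-spot truth: 0.583
7 of 15 LR pairs selected at FDR 0.05:
ligand  receptor pathway  R_global        z            q  n_interacting
   LG0       RC0     WNT  1.231060 9.394842 1.432591e-20             19
   LG1       RC1     BMP  1.247434 9.519808 6.506253e-21             25
   LG2       RC2   MHC-I  1.192924 9.103807 1.635364e-19             19
   LG3       RC3    CXCL  1.124956 8.585109 1.361260e-17             21
   LG4       RC4     WNT  1.270273 9.694098 2.395862e-21             24
   LG6 RC6A_RC6B   MHC-I  0.284349 2.170009 3.214948e-02              4
  LG13      RC13     BMP  0.419130 3.198598 1.726223e-03              4
```

All five planted pairs (LG0–LG4, z ≈ 9) are recovered decisively; the mean
per-gene Pearson correlation of 0.58 against the cell-level truth more than
quintuples the 0.11 achieved by neighborhood smoothing alone, which is the
image arm adding genuine sub-spot information. The two weakly-selected
non-planted pairs on this small slide illustrate the compositional
correlation that total-count normalization induces on a type-structured
section (see `docs/methods.md`). Note R is not confined to [−1, 1] under
unnormalized kernel weights; the z-score and FDR are calibrated regardless.

The same pipeline is available from the shell:

```bash
spotfuse simulate --seed 3 --out sim/
spotfuse train    --bundle sim/ --seed 3 --out model/
spotfuse impute   --bundle sim/ --model model/model.pkl --tiles geometric --out imputed/
spotfuse discover --imputed imputed/ --lrdb sim/lr_db.csv --out discovered/
spotfuse patterns --discover-dir discovered/ --k 3 --group-size 16 --out patterns/
spotfuse enrich   --discover-dir discovered/ --labels patterns/labels.tsv --out enrich/
```

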