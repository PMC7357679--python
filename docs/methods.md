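# Methods

`seadapt` implements a two-step semi-supervised domain adaptation pipeline
for patch-based multispectral habitat classification, together with the
synthetic benchmark, the radiometric calibration chain and the evaluation
tooling needed to exercise it without satellite data. This note records the
model, the defaults, and the design choices that were genuinely open.

## Problem setting

A scene is an H×W×B reflectance raster (B = 8 for WorldView-2-style
imagery); habitat labels (seagrass, sea, sand, land, intertidal) are sparse
expert annotations. A classifier predicts the class of the **center pixel**
of a 5×5×B patch. A model trained at one site (the *source domain*)
degrades at another site (the *target domain*) because the class-conditional
spectral distributions shift between sites. The pipeline adapts a trained
source model to a target site using all unlabeled target patches plus *n*
labeled target samples per class (*n*-shot).

## Networks

* **Embedding G** — two valid (unpadded), stride-1 convolutions: 20 filters
  of 2×2×B, then 100 filters of 4×4×20, both rectified, then a flatten. With
  P = 5 the spatial extent collapses to 1×1, so the embedding dimension is
  E = 100. A full-scale 5×5×8 patch flattens to 200 raw dimensions.
* **Classifier C** — one dense rectified layer of 84 units, then an
  N_c-unit softmax.
* **Discriminator D** — one dense rectified layer of 100 units, then a
  logistic unit giving P(embedding is from the source domain). The
  discriminator architecture is this package's choice; only its role (a
  binary cross-entropy domain classifier on embeddings) is fixed by the
  method.

Parameters are initialized uniformly at ±1/√fan-in from a seeded generator.
Inputs are standardized per band with mean/sd estimated from the source
training patches and applied identically to both domains (raw band scales
differ by orders of magnitude; the constant is carried with the embedding
and can be disabled). Networks are implemented directly in numpy with
explicit reverse-mode gradients — at these sizes (≈10⁴ parameters) there is
no benefit to a deep-learning framework, and the closed-form gradients are
unit-testable.

## Losses

* Classification: mean negative log-probability of the true class
  (logs floored at ε = 1e-12, so values are always finite).
* Adversarial: standard binary cross-entropy for D with source labeled 1
  and target labeled 0; the generator term is −E[log D(G_t(x_t))].
* Pair distance d(u,v) = ½‖u−v‖ — the *unsquared* Euclidean form. A
  `squared_distance` switch (default off) provides the squared variant used
  elsewhere in the contrastive-loss literature for comparison.
* Pair similarity k(u,v) = ½·max(0, m−‖u−v‖)², zero beyond the margin m.
* Semantic alignment L_SA: sum of d over all same-class cross-domain pairs;
  class separation L_CS: sum of k over all different-class cross-domain
  pairs. The optimizer path uses per-batch **means** of these terms (batch-
  size invariance); the raw-sum form is kept for oracle tests.
* Full objective: L_C(G_t∘C_t) + L_C(G_s∘C_s) + L_SA + L_CS, unit weights
  by default (configurable).

## Training procedure

1. **Source training** — mini-batch Adam on the classification loss;
   defaults: 50 epochs, batch 128, lr 2e-4.
2. **Adversarial marginal alignment** — G_t starts as a copy of G_s, which
   is frozen. Per batch: one D step (BCE), one G_t step (generator loss);
   300 epochs by default. The adversarial stage uses Adam with β₁ = 0.5
   (the standard setting for minimax training); with the usual β₁ = 0.9 the
   game does not settle at the D-loss = 2·ln 2 equilibrium and the target
   embedding degrades. Classification stages keep β₁ = 0.9.
3. **Pairing** — each of the n·N_c target shots is paired positively with a
   drawn pool of 400 source samples of its class and negatively with the
   pools of all other classes (5 classes, 1-shot ⇒ 2 000 positives, 8 000
   negatives). Pools are drawn without replacement when possible, with
   replacement (and a warning) otherwise.
4. **Joint contrastive alignment** — 240 epochs over shuffled pair batches
   of 128. Per batch the target shots' classification loss (through C_t,
   initialized from C_s), the drawn source samples' classification loss
   (through C_s), and the SA/CS terms are backpropagated, with gradients
   flowing into **both** G_s and G_t. `joint=False` freezes the source side
   (the "without joint optimization" ablation); a separate flag freezes only
   C_s.

Baselines runnable from the same config: source-only, adversarial-only
(adapted G_t with the source classifier), fine-tuning on the shots, and
contrastive-only (skip stage 2).

All randomness flows from `TrainConfig.seed` through per-stage generators,
so every procedure is bit-reproducible at a fixed thread count.

## Synthetic benchmark

The generator emulates the structure of cross-site multispectral habitat
data, not its physics:

* **Spectra** — five class mean spectra over eight bands whose magnitudes
  follow the empirical ordering land > intertidal > sand > seagrass > sea,
  with a smooth seeded per-class spectral shape. Pixel spectra are class
  mean + diagonal Gaussian noise (sd 0.02 by default; real per-class
  covariances are not modeled).
* **Geometry** — labels come from a smoothed Gaussian random field
  partitioned at its quantiles: contiguous, roughly equal-area regions at a
  controllable blob scale (default σ = 12 on an 80×80 scene). Only region
  *interiors* are labeled (boundary bands of half a patch width are left
  unlabeled, `label_margin=2`), emulating expert annotation of homogeneous
  regions; pixels everywhere still carry their true class spectra.
* **Shift** — the target site applies a per-band affine warp
  (gain ⊙ x + offset, the *marginal* shift) and a per-class mean
  perturbation (the *class-conditional* shift).

`benchmark_suite` fixes three regimes with constant shift vectors (the seed
varies only the realization): `none` (identity), `mild` (gain only), and
`strong` — a severe affine warp plus a "confusion chain" that pulls each
target class mean 35% of the way toward the next class's source mean. The
strong regime is calibrated to its defining property: a source-only model
breaks (accuracy well under 0.8) while the task remains learnable within
each domain (3-fold CV ≈ 1) and recoverable by the two-step method. Because
the within-domain task is nearly noiseless, passing it shows the adaptation
machinery works; it says nothing about sensor noise, mixed pixels, tides or
sun glint in real imagery.

Benchmark runs use a schedule reduced proportionally to the problem size
(10/30/24 epochs), up to 500 labeled training samples per class, 2 500
unlabeled patches per domain, and at most 100 pair batches per epoch; three
replicates per scenario resample shots, pools and initializations. These
problem sizes are the package's defaults for the synthetic study and keep a
full grid under a few minutes on one core.

## Atmospheric correction

The calibration chain matches image radiometry to in situ radiometry at S
stations: K(λ) = −(1/z)·ln(L(0.65)/L(0.21)) with z = 0.44 m; Beer's-law
propagation of L(0.21) to the surface with the same K; Lw(0+) = t·Lu(0−)
with a scalar air–water transmittance factor t = 0.543 (= 0.98/1.34², the
conventional value; configurable, since the interface treatment is a
modeling choice); Rrs = Lw(0+)/Es(0+); response-weighted trapezoidal band
averaging; then per-band OLS of in situ on image values giving gain, offset
and r². Negative K is physically odd but numerically defined and is returned
with a warning rather than an error.

## Evaluation

Cross-validation is stratified (class imbalance in labeled regions makes
unstratified small-k folds risky); when stratification is impossible —
e.g. leave-one-out — it falls back to plain shuffled folds with a warning.
Accuracy is overall (micro) accuracy over labeled pixels, excluding the
shots used for adaptation. Scene maps classify every pixel with a full,
nodata-free window; the border band of ⌊P/2⌋ pixels and nodata-adjacent
pixels stay 0. t-SNE export (via scikit-learn) produces 2-D coordinates for
both raw flattened patches and embedded representations, tagged by class,
domain and stage, up to 400 samples per class per domain.

## Numerical notes and limitations

* Ties in the class posterior break to the lowest class index.
* The unsquared pair distance has a constant-magnitude gradient, so the
  contrastive stage never reaches a stationary point exactly; late-epoch
  accuracy wobbles by a fraction of a percent. The squared variant anneals
  but is not the printed form, so it stays opt-in.
* SA/CS gradients at coincident pairs (‖u−v‖ = 0) are set to zero
  (subgradient choice).
* Patch windows touching nodata are dropped rather than imputed; centers
  without a full window are skipped, so maps are interior-only.
* The adversarial stage aligns marginals only; with symmetric class
  structure it can settle on a label-permuted alignment — the few-shot
  stage is what resolves the assignment. This mirrors the method's design
  and is why adversarial-only results vary widely across replicates.
* Model checkpoints are a single `.npz` of named parameter arrays plus a
  JSON header (shapes, normalization constants, metadata).
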