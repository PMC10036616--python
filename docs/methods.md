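# Methods

`tmenet` implements a weakly supervised, multilevel analysis of multiplexed
immunofluorescence tissue cores: from 7-channel core images and a binary
patient outcome (tumor recurrence), it learns — without any region or cell
annotation — a hierarchy of tissue-microenvironment elements (local
phenotypes → cellular neighborhoods → tissue areas), quantifies each
patient as an enrichment vector over those elements, and classifies
recurrence from that vector.  This note records the model, its
assumptions, the defaults and why, and what the synthetic experiments do
and do not establish.

## Image preprocessing

Each channel of each core is background-corrected with the classic
rolling-ball estimator: the background is the grayscale opening of the
image with a non-flat ball structuring element whose diameter equals the
configured window (default 50 px, i.e. ball radius 25 px — the window is
read as the size of the largest object that is *not* background).  The
estimate is subtracted and the result clipped at zero.  For radii above
12 px the opening is computed on a block-minimum downsampled copy
(factor 4) and re-enlarged bilinearly; this is the standard large-radius
approximation and agrees with the exact estimator to well under 1% of the
dynamic range on tissue-like images.  All channels are corrected,
DAPI included.  The ball variant (not the paraboloid) is used and recorded
in configuration.

Because marker intensities after spectral unmixing are in arbitrary units
and staining batches differ mainly by per-channel gain, every channel is
then scaled to unit mean **within a staining group** (institution by
default).  This cancels gain-only batch effects exactly while preserving
between-patient contrast inside a group, and it is what makes the
downstream pipeline scale-tolerant.

## Patch embedding

Cores are tiled into non-overlapping `20 × 20 × C` patches in row-major
order; incomplete border strips are discarded (a 2656-px core therefore
yields exactly 132 × 132 = 17 424 patches).  Two embedding routes share the
`L × d` PatchSet contract:

* **Handcrafted (default at desk scale).**  Per channel: mean and standard
  deviation; per channel pair: Pearson correlation of pixels (0 for a
  constant channel); per channel: mean squared finite-difference gradient.
  For C = 7 that is 42 informative features, zero-padded to the configured
  width `d`.  These capture marker expression, colocalization, and coarse
  texture/morphology deterministically, which keeps the synthetic
  experiments free of encoder-training variance.
* **Contrastive encoder.**  A small strided convolutional network trained
  with a normalized-temperature cross-entropy (NT-Xent) objective over two
  augmented views per patch (flips, 90° rotations, per-channel intensity
  jitter; temperature 0.1, batch 80 crops).  Depth/width/epochs are
  configuration; the default depth is deliberately small because the
  encoder's job here is an embedding contract, not ImageNet-scale
  representation learning.  Reported "contrastive accuracy" is the fraction
  of patches whose positive view outranks all in-batch negatives.

Embedding columns are z-scored; the statistics can be fit on training-fold
patients only (fold-safe mode) or frozen and re-applied to new cohorts
(deployed mode, used in the robustness experiment).  By default the
self-supervised stage sees all images, mirroring the protocol the analysis
reproduces; the fold-safe flag exists for stricter variants.

## Patch graphs

Each core's patch grid is wired with 4-adjacency plus one self-loop per
node; the cores of one patient form disconnected components of a single
patient graph.  Edges never bridge cores: two cores are physically
unrelated pieces of tissue, so fabricated adjacency between them would
corrupt neighborhood learning.  An interior node's closed 2-hop
neighborhood contains exactly 13 patches (itself + 12) — this fixes the
receptive field of neighborhood assignment.  Coarsening to the
neighborhood graph uses the quadratic form `Aᴺ = SᵀAS` with the soft
assignment S (DiffPool-style); for one-hot S this reduces to counting
inter-cluster edges.

## Multilevel assignment model

With `E` the `L × d` patch embeddings and `A` the patch adjacency:

* **Local phenotypes.**  An 8-layer perceptron with skip connections maps
  each embedding to P logits; a row softmax yields `S_P ∈ R^{L×P}`
  (row-stochastic).
* **Cellular neighborhoods.**  K rounds (default K = 2) of trainable
  aggregation `H ← φ(H W_self + Ā H W_neigh + b)` on the row-normalized
  adjacency Ā, then an assignment layer and row softmax produce
  `S_N ∈ R^{L×N}`.  A patch's row provably depends only on its ≤ K-hop
  neighbors (perturbation-tested).
* **Tissue areas.**  Neighborhood features `X_N = S_Nᵀ E` (column-sum
  normalized) are aggregated once on the coarsened graph `S_NᵀAS_N`, then
  assigned to areas: `S_A ∈ R^{N×A}`.  The patch-level area assignment is
  the composition `S_N · S_A` — row-stochastic as a product of stochastic
  matrices.  The patient abundance of areas is pooled from this patch-level
  composition so that every patch contributes once at every level.
* **Max-sum pooling.**  For each level, each patch (row) keeps only its
  maximal assignment entry (ties → lowest element index) and the columns
  are summed, yielding the abundance of each element; a patient is the
  concatenation `[𝒫, 𝒩, 𝒜]`.  Hard selection is the default (a patch
  belongs to one element only); the forward pass is hard, the backward pass
  uses the straight-through convention.  A soft (plain column-sum) mode
  exists for ablation.  Hard-max abundances satisfy
  `L/E < Σ abundance ≤ L`, with equality iff every row is one-hot.
* **Classifier.**  The enrichment vector is divided by L (patients
  contribute one or two cores, so L varies) and passed through a one-layer
  perceptron with a two-way softmax: recurrence vs no recurrence;
  prediction confidence is the larger probability.

Training is end-to-end with Adam (learning rate and weight decay are
searched or configured) on the cross-entropy of patient labels only.
Defaults: 100 epochs, 8 patients per mini-batch, dropout 0.1, hidden width
64, P = 10, N = 8, A = 4, K = 2, softmax assignment activation — the
selected optimum of the architecture search.  Seeded runs are bit
reproducible.

### Identifiability under weak supervision, and the hooks

Patient-level labels constrain only the class-discriminative directions of
the assignment space: the boundaries of elements that do not separate the
classes are unidentified, and with a pure cross-entropy objective the
learned phenotypes merge or split arbitrarily (measured patch-level
adjusted Rand index ≈ 0.16 on the planted cohort).  Cross-entropy is still
the default loss; two documented hooks address identifiability when the
goal includes recovering interpretable elements:

* **Assignment regularizers** — a row-confidence term (mean assignment
  entropy, pushing one-hot rows, consistent with the selected hard-max
  pooling) and an element-balance term (negative entropy of mean usage,
  preventing collapse).  Both default to weight 0.
* **Cluster warm start** — the phenotype head is pretrained for a few
  epochs to reproduce a k-means partition (k = P) of the training
  embeddings, then fine-tuned jointly at 0.01× the joint learning rate so
  end-to-end training refines rather than overwrites the partition.

The planted-structure experiments enable `confidence_weight = 0.05` and a
3-epoch warm start; with them the planted phenotypes are recovered at
ARI ≈ 0.87 while classification is unaffected.

A third option, `classifier_polish_steps`, refits the one-layer classifier
head to convergence on the training patients' enrichment vectors after the
joint loop, with the representation frozen.  The head is then a convex
logistic problem, so this is simply finishing its optimization; it matters
in cross-validation, where stopping the joint loop at a fixed epoch leaves
each fold's probabilities at a different calibration and corrupts pooled
out-of-fold metrics even when within-fold ranking is nearly perfect.
Default 0; the recovery experiments use 500 steps.

### Hyperparameter search

Random sampling without replacement from the configured grid (the full
published grid spans learning rate × weight decay × hops × hidden width ×
dropout × P × N × A = 138 240 candidates; the default budget is 400),
raced by successive halving on a stratified validation split: each rung
multiplies the epoch budget by η = 3 and keeps the best 1/η of configs by
validation loss.  The exact halving schedule and split construction are
package choices recorded in the trials table.

## Interpretability conventions

* Element profiles use each element's 100 highest-confidence patches
  (ties by patch index).
* Marker heatmaps: mean of per-patch mean channel intensity over the top
  patches, then each marker column divided by its maximum (column max = 1).
* Colocalization: Spearman correlation between flattened channel pairs per
  patch, averaged over patches; a constant channel contributes 0 (the
  correlation is undefined there); diagonal 1.
* Nucleus morphology: the DAPI channel is segmented classically — Otsu
  threshold, hole filling, distance-transform watershed — and per-nucleus
  area (px²), count per patch, and circularity `4πA/perimeter²` (clipped to
  [0, 1]) are reported.  A trained segmentation network would be
  interchangeable here; the morphology features, not segmentation fidelity,
  are the contract.
* Compositions: argmax (hard) labels are counted — neighborhoods over the
  closed 2-hop patch set (≤ 13 patches per top patch), areas over
  neighborhood assignments — and z-scored per row; a column-max-1 variant
  is exported for display since both conventions appear in practice.
* Differential abundance: two-sided Mann–Whitney–Wilcoxon per element on
  L-normalized abundances, Bonferroni-corrected over all P + N + A
  elements.  Covariate associations: Spearman for ordinal/continuous
  covariates (FIGO stage, age), two-sided t-tests for binary ones, with
  Benjamini–Hochberg FDR across the whole table ("false discovery"
  penalization is read as BH).
* Overlays: per-patch confidences are upsampled to pixel blocks, mapped
  through a dark-to-yellow colormap, and alpha-blended over the grayscale
  composite; output covers the patch-tiled region.

## Evaluation and clinical decision support

Cross-validation is stratified at the **patient** level (both cores travel
together — anything else leaks tissue between folds).  Out-of-fold
predictions are pooled; reported are accuracy with a normal-approximation
95% CI `p ± 1.96√(p(1−p)/n)`, ROC AUC with a stratified-bootstrap
percentile CI (2000 resamples, seeded), and Cohen's κ from the pooled
confusion matrix (κ = 0 with a warning if the marginals are degenerate).
The CI methods are labeled in the report because more than one convention
exists.  Confidence analysis buckets patients at 0.90/0.50 and lists
high-confidence misclassifications.

The decision tree is a CART **regressor** on {0,1} recurrence targets
(variance-reduction splits — equivalent to Gini up to scaling), serialized
as its split sequence.  The clinical workflow feeds it the tissue-area
abundances: in a planted two-area cohort the phenotype-, neighborhood- and
area-level abundances are deterministically collinear, so a tree over all
elements ties between levels and roots arbitrarily among them; areas are
the architecture-level summary a screening step would use, and the root
split is then checked against the planted hot/cold axis.  A full-enrichment
tree is also fitted and reported.

## Synthetic cohorts

The generator emulates a two-institution TMA study: `n` patients (default
prevalence 12.8% recurrence, or balanced for model experiments), one or two
cores each (default two), 7-marker panel, core side default 512 px at desk
scale (the acquisition-scale 2656 px is a configuration value).  Planted
structure per core, on the 20-px patch grid:

* **Areas** as contiguous Voronoi blobs whose seed labels are drawn from
  the patient class's area prior — default "hot" (immune-infiltrated) area
  prior 0.6 for non-recurrent vs 0.1 for recurrent patients, matching the
  cold-tumor phenotype of recurrence.
* **Neighborhoods** as contiguous Voronoi sub-blocks within each area
  (tumor-core vs immune-infiltrate mixtures).
* **Phenotypes** drawn per patch from the neighborhood mixture: tumor
  (CK⁺), CD8 T cell (CD8⁺/PD-1⁺), stroma (DAPI only) — each a marker
  signature, nucleus radius, cell density, and gamma-distributed per-cell
  expression noise (CV 0.25).

Cells are rendered as soft disks over a noisy background; per-core area
fractions concentrate on the class prior (Dirichlet-free, by seed
labeling), and the empirical class mean is within ±0.05 of the prior by
n = 40.  Covariates are simulated with one planted dependence — FIGO stage
weakly tracks the cold-area fraction — so covariate-association code has
real signal; the other covariates are independent noise with realistic
prevalences.  Institution batch effects are per-channel gain/offset plus
additive noise and never touch ground-truth labels.

**What passing synthetic tests shows** — that the implementation recovers
planted multilevel structure, discriminates classes whose difference is
architectural, and is invariant to gain-only batch distortion.  **What it
does not show** — performance on real tissue: no photorealistic
morphology, no spectral bleed-through or autofluorescence, no segmentation
difficulty, and planted effect sizes are honest but favorable.

## Experiment sizes and numerical choices

The recovery experiment uses 40 patients × two 512 × 512 cores
(1250 patches/patient), handcrafted embeddings at d = 64, the planted
element counts (P = 3, N = 2, A = 2, K = 2, hidden 32), and stratified
4-fold cross-validation pooled for the held-out AUC, with a final model
fitted on the full cohort for structure scoring; the robustness experiment
quantifies 19 patients stained "twice" (unit gains vs per-channel gains up
to 2×) with the trained model and its frozen standardizer.  These sizes
keep the full pipeline at desk scale while leaving the acquisition-scale
parameters available in configuration.

Ties in hard-max pooling and top-k selection break to the lowest index;
assignment rows are validated to sum to 1 within 1e-5; constant feature
columns are left unscaled by standardization; Spearman on constant
channels is defined as 0; a blank DAPI patch segments to zero nuclei
rather than erroring; κ with degenerate marginals is defined as 0 with a
warning.

## Known limitations

* The contrastive encoder is deliberately small; its published-scale
  counterpart (a deep residual network trained on millions of patches) is
  out of scope, so learned-embedding quality is not a claim of this
  package.
* Weak supervision alone does not identify non-discriminative element
  boundaries; interpretable recovery relies on the documented warm-start /
  regularizer hooks.
* Gain-only robustness is partly structural (per-institution channel
  normalization cancels gains exactly); offset- or noise-dominated batch
  effects are not cancelled and are only mildly attenuated.
* The synthetic cohort's two-area planted design makes level abundances
  collinear; conclusions about *which* level carries the signal are not
  testable there.
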