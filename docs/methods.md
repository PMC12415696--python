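# Methods

## The classification problem and its data model

The pipeline classifies 512×512 RGB tiles cut from H&E-stained lymph-node
whole-slide images into a neoplastic class (large-cell lymphoma-like,
label 1) and a non-neoplastic contrast class (reactive hyperplasia-like,
label 0). A tile inherits its label from its slide, and every slide
belongs to exactly one patient; that hierarchy is what the data-hygiene
machinery protects. Predictions are tile-level probabilities ŷ ∈ [0, 1];
slide-level interpretation comes from rendering the tile scores back at
their recorded coordinates.

## Synthetic cohorts

Real clinical WSIs are not distributable, so validation runs on a
generative stand-in with controlled ground truth. Tiles are rendered
under the Beer–Lambert model: per pixel, OD = c_H·S_H + c_E·S_E and
I = 255·10^(−OD), with S_H, S_E the unit-normalised canonical H&E stain
vectors (hematoxylin ≈ [0.650, 0.704, 0.286], eosin ≈ [0.072, 0.990,
0.105]). Nuclei are hard ellipses of hematoxylin OD (peak 0.9) on a
uniform eosin background (OD 0.25); overlaps add OD. Nucleus centres
follow a stationary Poisson process (sampled on a margin-expanded canvas)
so the expected per-pixel OD has the closed form
`density · od_peak · π(μ_r² + σ_r²) · E[axis ratio] / 512²`, which the
tests check against rendered images.

Default class morphologies: label 0 — radius 4 ± 0.8 px at 180 nuclei per
tile; label 1 — radius 9 ± 1.2 px at 60 nuclei per tile. These were
chosen so the classes are cleanly separable by nuclear size (the
morphological contrast of the real diagnostic problem) at a scale a
~100K-parameter CNN can learn on a desktop. Per-patient staining
variation emulates real inter-slide inconsistency: both stain vectors are
rotated within their OD plane by a patient angle drawn from N(0, 0.05 rad)
truncated at ±3σ, and concentration (×0.85–1.15) and brightness
(×0.9–1.1) scale factors are drawn per patient. Additive Gaussian pixel
noise (σ = 3 on the 8-bit scale) is applied after rendering. Everything
is keyed off `numpy.random.SeedSequence` spawn keys, so identical
arguments and seed give byte-identical cohorts.

What the generator does **not** emulate: tissue architecture (follicles,
capsule, sinuses), chromatin texture, cytoplasm, focus/compression
artefacts, or label noise. Passing tests therefore demonstrate that the
pipeline's machinery is correct and that the network can learn a real
morphological contrast under stain variation — not that it reaches any
particular accuracy on clinical slides.

## Tiling

Tessellation anchors a `tile_size` grid (default 512) at the top-left of
the ROI bounding box; a cell becomes a tile iff it lies fully inside the
image and at least `min_roi_coverage` (default 0.5) of its pixels are in
the mask. Output is row-major; coordinates are 0-based pixels with
half-open extents `[x, x+512)×[y, y+512)`, the same convention the
overlay and the `{slide_id}_x{X}_y{Y}.png` file names use. How boundary
tiles were handled in the original QuPath workflow is unrecorded; the
coverage rule is this package's choice and is stated here deliberately.

## Stain normalisation

All stain-matrix methods share OD = −log₁₀((I+1)/256) (the +1 avoids
log 0) and a foreground mask that keeps pixels with **all** OD channels
≥ β = 0.15; an image with fewer than 100 foreground pixels raises
"insufficient tissue".

- **Reinhard** matches per-channel CIELAB mean and standard deviation of
  the source to the target. A channel with zero spread is shifted only.
  The CIELAB conversion is an in-package vectorised float32
  implementation (gamma lookup + matrix algebra) verified against
  skimage's reference conversion to 0.03 L*a*b* units and byte-identical
  round trip; it exists because the reference implementation's float64
  path made Reinhard slower than Macenko, inverting the methods' natural
  cost ordering.
- **Macenko** takes the SVD of the foreground OD, projects onto the top-2
  singular plane, and reads the stain vectors at the 1st/99th angle
  percentiles. Concentrations are least-squares solutions clipped at
  zero; normalisation rescales each stain by the ratio of 99th-percentile
  concentrations (target/source) and reconstructs with the target matrix.
- **Ruifrok** uses the fixed canonical stain matrix for source and
  target; only the concentration rescale differs from identity.
- **Vahadane** runs a rank-2 sparse NMF of the foreground OD:
  multiplicative updates of the concentration matrix with an L1 penalty
  (λ = 0.1), one projected-gradient step on the dictionary per iteration
  (step 1/L, L the spectral norm of CCᵀ), columns renormalised with the
  concentrations rescaled to keep S·C invariant; 50 iterations, with a
  `converged` flag and a warning on non-convergence. The dictionary is
  initialised at the extreme-angle directions of the OD cloud perturbed
  by the seed — random initialisation frequently converges to poor local
  minima because the β-masked cloud never touches the stain axes.

Column order is fixed by convention: the column with the larger
first-channel (red) OD is hematoxylin. Profiles serialise to YAML at full
float precision.

Two identifiability facts shape the tests. First, with the canonical
vectors, pure-eosin pixels fall below the any-channel β threshold (eosin's
red OD is 0.072), so *no* estimator can recover the canonical eosin
vector exactly from masked 8-bit data; parameter-recovery checks
therefore use a well-conditioned synthetic stain pair whose pure pixels
survive the mask. Second, the L1 penalty tilts Vahadane's dictionary by
design, so exact self-normalisation holds only as λ → 0; the test
asserts identity within 3/255 at λ = 0.01 and monotone improvement from
λ = 0.1.

## Cohort preparation

Per-case tile counts are capped at the cohort median (lower middle value
for even cohort sizes, since an integer cap is required), subsampling
uniformly without replacement. Patients are split 60:30:10 into
train/validation/test within class strata using largest-remainder
apportionment; when apportionment would leave a set empty despite a class
having ≥ 3 patients, one patient moves from the largest set. Class
balancing removes tiles uniformly from the larger class; it is applied to
the training and validation sets only — the test set keeps its natural
imbalance to mimic deployment. Whether the original workflow balanced
validation as well as training is unrecorded; balancing both is this
package's choice. All three operations are seeded and deterministic, and
the split CSV plus seed reconstructs any run.

## The network and its training

Architecture (128×128×3 input): conv(128, 3×3, same, stride 1) →
maxpool(2) → conv(64, 3×3) → maxpool(2) → global average pooling →
dropout 0.25 → dense(128) → dense(64) → dense(1, sigmoid), ReLU
elsewhere; optional L1/L2 penalties on dense weights. Kernel geometry is
not recorded in the source description; 3×3 stride-1 same-padding is this
package's choice, giving a closed-form 94,017 trainable parameters. The
published feature-extractor count of 20,256 cannot be reproduced from the
described layer widths under standard assumptions and is documented as
irreconcilable rather than silently matched. The dropout rate is 0.25 in
the methods text versus 10% in the figure captions; the text wins and the
rate is configurable.

The transfer-learning variant freezes any feature extractor for
224×224×3 input and trains flatten → dropout → dense(32) → dense(16) →
dense(1, sigmoid): 32·D + 577 trainable parameters for feature dimension
D. Defaults there: learning rate 5e-4 with exponential decay (×0.96 per
1000 steps), early stopping on validation accuracy with patience 3. A
seeded random-projection extractor ships for exercising the head; it is
synthetic plumbing, not a learned backbone.

Training is Adam on binary cross-entropy with seeded initialisation
(He-normal), shuffling and dropout; the gradient is taken at the logits
(fused sigmoid + BCE) for stability. The engine is pure numpy:
convolutions run as im2col GEMMs for shallow inputs and as
one-GEMM-per-kernel-offset with shifted-slice accumulation for deep
inputs (the two paths are tested for equivalence, and the whole stack
against finite differences). Given a fixed BLAS configuration the
training loop is deterministic; history records per-epoch train/val loss
and accuracy, with training metrics accumulated as running means over the
epoch's optimisation batches.

### Problem sizes used by the verification suite

The original setting — batch 512, 100 epochs on ~10⁵ tiles — is
available via `TrainConfig.paper_scale()`. The shipped verification runs
use a desk scale chosen once: 6 patients per class × 20 tiles, Reinhard
normalisation, batch 16, 8 epochs, learning rate 1e-3, three seeds.
Two facts set these numbers. With global average pooling on uncentered
[0, 1] inputs the logit contrast grows roughly like lr × steps, and the
original budget corresponds to lr × steps ≈ 2; the desk scale reproduces
that product (~0.5–1 over 60 steps at 1e-3) rather than the step count.
And the held-out criterion is patient-level AUROC ≥ 0.90 (three-seed
median), which this scale passes with margin (the class contrast is
rank-separable well before the 0.5 threshold calibrates, so accuracy can
lag AUROC at small step counts — visible in the history CSVs). The
capacity check trains dropout-free on an amplified-contrast fixture for
the same reason: it probes that the stack can fit its training set, not
the regulariser's noise floor.

## Evaluation

Confusion counts use the ≥ 0.5 threshold convention (an operating
threshold is otherwise unrecorded); accuracy, precision, sensitivity,
specificity and F1 follow the standard identities, and any metric with a
zero denominator is reported as explicitly undefined rather than as zero
or NaN. AUROC is the Mann–Whitney pair-win probability with ties counted
half. DeLong's test uses the fast structural-components estimator of
var(AUC_A − AUC_B) — midrank-based V10/V01 components, full 2×2
covariance — with a two-sided normal p-value; a degenerate zero-variance
comparison of equal AUCs (a model against itself) returns p = 1.
McNemar's test counts b (A wrong, B right) and c (A right, B wrong) and
uses the exact two-sided binomial on b + c by default, with the
continuity-corrected chi-square available for large discordance.
Cross-model comparisons pair records by tile identity and refuse
unpairable sets, naming the offending tiles. Significance is reported at
α = 0.05.

The independent oracles in the test suite: an O(n²) pair-counting AUROC,
direct binomial tail enumeration for McNemar (all b + c ≤ 20), and a
100,000-replicate label-preserving bootstrap of the AUC difference
(z-statistic with the bootstrap standard error) for DeLong at n = 30,
agreeing within 0.02.

## Overlay

`build_overlay` collects one cell per tile prediction of a slide
(duplicate origins are an error); rendering tints each cell with the
linear blue (0, 0, 255) → red (255, 0, 0) interpolation at ŷ, rounded
half-up, alpha-blended at opacity 0.4 over the base image; pixels outside
cells are untouched. A two-colour map without a midpoint hue was chosen
because only the shade-tracks-probability behaviour is specified by the
source figure. GeoJSON export writes one closed-ring polygon per cell in
pixel coordinates (y increasing downward, the slide-viewer convention,
declared in the document properties) with the score at 6-decimal
precision; the round trip back to an overlay map is lossless at that
precision.

## Workflow

`run_experiment` executes generate → cap → split → balance → normalise →
train → evaluate → overlay. The stain profile is fitted once on the first
training tile (a shared-target choice; the original target selection is
unrecorded) and applied identically to train, validation and test tiles;
the test split is first read at the evaluation stage. Each run writes its
resolved configuration, split, history, predictions, metrics, overlay PNG
and GeoJSON, and a timestamped log; any stage failure aborts with the
stage name. Stain-normalisation throughput can be measured with
`benchmark_throughput` (mean of three timed passes) but is reported for
information only — it is hardware-dependent and only the Reinhard-faster-
than-Macenko ordering is asserted, loosely, in the tests.

## Known limitations

- The synthetic cohort bounds what the tests can claim: correctness of
  the machinery and learnability of a morphology contrast, not clinical
  performance.
- The numpy engine is single-core and ~2 orders of magnitude slower than
  a compiled DL framework; the original full-scale training setting is
  configurable but slow.
- GAN-based normalisers are out of scope (their value is pre-trained
  weights); likewise pyramidal/CZI WSI parsing — slides enter as plain
  RGB arrays with masks.
- Bit-exact agreement with other stain-normalisation implementations is
  not claimed; conventions (log base, +1 offset, percentiles) are stated
  above instead.
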