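# Methods

## Pipeline model

The package treats colitis histology assessment as patch classification
followed by composition analysis. Its assumptions, in order of appearance:

- **Tissue filtering** assumes a patch is informative iff it contains
  enough mucosa/submucosa. A patch is kept iff the Background/Muscle share
  of its area on the block-wise tissue map is ≤ 0.65; the boundary value
  0.65 itself is kept (only *strictly more* unwanted area removes a patch).
  Partially covered map cells are weighted by overlap area. Partial border
  blocks are classified on zero-padded crops and flagged.
- **Two-phase training** assumes that (a) slide-level colitis status is
  cheap and patch-level annotation is expensive, and (b) healthy tissue in
  colitis colons looks like healthy tissue in controls. Under (b), a
  feature cluster that is essentially absent from control mice
  (mean per-mouse proportion < τ = 0.05) and more common in colitis mice
  can be labelled Involved wholesale. Patches from control slides always
  refine to Uninvolved, whatever their cluster. A manual-override map can
  force individual cluster labels (standing in for expert review).
- **Overlay inference** assumes averaging confidences over many overlapping
  windows (offset lattice: step 20 px, 10 steps each way, i.e. the full
  21×21 = 441-position lattice per grid patch) removes the dependence on
  where a tile boundary happened to fall. A pixel is called Involved only
  when its mean confidence is strictly above 0.5 — a 50% tie is a
  conservative Uninvolved.
- **Phenotype prediction** assumes mouse models differ in the *composition*
  of injury, not just its amount, so per-mouse proportion vectors
  (Uninvolved + involved class shares, summing to 1) are sufficient LDA
  features. Shrinkage (Ledoit–Wolf) is applied because compositional
  features over few mice give near-singular pooled covariances. Priors are
  empirical class frequencies. The model LDA and the score-bin LDA are fit
  independently on the same feature table.

## Backbone

All trainable image models are single-hidden-layer perceptrons
(scikit-learn `MLPClassifier`) over area-averaged, downscaled patches
(default 16×16×3 inputs for 224/64/48-px patches, 8×8×3 for 32-px tissue
blocks). The hidden layer (default width 512 for the involvement
classifier) doubles as the patch embedding used for refinement and class
discovery. Training runs epoch-by-epoch with Adam; the epoch with the best
validation weighted F1 is kept. With `epochs=0` the network stays at
(near-)initialization and still emits normalized confidences. Every fit is
a pure function of (data, config, random_state).

This backbone is deliberately small: the pipeline's claims are about the
*training procedure* (label refinement, filtering, averaging), not about
network capacity, and the synthetic textures are learnable by construction
(raw-pixel nearest-centroid accuracy ≥ 90% is asserted in the tests).

## Synthetic swiss rolls

A slide is an Archimedean spiral band on a near-white background; the band
splits radially into mucosa, a submucosa stripe and a muscle stripe.
Normalized spiral arc length t ∈ [0, 1] (0 = centre = proximal) encodes the
proximal–distal axis. Injury is planted as up to three contiguous arcs whose
common half-width is bisected until the involved share of mucosal pixels
hits the profile's target fraction; placement follows the model's pattern
(proximal-sparing: t > 0.5 only; proximal-involving: at least one arc with
centre in t < 0.4; uniform: anywhere). The realized fraction is kept within
±0.1 of the profile mean by construction (the slide-to-slide fraction draw,
sd 0.06, is clipped at ±0.09).

Ten procedural textures (base colour + jittered grid of ring/blob/stipple
elements) stand in for H&E appearance: three uninvolved mucosal classes
(Crypts, LightlyPacked, Rosettes), four involved classes (Inflammatory,
CryptDropout, CryptDilation, DistortedGlands), and Background, Muscle,
Submucosa. Colours are chosen to be pairwise separable — basophilic purple
for inflammatory infiltrate, eosinophilic salmon for crypt dropout, pale
blue-lavender for dilated crypt lumens, pale orange for submucosal
connective tissue — because the pipeline is texture-agnostic and only class
distinctness matters for testing it.

Per-model defaults (configuration, not literature claims): Control has
involved fraction 0; the Klf5-knockout-like model 0.5 with
architecture-distortion-dominated injury; the DSS-like model 0.45 with
inflammation/dropout-dominated, proximal-sparing injury; the combined model
0.6 and uniform placement. Colitis profiles also skew their *healthy* mucosa
toward the LightlyPacked appearance (mix 0.1/0.8/0.1 vs the control's
uniform third/third/third). This models peri-injury mucosa and is what
makes phase 1 fail in an instructive way: the texture most common in
colitis slides' healthy regions is mostly labelled `Colitis` at slide
level, so a slide-label classifier systematically over-calls it — exactly
the failure mode pseudo-label refinement is designed to repair.

Clinical score follows `round(clip(12·f + ε, 0, 12))` with
ε ~ N(0, noise_sd), noise_sd = 1 by default, where f is the slide's
realized involved fraction. This reproduces a moderate involvement–score
correlation with an analytic benchmark R² = Var(12f)/(Var(12f) + noise_sd²)
that the experiments compare their measured R² against.

What the generator does **not** model: nuclei-scale morphology, staining
variation, scanner artefacts, tissue folds and tears, sex/genotype
covariates, or ambiguous transitional histology. Passing tests therefore
demonstrate that the *pipeline machinery* is correct and self-consistent,
not that the classifiers would reach the same accuracy on real slides.

## Problem sizes and numerical choices

Desk-scale defaults, chosen so a full run takes seconds to minutes on one
CPU: 512-px slides (1024 px for tissue-map work, whose muscle/submucosa
stripes must be at least one 32-px block thick), 48-px patches at ≥ 50%
mucosal content, 160 patches per slide, 8-mouse cohorts for the two-phase
experiment and 40-mouse cohorts for phenotype prediction. The two-phase
cohort plants three uninvolved and two involved texture classes so that
k = 5 refinement clusters correspond one-to-one to texture groups; the
phenotype cohort uses all four involved classes.

- Cohort splits are mouse-level (never patch-level, to avoid leakage
  between overlapping patches), stratified by model, with largest-remainder
  rounding of the 0.70/0.10/0.20 fractions; a non-empty test set is
  enforced, and when the validation bucket rounds to empty the experiment
  carves a 10% patch-level validation slice out of the training mice.
- PCA uses the full SVD and retains the *smallest* component count whose
  cumulative explained variance reaches the target (default 0.95), with a
  fixed sign convention (each component's largest-magnitude entry is
  positive) for cross-implementation determinism.
- k-means uses 10 seeded restarts; ties in assignment go to the lowest
  centroid index. Representatives are the n nearest assigned patches per
  centroid, ties in manifest order.
- Confidence accumulation keeps per-pixel sum and count arrays at slide
  resolution (exact means, bounded memory); uncovered pixels are excluded
  from every denominator. Overlays blend tint at α = 0.35 so the underlying
  histology stays visible.
- All randomness flows from integer seeds through `numpy.random`
  SeedSequence spawning; reruns are bit-identical.

## Known limitations

- The 512-wide embedding of a one-hidden-layer MLP is a far weaker
  representation than a deep network's penultimate layer; cluster-based
  refinement works here because the synthetic textures are linearly
  separable, and the enrichment rule's τ = 0.05 has only been exercised in
  that regime.
- The enrichment rule labels whole clusters; a cluster mixing involved and
  uninvolved textures contaminates every patch it contains. Choosing k
  well below the number of distinct textures degrades refined labels.
- Score-bin prediction is intrinsically harder than model prediction: bins
  cut a continuous severity scale, so mice near bin edges are ambiguous
  even under a perfect predictor.
- InvolvedProportion from overlays under-reports the planted mucosal
  involved fraction, because submucosa pixels enter the denominator; the
  oracle-overlay experiment reports ≈ 0.34 for a planted fraction of 0.40.
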