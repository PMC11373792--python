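# Methods

## Scope and data model

`hyperseed` operates on reflectance cubes `(lines × samples × bands)`
from a line-scan benchtop imager: 462 bands spanning roughly
400–1000 nm, frames on the order of 1600×1000, stored as ENVI BIL
(binary payload + text header). Band indices are 1-based everywhere in
the public API, matching instrument numbering. The reader/writer
supports BIL, BIP and BSQ interleaves, preserves unknown header keys
and explicit wavelength lists verbatim, and round-trips cube data
bit-exactly (property-tested for all three interleaves).

### Band→wavelength calibration

The default calibration is a least-squares line through the six
printed color-window endpoints (band, nm): (23, 421.29), (44, 448.94),
(76, 491.19), (127, 558.79), (173, 620.05), (292, 779.75). The fit is
1.33253 nm/band with offset 390.100 nm; all six anchors are reproduced
with residual < 0.6 nm, below one band step. A nominal 0.67 nm
sampling interval sometimes quoted for this class of instrument is
inconsistent with 462 bands over 400–1000 nm (implied step ≈ 1.33 nm)
and with the printed band/wavelength pairs, so it is ignored; the
printed pairs are the operative mapping. Whether the instrument's true
wavelength table is linear or tabulated is unresolved — explicit
per-band lists are supported and take precedence when a header carries
one.

## Synthetic scenes

No seed-image corpus is distributed with the package, so the synthetic
generator is the test bed for every downstream stage. It emulates the
acquisition geometry — bright seeds on a dark stage — not seed
appearance:

* **Geometry.** Non-overlapping ellipses (default semi-axes 8–14 px,
  minimum gap 6 px) placed by rejection sampling with bounded retries;
  an infeasible packing raises a placement error naming the
  constraint. Default frame 160×220, chosen so a handful of scenes
  covers tens of seeds at interactive cost.
* **Spectra.** Per-class reflectance = common baseline (0.30) plus
  Gaussian bumps `A·exp(−(λ−c)²/2w²)`; background 0.04; additive
  Gaussian noise (default sd 0.01 reflectance units) clipped to
  [0, 1]. Default bump width 3 nm (≈ 2 band steps) and amplitude 0.35:
  narrow enough that a bump planted at one band contributes nothing
  measurable to candidate bands ≥ 10 band steps away, which is what
  makes "signal only at the planted triple" a real guarantee rather
  than an approximation.
* **Ground truth.** A per-pixel instance mask plus an instance list
  (class, ellipse parameters, bounding box, area); masks and cubes are
  deterministic functions of a single integer seed, corpus scene *i*
  uses `seed + i`.

With noise sd 0, the in-seed spectrum equals the class signature
exactly (asserted bit-level in the tests).

Two packaged corpora:

* `default_three_class_spec` — classes A/B/C bright at the planted
  red/green/blue bands (default 188-83-41); used by the segmentation
  and end-to-end experiments.
* `band_search_spec` — A/B/C as above plus a baseline-only class D,
  smaller seeds in a 110×150 frame. With three classes and three
  display channels, two informative channels already separate
  everything and the third band is irrelevant — the planted triple
  would tie with decoys. Class D breaks the tie: dropping any planted
  band collapses one (class, D) pair, so the planted triple is the
  unique optimum. This is why the search corpus has four classes.

What the generator does **not** model: seed texture, specular
highlights, shadows, touching seeds, within-class spectral
variability. Passing tests therefore demonstrate correctness of the
pipeline's mechanics (band selection finds planted contrast,
segmentation recovers well-separated convex blobs, the classifier
learns separable color classes), not performance on real imagery.

## RGB reconstruction and band-triple search

A band image is an 8-bit monotone rescale of one spectral slice.
Default scaling is per-band min–max to 0–255 (the source material does
not state a scaling); a constant band maps to 0, and a global fixed
affine scaling is available for cross-scene comparability. Composition
stacks the chosen (R, G, B) bands; window enforcement (red 173–292,
green 76–127, blue 23–44) is on by default with an explicit override,
and provenance (source cube, triple) is recorded on the image.

The search scores every triple on a candidate grid by actually running
the downstream chain: compose each corpus scene, segment it, label
each recovered seed by the ground-truth instance it overlaps most, and
hand the per-seed features to a pluggable evaluator. Two evaluator
tiers exist by design: full network training (faithful but expensive —
one training run per triple) and the default desk-scale proxy,
3-fold cross-validated multinomial logistic regression on per-seed
channel means and standard deviations (6 features). The proxy
preserves the search's structure — triples are compared by the
accuracy of a classifier trained on the reconstruction they induce —
at ~1000× less cost. Ranking is accuracy-descending with (r, g, b)
lexicographic tie-break; an evaluator failure is recorded on that
triple (`accuracy = None` plus the message), never silently dropped;
triples beating a designated baseline triple are flagged. Whether
scoring uses whole scenes or segmented seeds was an open choice;
scoring segmented seeds matches what the classifier will actually see
and is the implemented default.

## Segmentation

Grayscale uses fixed luminance weights (0.299, 0.587, 0.114) with
round-to-nearest. Binarization is Otsu's method as an exhaustive scan
of all 256 levels maximizing between-class variance, ties broken
toward the lower threshold (strict-improvement scan); a constant image
yields all background. Foreground is above-threshold (bright seeds on
a dark stage) with an inversion flag. Hole filling sets background
regions not connected to the border to foreground. "Contour cleanup"
is morphological opening with a disk (default radius 2 px) — the
smallest operation that matches the stated purpose of smoothing
contours and removing specks before component labelling.
Components are 8-connected, filtered by minimum area (default 0.1% of
frame pixels), returned in raster order of bounding-box top-left, and
each carries its solidity so downstream code can flag merged seeds.
Touching seeds are *not* split: the workflow this implements removed
stuck seeds manually, so the package filters (via solidity) rather
than guessing a watershed split. Crops expand the bounding box by a
pad (default 4 px, clamped), black out out-of-mask pixels, and resize
bilinearly to 224×224 (the classifier input); both fill policy and
interpolation were unstated upstream and are configurable.

## Augmentation and splitting

Exactly six transforms per crop, fixed order: rotate 45° (same canvas,
black corners, bilinear), rotate 90°, color enhancement, brightness
enhancement, horizontal mirror, contrast enhancement. Enhancement
factors default to 1.3, fixed rather than jittered, so the expansion
is reproducible; rotate-90 and mirror are exactly lossless (pixel
multiset preserved, tested as group identities). With originals
retained the dataset grows sevenfold — 1088 crops → 7616 rows.
Normalization (per-channel mean/sd of the training split) is applied
at training time and persisted with the checkpoint, not baked into
stored images, so augmented files stay inspectable.

Splitting is stratified per class at 7:2:1 with
`train = ⌊0.7n⌋`, `val = ⌊0.2n + 0.5⌋`, `test = n − train − val` —
the unique simple rounding rule consistent with all seven published
per-variety rows (e.g. 1099 → 769/220/110; totals 5328/1524/764).
Membership is a seeded shuffle. By default the seven variants of one
original move as a block between splits (leakage guard, grouped on the
manifest's `origin` column); because blocks have size 7, grouped
per-class counts are the group-level 7:2:1 counts times 7 and can
deviate from the row-level rule by less than one block. The ungrouped
mode reproduces the row-level counts exactly and mirrors
augment-before-split workflows; neither mode is asserted to be what
any particular lab did.

## Classifiers

All models are built from scratch in `hyperseed.nn` (numpy, float32,
im2col convolution over BLAS matmul, explicit backward passes; every
layer's gradients were verified against central finite differences).

* Plain families: ResNet-18/34 (basic blocks, depths 2-2-2-2 /
  3-4-6-3) and ResNet-50/101 (bottlenecks, 3-4-6-3 / 3-4-23-3), 7×7/2
  stem + 3×3/2 max pool, four stages, global average pool, linear
  head. Parameter counts match the standard reference models exactly
  (e.g. 21,288,263 for ResNet-34 with a 7-class head).
* **SE block**: squeeze = global average pool; excitation = C → C/r →
  C bottleneck (r default 16, hidden width at least 1) with ReLU and
  sigmoid; output channels rescaled by weights in (0, 1).
* **CBAM block**: channel attention (average- and max-pooled
  descriptors through a shared two-layer MLP, summed, sigmoid) then
  spatial attention (channel-wise mean and max maps, k×k convolution,
  k odd, default 7, sigmoid), strictly channel→spatial. Note the
  shared MLP has independent per-channel output units, so identical
  input channels do *not* generally receive identical channel weights;
  the invariant that does hold — channel weights depend on the input
  only through its pooled descriptors — is what the tests pin down.
* **Deformable convolution**: each kernel tap samples at its grid
  position plus a learned fractional (row, col) offset predicted by a
  companion standard convolution; bilinear interpolation, zero beyond
  borders. The offset predictor is zero-initialized, making the
  untrained layer exactly a standard convolution (verified against an
  independent scipy oracle to < 1e-5 on random inputs) and letting
  training start from that equivalence point.

Modified families place attention at stage level: one block after the
stem max pool, one after the Conv2 stage ("after Conv2" is read as
after the stage's final block; the second placement mirrors the stated
stem-pool placement and is flag-selectable via
`ModelConfig.attention_points`). `se_resnet34_dcn` additionally
replaces the first 3×3 convolution of Conv2's first block ("initial
stage of the convolution of Conv2") with the deformable layer. Its
census is therefore exactly 2 SE modules, 1 deformable convolution,
5 convolutional stages (stem + four residual stages) and 1 fully
connected layer. A reduced family `se_resnet_small` (3×3 stem, two
SE-attended basic-block stages, ~16 base channels) exists for
desk-scale experiments on 32 px crops.

No pretrained weights: initialization is seeded He-normal, so whole
runs are bit-reproducible. Softmax lives at inference; training uses
logits with cross-entropy.

## Training and evaluation

The default regimen: SGD with learning rate 0.001, momentum 0.9,
weight decay 0.01 (classical coupled formulation), batch size 8, 50
epochs, constant learning rate (only an "initial" rate is specified
upstream; a schedule hook exists but is off). Data order, weight
initialization and the split all derive from integer seeds. Per-epoch
history records train/validation loss and accuracy; the retained
checkpoint is the best-validation-accuracy epoch (final-epoch
behavior remains visible in the history; which one a given paper
reports is generally unstated, so both are kept). A non-finite loss
raises a divergence error naming the epoch. Checkpoints are single
`.npz` files carrying weights, model config, train config,
normalization constants and class labels.

Evaluation is argmax of softmax (ties to the lowest class index) into
a k×k confusion matrix (rows true, columns predicted). Per class:
`TP = diag`, `FP = column − TP`, `FN = row − TP`,
`TN = total − TP − FP − FN`; precision TP/(TP+FP), recall TP/(TP+FN),
specificity TN/(TN+FP), F1 = 2PR/(P+R). Aggregation is macro
(unweighted over classes) by default — matching per-variety reporting
conventions — with support-weighted available by flag; accuracy and
macro recall are computed independently since they only coincide for
balanced test sets. A 0/0 cell is defined as 0 and the class is
flagged in the report. "Per-class accuracy" in the report is
per-class recall.

## Pipeline

Stages (generate → reconstruct → segment → augment → split → train →
evaluate) communicate only through files and CSV manifests under a
workspace, so each stage is independently runnable and replaceable. A
content hash of (stage name, full pipeline config) marks completed
stages; re-running with unchanged config skips them without changing
results, and any stage failure halts with the stage name while earlier
artifacts remain on disk. The packaged demo configuration is the
three-class corpus, 4 scenes, 32 px crops, the small SE-residual model
and a 10-epoch run of the standard regimen — sized so the full chain
takes well under a minute on one CPU.

## Problem sizes used by the verification scripts

The test suite and `scripts/acceptance.py` use deliberately small
instances: search corpora of 4 scenes at 110×150 px with 12 seeds
each over a 4×4×4 grid (10 seeded repetitions), 20 noise-free
120×160 scenes for segmentation fidelity, 100 random inputs for the
deformable-convolution equivalence, 50 random images for the Otsu
oracle, and the demo pipeline above for the end-to-end bar. These
sizes were chosen so the complete verification runs in minutes while
every check still exercises the full code path at the study's stated
conditions (462 bands, default calibration, 7:2:1 rule, sevenfold
expansion, standard training regimen).

## Known limitations

* Training the full-depth families on 224 px inputs is functional but
  slow in numpy (seconds per image); the full ResNet evaluator for the
  band search exists as an interface tier, not a routine path.
* The synthetic generator's simplifications (see above) mean measured
  accuracies on it say nothing quantitative about real seed imagery.
* Touching-seed splitting is out of scope by design; low-solidity
  components are flagged, not divided.
* Radiometric calibration (dark current, white reference) is not
  modeled; cubes are assumed to already be reflectance.
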