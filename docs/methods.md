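# Methods

## Problem and approach

`histomap` maps tumor heterogeneity on low-magnification (5x, ~2-2.3 μm/px)
H&E whole-slide images. Instead of tiling the slide into fixed patches, it
over-segments the image into SLIC superpixels — contiguous, roughly
equal-area clusters of similar neighboring pixels that adhere to tissue
boundaries — and classifies each superpixel with a compact CNN into
tissue-level categories (tumor, stroma, lymphocyte clusters, necrosis, fat,
empty space, ...). The classified map is then reduced to composition
features: the fraction of tumor-compartment pixels occupied by stroma
(stroma-to-tumor ratio), by lymphocyte clusters, by necrosis, and so on.
Working at 5x makes a whole slide a single ~10^8-pixel raster that one CPU
can segment and classify in minutes, and makes the classification unit — a
~40 px superpixel, roughly 80-120 μm across — directly interpretable by a
pathologist.

## Pipeline stages

### Stain normalization (Reinhard)

Every slide is color-matched to a reference before segmentation. The image
is mapped RGB (scaled to [0, 1]) -> LMS cone space (Ruderman matrix) ->
log10 (an epsilon of 1e-6 guards zero channels) -> the decorrelated lαβ
space; each channel is shifted and scaled so its mean and standard deviation
equal the reference's, then mapped back and clipped to 8-bit RGB. Numerical
choices:

- The inverse matrices are computed by `numpy.linalg.inv` from the published
  forward matrices rather than typed in from their four-decimal published
  roundings, so self-normalization is an identity up to uint8 rounding
  (verified to within 2 intensity levels).
- Statistics use every pixel by default. An optional background exclusion
  (mean luminance above 0.9 of maximum) exists behind a flag but is off: at
  5x the white background carries real information about section layout and
  excluding it is a choice the user should make explicitly.
- A source channel with zero variance cannot be scaled; it is shifted to the
  target mean with a warning.
- The reference is user-supplied (image or stored `ColorStats` JSON); there
  is no canonical built-in reference slide.

### Superpixel sizing and segmentation

The superpixel count for an image of S pixels is N = ceil(S / U) with
U = 1500 px by default, holding mean superpixel area (hence physical size,
~78 μm side at 2.016 μm/px) constant across differently-sized slides. Note
one arithmetic consequence the user should not be surprised by: U = 1500
means mean *area* 1500 px² (side ~39 px), not side 51 px; reported mean
sides around 51 px would correspond to U ≈ 2600.

Segmentation is scikit-image SLIC in CIELAB with connectivity enforcement.
Defaults, chosen on the synthetic reference substrate and exposed in the
API/CLI:

- `compactness = 20`. At compactness 10 the color term dominates enough
  that many seeds wander and the post-hoc connectivity step merges their
  fragments, leaving the achieved count ~25% below target; at 20 the count
  stays within ~12% and boundary adherence is equal or better.
- `smoothing_sigma = 1` px of Gaussian pre-smoothing inside SLIC, which
  suppresses nucleus-scale texture so boundaries follow tissue regions
  rather than single dark spots.
- `min_size_factor = 0.2`, keeping legitimate small superpixels instead of
  merging them into neighbors.

Coordinates are 0-based (row, col); bounding boxes are half-open; a
centroid is the unweighted mean of member pixel centers.

### Patch extraction

Each superpixel becomes one CNN input: the axis-aligned bounding-box crop,
resized bilinearly to 56x56 (default) or 75x75. Pixels of neighboring
superpixels inside the box are kept — the local context is informative and
masking would introduce artificial edges; a masked mode (neighbors replaced
by the superpixel mean color) exists behind a flag for ablation. A crop
already at target size is returned verbatim.

### Isocenter labeling

Annotations mark samples of each region without delineating boundaries
(GeoJSON polygons, x = column / y = row in pixel units, or a full label
mask + legend). A superpixel is labeled iff its centroid — rounded half-up
to a pixel — lies strictly inside regions of exactly one class; centroids
outside all regions, or inside overlapping regions of different classes,
are excluded. This is deliberately conservative: ambiguous superpixels are
dropped from training and testing rather than guessed.

### Augmentation and balancing

Labeled patches are expanded by rotations (90°, −90°, 180°), horizontal and
vertical flips, and per-channel histogram equalization (contrast); the
original is always retained, so the full family yields 7 patches per
superpixel. Class imbalance is evened out by oversampling each minority
class (sampling with replacement, seeded) from its own augmentation pool up
to the largest class's pool size, so post-balancing counts are equal.

### The classifier

A compact CNN: six 3x3 convolutions of widths (32, 32, 64, 64, 128, 128)
with size-preserving zero padding, ReLU everywhere except the softmax
output, dropout 0.2 followed by 2x2 max-pool (stride 2, floor on odd sizes:
56 -> 28 -> 14 -> 7) after every conv pair, flatten (7x7x128 = 6272), a
256-unit ReLU dense layer, and a softmax over the classes. With a 56x56x3
input and 6 classes this is exactly 1,894,438 trainable parameters (~1.9 M).
Size-preserving padding is load-bearing: with valid padding the count drops
to ~0.58 M, so the parameter total pins the architecture.

Training: inputs scaled 0-255 -> 0-1 by the maximum value; Glorot uniform
initialization; Adam at learning rate 1e-3; categorical cross-entropy;
default 50 epochs with batch size 256 (56 px) or 150 (75 px), both
overridable; a stratified 10% validation split (seeded) is carved from the
training patches and the weights of the epoch with the highest validation
accuracy are kept. The weights incident to each hidden unit (each conv
filter, each dense column) are rescaled to max-norm ≤ 3 after every
optimizer step; biases are not constrained and no dropout follows the dense
layer — neither is assumed beyond the stated regularization.

The network, its backpropagation (im2col convolutions, pooling masks), and
Adam are implemented directly in NumPy. Consequences worth knowing: training
is exactly reproducible for a fixed seed on any platform, runs on one CPU,
and is fast enough for desk-scale corpora (tens of seconds per epoch per
~1000 patches at 56 px); it is not intended for datasets of 10^5 patches.
Max-pool gradient is split equally among tied maxima within a window — ties
have measure zero for float activations and the subgradient total is
preserved.

At Adam's published learning rate the optimizer needs a few hundred steps
before even linearly separable data are fit; with small corpora that means
accuracy rises over several epochs rather than within the first one. The
test suite sizes its corpora so 5-10 epochs suffice.

### Mapping and composition

Per-superpixel predictions are projected back to the pixel grid (the class
of a pixel is the class of its superpixel), rendered through an explicit
class -> RGB palette, and tallied. Composition scores divide each class's
pixel count by the total over a configurable set of "tumor compartment"
classes — by default the tumor-associated classes (tumor, stroma,
lymphocyte clusters, plus necrosis/differentiation/hemorrhage where
defined), excluding empty/white space, fat and normal anatomy (epidermis,
muscle, kidney), which is documented rather than prescribed because the
compartment definition is a scientific choice. Ratios use pixel counts; a
superpixel-count variant can be had by tallying `classes` directly. For
cohort studies, per-subject scores are dichotomized at the median
(score ≤ median -> "low"), keeping group sizes within ties of each other;
survival fitting itself (Kaplan-Meier, Cox, rank tests) is out of scope and
the groups are exported for standard statistical packages.

### Evaluation metrics

Confusion-matrix metrics are orientation-explicit because the common names
(precision/recall/specificity) silently depend on whether rows are truth or
prediction: `overall_accuracy` (100·trace/total), `macro_row_ratio` /
`macro_col_ratio` (unweighted mean over classes of diagonal over row/column
total), and per-class `class_row_ratio` / `class_col_ratio`. Percentages
are rounded half-up to one decimal. Three reference cohort tables
(melanoma, triple-negative breast cancer, mouse neuroblastoma) ship as CSV
fixtures; all of their printed summary figures recompute exactly except two
documented printing inconsistencies (see `src/histomap/data/README.md`),
which are excluded from exact checks rather than papered over.

## The synthetic mosaic generator

Real 5x slides cannot ship with the package, so tests run on generated
mosaics that emulate what matters to the pipeline:

- **Layout** — per-class smooth random fields (Gaussian-filtered white
  noise, sigma defaulting to 1/8 of the frame side) with per-class bias
  offsets fitted iteratively so the argmax-class area fractions hit their
  targets within ±0.4 points. This yields compact blobs much larger than a
  superpixel, like tissue regions at 5x.
- **Texture** — per-class base color plus Gaussian jitter; dark elliptical
  nuclei spots for cell-rich classes (dense and small for lymphocyte
  clusters, sparser and larger for tumor); fibrous streaks for stroma; a
  faint membrane lattice for fat. Classes are separable at patch scale but
  not from a single pixel, so the classifier must integrate over the patch.
- **Annotations** — a few square sample regions per class, each strictly
  interior to one ground-truth region (placed by erosion of the class
  mask), emulating non-exhaustive pathologist marking; the exact truth mask
  is also emitted for oracle checks.
- **Corpora** — train/test slide sets from disjoint seed streams
  (`numpy.random.SeedSequence`), bit-reproducible.

The default 6-class recipe (tumor, stroma, epidermis, lymphocyte clusters,
fat, empty space; fractions 0.28/0.18/0.10/0.12/0.14/0.18; 512x512 frames)
is sized so the full chain — generate, normalize, segment (~170 superpixels
per slide at U = 1500), label, augment (~1000 patches), train 10 epochs,
classify held-out slides, quantify — runs in a few minutes on one CPU.

What the mosaics do **not** emulate: real stain variation and scanner
profiles, nucleus-level morphology, gradual tissue transitions, tissue
folds/artifacts, and class boundaries that are genuinely ambiguous at 5x.
Passing the property suite therefore demonstrates that the machinery is
correct and self-consistent (labels follow the truth mask, the classifier
can learn texture classes, composition is recovered within 2 points, SLIC
adheres to region boundaries); it does not certify accuracy on clinical
material, which requires pathologist-annotated slides.

## Design choices in brief

- Eq. `N = ceil(S/U)` is taken as authoritative for sizing; the "51 px mean
  side" figure that circulates for U = 1500 is inconsistent with it and is
  not reproduced.
- Boundary/overlap ties in labeling resolve to "unlabeled", never to a
  guess.
- The conventional "average precision/recall" names are avoided in the API;
  row/column-explicit names make every reported figure reproducible
  regardless of orientation convention.
- Median ties go to "low" (≤ median), the conservative direction for a
  "high-risk" group.
- The CLI is a thin shell over the library: every command is a pure
  function of inputs + options + seed and writes a JSON run manifest
  (options, package version, SHA-256 of file inputs) beside its outputs.

## Known limitations

- The NumPy CNN trains at CPU speed; epoch counts beyond ~50 on corpora
  beyond ~10^4 patches are impractical.
- SLIC parameter defaults were chosen on the synthetic substrate; clinical
  slides with weak region contrast may need a lower compactness and will
  always show some boundary straddling.
- GeoJSON geometries are interpreted in pixel units of the 5x frame; no
  coordinate-system transforms are applied.
- Only plain rasters are consumed; pyramidal WSI containers must be
  exported to 5x PNG/TIFF first.
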