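# histomap

Superpixel-based tissue classification and tumor-composition mapping for
**low-magnification (5x) H&E whole-slide images**, for computational
pathology researchers who need slide-level phenotype quantification —
stroma-to-tumor ratio, lymphocyte-cluster burden, necrosis fraction — at
desk-scale computational cost rather than the cost of 20-40x tile pipelines.

## Method

1. **Stain normalization** (Reinhard): each slide is mapped to the
   decorrelated log color space lαβ (RGB → LMS → log10 → lαβ), every channel
   is shifted/scaled to a reference's per-channel mean and standard
   deviation, and mapped back to RGB.
2. **Superpixel segmentation** (SLIC): the number of superpixels for an
   image of *Sᵢ* pixels is

   &nbsp;&nbsp;&nbsp;&nbsp;*Nᵢ* = ⌈*Sᵢ* / *U*⌉,&nbsp;&nbsp; *U* = 1500 px,

   holding mean superpixel area — about 78 μm per side at 2 μm/px — constant
   across slides. SLIC clusters pixels in CIELAB color + position, yielding
   contiguous, boundary-adhering regions.
3. **Patch classification**: each superpixel's bounding-box crop is resized
   bilinearly to 56×56 (or 75×75) and classified by a compact CNN — six 3×3
   convolutions (32, 32, 64, 64, 128, 128) with size-preserving padding,
   dropout 0.2 + 2×2 max-pool after each conv pair, a 256-unit dense layer
   and a softmax; 1,894,438 trainable parameters (~1.9 M) for 6 classes.
   Training: Adam (lr 10⁻³), categorical cross-entropy, Glorot uniform init,
   max-norm 3 on the weights incident to each hidden unit, best-validation
   checkpointing. Ground truth comes from *isocenter labeling*: a superpixel
   inherits the class of the annotated region containing its centroid, so
   annotations never need boundary delineation. The network is implemented
   in NumPy — no GPU or deep-learning framework required — and is exactly
   reproducible for a fixed seed.
4. **Mapping & quantification**: predictions are rendered back to a
   per-pixel class raster; composition scores divide each class's pixels by
   the total over the "tumor compartment" classes, e.g.

   &nbsp;&nbsp;&nbsp;&nbsp;stroma ratio = stroma px / (tumor + stroma + lymphocyte + … px),

   and per-subject scores are median-split into low/high groups for
   downstream survival statistics.

A seeded synthetic mosaic generator (`histomap.synthetic`) produces
annotated histology-like slides so the whole pipeline is testable without
any data download. See `docs/methods.md` for assumptions, parameter
defaults and limitations.

## Worked example

`examples/` contains one short script per capability. Segmentation sizing
(`examples/02_superpixel_segmentation.py`):

```
8000x8000 slide -> 42667 superpixels (mean area 1500.0 px)
12000x12000 slide -> 96000 superpixels (mean area 1500.0 px)
physical side of a 1500 px superpixel at 2.016 um/px: 78.1 um

512x512 mosaic: target 175, achieved 154 superpixels
superpixel areas: mean 1702 px, min 381, max 3162
```

The sizing rule keeps the mean superpixel area at *U* regardless of slide
size; the achieved count on a real segmentation sits a little under the
target because SLIC merges sub-minimum fragments.

Confusion-matrix metrics on the packaged reference cohort tables
(`examples/04_confusion_metrics.py`):

```
melanoma: 14092 superpixels, 6 classes
  overall accuracy   98.8 %
  macro row ratio    96.9 %
  macro col ratio    98.8 %
tnbc: 10349 superpixels, 6 classes
  overall accuracy   93.1 %
  macro row ratio    93.9 %
  macro col ratio    93.6 %
necrosis vs stroma in the breast-cancer table (the clinically hard distinction):
  necrosis row ratio 79.5 %  col ratio 91.5 %
```

Row/column ratios are the per-class diagonal fractions averaged without
weighting (macro); the breast-cancer necrosis row shows the hardest
distinction at 5x, necrosis vs stroma.

`examples/03_train_and_map.py` runs the full chain on a small synthetic
corpus — segment → isocenter-label → augment → train the CNN for ten
epochs → classify a held-out slide → quantify (about six minutes on one
CPU):

```
133 labeled superpixels from 3 training slides
966 patches after augmentation and balancing
classifier: 1,894,438 trainable parameters
validation accuracy by epoch: 0.36 0.84 0.74 0.88 0.93 0.91 0.94 0.95 0.94 0.94

held-out slide: 147 superpixels, accuracy 0.959
composition of tumor compartments (recovered vs ground truth):
  tumor        0.477  vs  0.479
  stroma       0.314  vs  0.309
  lymphocytes  0.209  vs  0.212
```

96% of held-out superpixels get the right tissue class, and the slide-level
composition — the quantity the pipeline exists to measure — matches the
generator's ground truth within half a percentage point per compartment.

The same stages are available from the shell:

```sh
histomap simulate --output corpus --seed 1
histomap train --corpus corpus --output model.npz --epochs 10
histomap classify --input corpus/test/test_000.png --model model.npz --output mapped
histomap quantify --tally mapped/map_tally.csv \
    --denominator tumor,stroma,lymphocytes --output quantified
histomap evaluate --cm melanoma
```

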