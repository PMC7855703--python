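"""End to end on a small synthetic corpus: segment, label, train, map, quantify.

Three training slides and one held-out slide are generated; superpixels are
labeled from the sample annotations by their centroid (isocenter), augmented
and balanced, and the compact CNN is trained for ten epochs. The held-out
slide is then classified and its composition within the tumor compartments is
compared to the generator's ground truth. Takes about six minutes on one CPU
(training the NumPy CNN dominates).
"""

import warnings

import numpy as np

import histomap as hm

warnings.simplefilter("ignore")
SEED = 17

spec = hm.melanoma_like_spec()
corpus = hm.generate_corpus(spec, n_train=3, n_test=1, seed=SEED)
names = corpus.class_names

patches_list, labels_list = [], []
for m in corpus.train:
    seg = hm.segment_slic(m.image, hm.superpixel_count(m.image.shape[0] * m.image.shape[1]))
    assigned = hm.assign_labels(seg, m.annotations)
    patches = hm.extract_patches(m.image, seg, side=56)
    keep = [i for i, s in enumerate(patches.source_ids) if int(s) in assigned]
    patches_list.append(patches.patches[keep])
    labels_list.extend(names.index(assigned[int(patches.source_ids[i])]) for i in keep)

dataset = hm.PatchDataset(
    np.concatenate(patches_list),
    np.arange(sum(map(len, patches_list))),
    labels=np.asarray(labels_list),
    class_names=names,
)
print(f"{len(dataset)} labeled superpixels from {len(corpus.train)} training slides")
augmented = hm.augment(dataset, hm.AugmentationPolicy(balance=True), seed=SEED)
print(f"{len(augmented)} patches after augmentation and balancing")

model = hm.build_model(hm.ArchitectureConfig(n_classes=len(names)), seed=SEED)
print(f"classifier: {hm.count_parameters(model):,} trainable parameters")
model, history = hm.train(
    model, augmented, hm.TrainingConfig(epochs=10, batch_size=64, seed=SEED)
)
print("validation accuracy by epoch:",
      " ".join(f"{h['val_acc']:.2f}" for h in history))

test = corpus.test[0]
seg = hm.segment_slic(test.image, hm.superpixel_count(test.image.shape[0] * test.image.shape[1]))
patches = hm.extract_patches(test.image, seg, side=56)
pred, _ = hm.predict(model, patches)
truth = hm.assign_labels(seg, hm.AnnotationSet.from_label_mask(test.truth_mask, test.legend))
accuracy = np.mean([names[p] == truth[int(s)] for s, p in zip(patches.source_ids, pred)])
print(f"\nheld-out slide: {seg.n_superpixels} superpixels, accuracy {accuracy:.3f}")

classes = {int(s): names[p] for s, p in zip(patches.source_ids, pred)}
cmap = hm.render_map(seg, classes, hm.synthetic.DEFAULT_PALETTE, names)
compartments = ["tumor", "stroma", "lymphocytes"]
summary = hm.composition(cmap, compartments)
truth_counts = np.bincount(test.truth_mask.ravel(), minlength=len(names))
truth_total = sum(truth_counts[names.index(c)] for c in compartments)
print("composition of tumor compartments (recovered vs ground truth):")
for c in compartments:
    print(f"  {c:12s} {summary.fractions[c]:.3f}  vs  "
          f"{truth_counts[names.index(c)] / truth_total:.3f}")
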