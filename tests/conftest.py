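"""Shared fixtures.

The expensive full-pipeline run (generate corpus -> normalize -> segment ->
label -> augment -> train CNN -> classify held-out slides -> quantify) is a
session fixture so the end-to-end assertions share one computation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import histomap as hm

PIPELINE_SEED = 17
N_TRAIN, N_TEST = 3, 2
EPOCHS = 10
BATCH = 64
DENOMINATOR = ["tumor", "stroma", "lymphocytes"]


@pytest.fixture(scope="session")
def mosaic():
    """One default 6-class mosaic, seeded."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return hm.generate_mosaic(hm.melanoma_like_spec(seed=7))


@pytest.fixture(scope="session")
def mosaic_segmentation(mosaic):
    n = hm.superpixel_count(mosaic.image.shape[0] * mosaic.image.shape[1])
    return hm.segment_slic(mosaic.image, n)


def _foreign_fraction(seg, truth_mask, threshold=0.05):
    """Fraction of superpixels with more than ``threshold`` foreign-class pixels."""
    bad = 0
    for rec in seg.records:
        classes = truth_mask[seg.label_raster == rec.id]
        purity = np.bincount(classes).max() / classes.size
        if 1.0 - purity > threshold:
            bad += 1
    return bad / seg.n_superpixels


@pytest.fixture(scope="session")
def pipeline_run():
    """Full pipeline on the seeded synthetic corpus; returns summary metrics."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        spec = hm.melanoma_like_spec()
        corpus = hm.generate_corpus(spec, N_TRAIN, N_TEST, seed=PIPELINE_SEED)
        cn = corpus.class_names
        ref_stats = hm.compute_color_stats(corpus.train[0].image)

        all_patches, all_labels = [], []
        purity_match = purity_total = 0
        foreign = []
        for m in corpus.train:
            img = hm.reinhard_normalize(m.image, ref_stats)
            seg = hm.segment_slic(img, hm.superpixel_count(img.shape[0] * img.shape[1]))
            foreign.append(_foreign_fraction(seg, m.truth_mask))
            labels = hm.assign_labels(seg, m.annotations)
            patches = hm.extract_patches(img, seg, side=56)
            keep = [i for i, s in enumerate(patches.source_ids) if int(s) in labels]
            all_patches.append(patches.patches[keep])
            all_labels.extend(
                cn.index(labels[int(patches.source_ids[i])]) for i in keep
            )
            for rec in seg.records:
                if rec.id in labels:
                    majority = cn[
                        np.bincount(m.truth_mask[seg.label_raster == rec.id]).argmax()
                    ]
                    purity_total += 1
                    purity_match += majority == labels[rec.id]

        dataset = hm.PatchDataset(
            patches=np.concatenate(all_patches),
            source_ids=np.arange(sum(len(p) for p in all_patches)),
            labels=np.asarray(all_labels),
            class_names=cn,
        )
        augmented = hm.augment(
            dataset, hm.AugmentationPolicy(balance=True), seed=PIPELINE_SEED
        )
        model = hm.build_model(
            hm.ArchitectureConfig(n_classes=len(cn)), seed=PIPELINE_SEED
        )
        model, history = hm.train(
            model,
            augmented,
            hm.TrainingConfig(epochs=EPOCHS, batch_size=BATCH, seed=PIPELINE_SEED),
        )

        hits = total = 0
        composition_errors = []
        for m in corpus.test:
            img = hm.reinhard_normalize(m.image, ref_stats)
            seg = hm.segment_slic(img, hm.superpixel_count(img.shape[0] * img.shape[1]))
            foreign.append(_foreign_fraction(seg, m.truth_mask))
            patches = hm.extract_patches(img, seg, side=56)
            pred, _ = hm.predict(model, patches)
            truth = hm.assign_labels(
                seg, hm.AnnotationSet.from_label_mask(m.truth_mask, m.legend)
            )
            for sid, p in zip(patches.source_ids, pred):
                total += 1
                hits += cn[p] == truth[int(sid)]
            classes = {int(s): cn[p] for s, p in zip(patches.source_ids, pred)}
            palette = {c: (i, 0, 0) for i, c in enumerate(cn)}
            cmap = hm.render_map(seg, classes, palette, cn)
            summary = hm.composition(cmap, DENOMINATOR)
            truth_counts = np.bincount(m.truth_mask.ravel(), minlength=len(cn))
            truth_total = sum(truth_counts[cn.index(c)] for c in DENOMINATOR)
            composition_errors.append(
                max(
                    abs(summary.fractions[c] - truth_counts[cn.index(c)] / truth_total)
                    for c in DENOMINATOR
                )
            )

    return {
        "corpus": corpus,
        "model": model,
        "history": history,
        "label_purity": purity_match / purity_total,
        "n_labeled": purity_total,
        "test_accuracy": hits / total,
        "n_test_superpixels": total,
        "composition_errors": composition_errors,
        "foreign_fractions": foreign,
        "best_val_acc": max(h["val_acc"] for h in history),
    }
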