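"""Whole-slide classification maps and tumor-composition features.

Once every superpixel carries a predicted tissue class, the per-superpixel
labels are rendered back onto the pixel grid to form a class raster, pixels
are tallied per class, and composition scores — e.g. the stroma-to-tumor
ratio (stroma pixels over all pixels in tumor compartments) or the
lymphocyte-cluster ratio — are computed over a configurable set of "tumor
compartment" classes that excludes background, fat and normal anatomy.
Per-subject scores can then be dichotomized at the median into low/high
groups for downstream survival or group-comparison statistics.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .superpixels import SuperpixelSegmentation

__all__ = [
    "ClassificationMap",
    "CompositionSummary",
    "render_map",
    "composition",
    "median_split",
]

# canonical score aliases for classes with established names in pathology
_SCORE_ALIASES = {
    "stroma": "stroma_ratio",
    "lymphocytes": "lymphocyte_ratio",
    "necrosis": "necrosis_ratio",
    "differentiation": "differentiation_ratio",
    "hemorrhage": "hemorrhage_ratio",
    "tumor": "tumor_ratio",
}


@dataclass
class ClassificationMap:
    """Per-pixel class raster derived from a classified segmentation."""

    seg: SuperpixelSegmentation
    class_names: List[str]
    classes: np.ndarray  # (n_superpixels,) class index per superpixel id
    class_raster: np.ndarray  # (H, W) class index per pixel
    palette: Dict[str, tuple]
    pixel_tally: Dict[str, int]

    def render_rgb(self) -> np.ndarray:
        lut = np.array([self.palette[c] for c in self.class_names], dtype=np.uint8)
        return lut[self.class_raster]

    def save(self, directory: str, name: str = "map") -> None:
        """Indexed PNG + JSON legend + tally CSV."""
        os.makedirs(directory, exist_ok=True)
        img = Image.fromarray(self.class_raster.astype(np.uint8), mode="P")
        flat = []
        for c in self.class_names:
            flat.extend(self.palette[c])
        img.putpalette(flat)
        img.save(os.path.join(directory, f"{name}_classes.png"))
        with open(os.path.join(directory, f"{name}_legend.json"), "w") as fh:
            json.dump(
                {
                    "class_names": self.class_names,
                    "palette": {c: list(self.palette[c]) for c in self.class_names},
                },
                fh,
            )
        pd.DataFrame(
            [{"class_name": c, "pixels": self.pixel_tally[c]} for c in self.class_names]
        ).to_csv(os.path.join(directory, f"{name}_tally.csv"), index=False)


@dataclass
class CompositionSummary:
    """Class fractions within the tumor-compartment denominator."""

    fractions: Dict[str, float]
    denominator_classes: List[str]
    scores: Dict[str, float]
    denominator_pixels: int

    def to_csv(self, path: str) -> None:
        rows = [
            {"class_name": c, "fraction": self.fractions[c], "in_denominator": True}
            for c in self.denominator_classes
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


def render_map(
    seg: SuperpixelSegmentation,
    classes: Mapping[int, str],
    palette: Mapping[str, tuple],
    class_names: Optional[Sequence[str]] = None,
) -> ClassificationMap:
    """Project per-superpixel classes onto the pixel grid and tally pixels.

    ``classes`` must cover every superpixel id. The raster is a pure lookup:
    the class of pixel p is the class of its superpixel.
    """
    if class_names is None:
        class_names = sorted(set(classes.values()))
    class_names = list(class_names)
    index = {c: i for i, c in enumerate(class_names)}
    n = seg.n_superpixels
    per_sp = np.empty(n, dtype=np.int32)
    for rec in seg.records:
        if rec.id not in classes:
            raise KeyError(f"no class for superpixel {rec.id}")
        cname = classes[rec.id]
        if cname not in index:
            raise KeyError(f"class {cname!r} missing from class_names")
        per_sp[rec.id] = index[cname]
    class_raster = per_sp[seg.label_raster]
    counts = np.bincount(class_raster.ravel(), minlength=len(class_names))
    tally = {c: int(counts[i]) for i, c in enumerate(class_names)}
    missing = set(class_names) - set(palette)
    if missing:
        raise KeyError(f"palette missing classes: {sorted(missing)}")
    return ClassificationMap(
        seg=seg,
        class_names=class_names,
        classes=per_sp,
        class_raster=class_raster,
        palette={c: tuple(palette[c]) for c in class_names},
        pixel_tally=tally,
    )


def composition(
    cmap_or_tally,
    denominator_classes: Sequence[str],
) -> CompositionSummary:
    """Composition fractions over the tumor-compartment denominator.

    Accepts a :class:`ClassificationMap` or a plain class -> pixel-count
    mapping. Each class in ``denominator_classes`` gets
    ``pixels(class) / pixels(denominator)``; classes outside the denominator
    (empty space, fat, normal anatomy) are excluded from the total.
    """
    tally = cmap_or_tally.pixel_tally if isinstance(cmap_or_tally, ClassificationMap) else dict(cmap_or_tally)
    denominator_classes = list(denominator_classes)
    if not denominator_classes:
        raise ValueError("denominator_classes must be non-empty")
    unknown = [c for c in denominator_classes if c not in tally]
    if unknown:
        raise ValueError(f"denominator classes not present in tally: {unknown}")
    total = sum(tally[c] for c in denominator_classes)
    if total == 0:
        raise ValueError("empty tumor compartment")
    fractions = {c: tally[c] / total for c in denominator_classes}
    scores = {_SCORE_ALIASES.get(c, f"{c}_ratio"): fractions[c] for c in denominator_classes}
    return CompositionSummary(
        fractions=fractions,
        denominator_classes=denominator_classes,
        scores=scores,
        denominator_pixels=int(total),
    )


def median_split(scores: Mapping[str, float]) -> Dict[str, str]:
    """Dichotomize per-subject scores at the median: ``<= median`` -> "low".

    Splitting at the median keeps group sizes within the number of subjects
    tied at the median of each other, which is what makes the groups
    comparable for survival analysis.
    """
    if len(scores) < 2:
        raise ValueError("need at least 2 subjects")
    values = np.asarray(list(scores.values()), dtype=float)
    if np.all(values == values[0]):
        raise ValueError("degenerate split: all scores equal")
    med = float(np.median(values))
    return {k: ("low" if v <= med else "high") for k, v in scores.items()}


def groups_to_csv(scores: Mapping[str, float], groups: Mapping[str, str], path: str) -> None:
    pd.DataFrame(
        [{"subject_id": k, "score": scores[k], "group": groups[k]} for k in scores]
    ).to_csv(path, index=False)
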