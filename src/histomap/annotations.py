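"""Region annotations and superpixel label assignment.

Pathologist-style annotations mark samples of each tissue category without
delineating boundaries. A superpixel inherits the class of the annotated
region that contains its isocenter (centroid); superpixels whose centroid
falls outside every region, or inside regions of two different classes, stay
unlabeled and are excluded from training and testing.

Labeled patches are expanded by the standard augmentation family — rotations
(90°, −90°, 180°), horizontal/vertical flips, histogram-equalization
contrast — and class imbalance is evened out by seeded oversampling from the
augmentation pool.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
from shapely.geometry import Point, shape, mapping
from shapely.geometry.base import BaseGeometry
from skimage import exposure

from .superpixels import PatchDataset, SuperpixelSegmentation

__all__ = [
    "Region",
    "AnnotationSet",
    "AugmentationPolicy",
    "assign_labels",
    "augment",
]


@dataclass
class Region:
    """One annotated region: a class name plus a polygon or boolean mask.

    Polygon coordinates are (x=col, y=row) in pixel units of the 5x image.
    """

    class_name: str
    geometry: Optional[BaseGeometry] = None
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if (self.geometry is None) == (self.mask is None):
            raise ValueError("region needs exactly one of geometry or mask")

    def contains(self, row: int, col: int) -> bool:
        """Strict containment of a pixel-center point."""
        if self.geometry is not None:
            return bool(self.geometry.contains(Point(float(col), float(row))))
        h, w = self.mask.shape
        return 0 <= row < h and 0 <= col < w and bool(self.mask[row, col])


@dataclass
class AnnotationSet:
    """Named tissue-class regions for one image frame."""

    regions: List[Region]
    class_names: List[str]

    def __post_init__(self) -> None:
        if len(set(self.class_names)) != len(self.class_names):
            raise ValueError("class_names must be unique")
        for r in self.regions:
            if r.class_name not in self.class_names:
                raise ValueError(f"region class {r.class_name!r} not in class_names")

    @classmethod
    def from_geojson(cls, path_or_obj: Union[str, dict], class_names: Optional[Sequence[str]] = None) -> "AnnotationSet":
        """Load a FeatureCollection whose features carry a ``class_name`` property."""
        if isinstance(path_or_obj, str):
            with open(path_or_obj) as fh:
                obj = json.load(fh)
        else:
            obj = path_or_obj
        regions = [
            Region(class_name=f["properties"]["class_name"], geometry=shape(f["geometry"]))
            for f in obj["features"]
        ]
        if class_names is None:
            seen: List[str] = []
            for r in regions:
                if r.class_name not in seen:
                    seen.append(r.class_name)
            class_names = seen
        return cls(regions=regions, class_names=list(class_names))

    def to_geojson(self, path: Optional[str] = None) -> dict:
        feats = []
        for r in self.regions:
            if r.geometry is None:
                raise ValueError("mask regions cannot be serialized to GeoJSON")
            feats.append(
                {
                    "type": "Feature",
                    "properties": {"class_name": r.class_name},
                    "geometry": mapping(r.geometry),
                }
            )
        obj = {"type": "FeatureCollection", "features": feats}
        if path is not None:
            with open(path, "w") as fh:
                json.dump(obj, fh)
        return obj

    @classmethod
    def from_label_mask(cls, mask: np.ndarray, legend: Dict[int, str]) -> "AnnotationSet":
        """Build full-coverage regions from an integer label raster + legend."""
        mask = np.asarray(mask)
        class_names = [legend[k] for k in sorted(legend)]
        regions = [
            Region(class_name=legend[k], mask=(mask == k)) for k in sorted(legend) if np.any(mask == k)
        ]
        return cls(regions=regions, class_names=class_names)


def assign_labels(seg: SuperpixelSegmentation, ann: AnnotationSet) -> Dict[int, str]:
    """Isocenter labeling: superpixel id -> class name (partial map).

    A superpixel is labeled iff its centroid (rounded half-up to the nearest
    pixel) lies strictly inside regions of exactly one class; centroids in no
    region, or in overlapping regions of different classes, are left out.
    """
    labels: Dict[int, str] = {}
    for rec in seg.records:
        row = int(np.floor(rec.centroid[0] + 0.5))
        col = int(np.floor(rec.centroid[1] + 0.5))
        hit_classes = {r.class_name for r in ann.regions if r.contains(row, col)}
        if len(hit_classes) == 1:
            labels[rec.id] = hit_classes.pop()
        elif len(hit_classes) > 1:
            warnings.warn(
                f"superpixel {rec.id} centroid falls in overlapping regions of "
                f"classes {sorted(hit_classes)}; left unlabeled",
                stacklevel=2,
            )
    return labels


@dataclass(frozen=True)
class AugmentationPolicy:
    """Which transforms to apply and whether to even out class imbalance.

    The identity (the original patch) is always retained. ``balance`` uses
    seeded sampling with replacement from each class's augmentation pool so
    every class reaches the largest class's pool size.
    """

    rotations: tuple = (90, -90, 180)
    flips: tuple = ("horizontal", "vertical")
    contrast: bool = True
    balance: bool = False

    def transforms(self):
        """Ordered (name, function) pairs, identity excluded."""
        out = []
        for deg in self.rotations:
            if deg not in (90, -90, 180):
                raise ValueError(f"unsupported rotation {deg}")
            k = {90: 1, 180: 2, -90: 3}[deg]
            out.append((f"rot{deg}", lambda p, k=k: np.rot90(p, k=k)))
        for f in self.flips:
            if f == "horizontal":
                out.append(("fliph", lambda p: p[:, ::-1]))
            elif f == "vertical":
                out.append(("flipv", lambda p: p[::-1, :]))
            else:
                raise ValueError(f"unsupported flip {f}")
        if self.contrast:
            out.append(("histeq", _equalize))
        return out


def _equalize(patch: np.ndarray) -> np.ndarray:
    eq = np.stack([exposure.equalize_hist(patch[..., c]) for c in range(3)], axis=-1)
    return np.clip(np.rint(eq * 255.0), 0, 255).astype(np.uint8)


def augment(
    dataset: PatchDataset,
    policy: AugmentationPolicy = AugmentationPolicy(),
    seed: int = 0,
) -> PatchDataset:
    """Expand a labeled patch set by the policy's transforms.

    The output holds every original followed by its transformed copies, label
    preserved. With ``policy.balance`` each class is then oversampled (with
    replacement, seeded) from its own pool up to the largest class pool, so
    post-balancing class counts are equal.
    """
    if dataset.labels is None:
        raise ValueError("dataset must be labeled")
    transforms = policy.transforms()
    n_classes = len(dataset.class_names)
    counts = np.bincount(dataset.labels, minlength=n_classes)

    patches = [dataset.patches]
    ids = [dataset.source_ids]
    labels = [dataset.labels]
    for _, fn in transforms:
        patches.append(np.stack([fn(p) for p in dataset.patches]))
        ids.append(dataset.source_ids)
        labels.append(dataset.labels)
    pool_patches = np.concatenate(patches)
    pool_ids = np.concatenate(ids)
    pool_labels = np.concatenate(labels)

    if policy.balance:
        present = counts > 0
        if not np.all(present):
            missing = dataset.class_names[int(np.argmin(counts))]
            raise ValueError(f"cannot balance empty class {missing!r}")
        rng = np.random.default_rng(seed)
        pool_counts = np.bincount(pool_labels, minlength=n_classes)
        target = int(pool_counts.max())
        extra_idx = []
        for c in range(n_classes):
            deficit = target - int(pool_counts[c])
            if deficit > 0:
                members = np.flatnonzero(pool_labels == c)
                extra_idx.append(rng.choice(members, size=deficit, replace=True))
        if extra_idx:
            extra = np.concatenate(extra_idx)
            pool_patches = np.concatenate([pool_patches, pool_patches[extra]])
            pool_ids = np.concatenate([pool_ids, pool_ids[extra]])
            pool_labels = np.concatenate([pool_labels, pool_labels[extra]])

    return PatchDataset(
        patches=pool_patches,
        source_ids=pool_ids,
        labels=pool_labels,
        class_names=list(dataset.class_names),
    )
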