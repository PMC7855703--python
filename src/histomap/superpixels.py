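"""SLIC superpixel segmentation of low-magnification slide images.

A slide at 5x is over-segmented into superpixels of roughly constant area U
(default 1500 px, ≈117 μm per side at ~2-2.3 μm/px): the superpixel count for
an image of S pixels is ceil(S / U), so the mean superpixel size is held
across slides regardless of their dimensions. Each superpixel is then cropped
at its bounding box and resized bilinearly to a fixed CNN input side (56 or
75 px).
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import tifffile
from PIL import Image
from skimage.measure import regionprops
from skimage.segmentation import slic
from skimage.transform import resize

__all__ = [
    "DEFAULT_PIXELS_PER_SUPERPIXEL",
    "SuperpixelRecord",
    "SuperpixelSegmentation",
    "PatchDataset",
    "superpixel_count",
    "segment_slic",
    "extract_patches",
    "physical_superpixel_size",
]

#: desired mean superpixel area in pixels (the constant U), held across slides
DEFAULT_PIXELS_PER_SUPERPIXEL = 1500

#: allowed CNN input sides
PATCH_SIDES = (56, 75)


@dataclass(frozen=True)
class SuperpixelRecord:
    """Geometry of one superpixel: area, centroid and half-open bounding box."""

    id: int
    pixel_count: int
    centroid: tuple  # (row, col), mean of member pixel centers
    bounding_box: tuple  # (min_row, min_col, max_row, max_col), half-open


@dataclass
class SuperpixelSegmentation:
    """Per-pixel superpixel ids plus per-superpixel geometry records.

    Ids are contiguous integers starting at 0; every pixel carries exactly
    one id.
    """

    label_raster: np.ndarray
    records: list = field(default_factory=list)

    @property
    def n_superpixels(self) -> int:
        return len(self.records)

    def to_csv(self, path: str) -> None:
        rows = [
            {
                "id": r.id,
                "pixel_count": r.pixel_count,
                "centroid_row": r.centroid[0],
                "centroid_col": r.centroid[1],
                "bbox_min_row": r.bounding_box[0],
                "bbox_min_col": r.bounding_box[1],
                "bbox_max_row": r.bounding_box[2],
                "bbox_max_col": r.bounding_box[3],
            }
            for r in self.records
        ]
        pd.DataFrame(rows).to_csv(path, index=False)

    def save(self, directory: str, name: str = "segmentation") -> None:
        """Write the label raster as 32-bit TIFF and the records as CSV."""
        os.makedirs(directory, exist_ok=True)
        tifffile.imwrite(
            os.path.join(directory, f"{name}_labels.tif"),
            self.label_raster.astype(np.int32),
        )
        self.to_csv(os.path.join(directory, f"{name}_superpixels.csv"))

    @classmethod
    def load(cls, directory: str, name: str = "segmentation") -> "SuperpixelSegmentation":
        labels = tifffile.imread(os.path.join(directory, f"{name}_labels.tif"))
        return cls(label_raster=np.asarray(labels), records=_records_from_labels(labels))


@dataclass
class PatchDataset:
    """Fixed-size RGB patches, one per superpixel, the CNN's currency.

    ``labels`` (when present) are integer indices into ``class_names``.
    """

    patches: np.ndarray  # (N, side, side, 3) uint8
    source_ids: np.ndarray  # (N,) superpixel id per patch
    labels: Optional[np.ndarray] = None  # (N,) int indices into class_names
    class_names: Optional[list] = None

    def __post_init__(self) -> None:
        self.patches = np.asarray(self.patches)
        self.source_ids = np.asarray(self.source_ids)
        if self.patches.ndim != 4 or self.patches.shape[1] != self.patches.shape[2]:
            raise ValueError("patches must be (N, side, side, 3)")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.class_names is None:
                raise ValueError("labels given without class_names")
            if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= len(self.class_names)):
                raise ValueError("labels must index into class_names")

    @property
    def side(self) -> int:
        return int(self.patches.shape[1])

    def __len__(self) -> int:
        return int(self.patches.shape[0])

    def save(self, directory: str, prefix: str = "slide") -> None:
        """Write one PNG per patch plus a manifest CSV."""
        os.makedirs(directory, exist_ok=True)
        rows = []
        for i in range(len(self)):
            fname = f"{prefix}_{int(self.source_ids[i])}.png"
            Image.fromarray(self.patches[i]).save(os.path.join(directory, fname))
            rows.append(
                {
                    "file": fname,
                    "superpixel_id": int(self.source_ids[i]),
                    "label": (
                        self.class_names[int(self.labels[i])] if self.labels is not None else ""
                    ),
                }
            )
        pd.DataFrame(rows).to_csv(os.path.join(directory, "manifest.csv"), index=False)


def superpixel_count(si: int, u: int = DEFAULT_PIXELS_PER_SUPERPIXEL) -> int:
    """Number of superpixels for an image of ``si`` pixels: ceil(si / u).

    Holding ``u`` constant across slides keeps the mean superpixel area (and
    hence physical size) uniform over a dataset of differently sized scans.
    """
    if si < 1 or u < 1:
        raise ValueError("si and u must be positive")
    return math.ceil(si / u)


def _records_from_labels(labels: np.ndarray) -> list:
    # regionprops requires positive labels
    return [
        SuperpixelRecord(
            id=int(p.label - 1),
            pixel_count=int(p.area),
            centroid=(float(p.centroid[0]), float(p.centroid[1])),
            bounding_box=tuple(int(v) for v in p.bbox),
        )
        for p in regionprops(labels + 1)
    ]


def segment_slic(
    image: np.ndarray,
    n_superpixels: int,
    compactness: float = 20.0,
    smoothing_sigma: float = 1.0,
    min_size_factor: float = 0.2,
) -> SuperpixelSegmentation:
    """Segment an RGB image into ~``n_superpixels`` SLIC superpixels.

    SLIC clusters pixels jointly in CIELAB color and image position, yielding
    roughly uniform, boundary-adhering regions; connectivity is enforced so
    every superpixel is one 4-connected component. The achieved count is
    approximate (SLIC merges fragments below ``min_size_factor`` of the mean
    area). ``smoothing_sigma`` is the Gaussian pre-smoothing applied inside
    SLIC; it suppresses sub-superpixel texture (nuclei) so boundaries follow
    tissue regions rather than single cells. Deterministic for fixed inputs.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an HxWx3 RGB raster")
    n_pixels = image.shape[0] * image.shape[1]
    if n_superpixels < 1 or n_superpixels > n_pixels:
        raise ValueError("n_superpixels must be in [1, pixel count]")
    labels = slic(
        image,
        n_segments=n_superpixels,
        compactness=compactness,
        sigma=smoothing_sigma,
        min_size_factor=min_size_factor,
        start_label=0,
        enforce_connectivity=True,
        convert2lab=True,
        channel_axis=-1,
    )
    # ensure contiguous ids 0..K-1
    _, labels = np.unique(labels, return_inverse=True)
    labels = labels.reshape(image.shape[:2]).astype(np.int32)
    return SuperpixelSegmentation(label_raster=labels, records=_records_from_labels(labels))


def extract_patches(
    image: np.ndarray,
    seg: SuperpixelSegmentation,
    side: int = 56,
    masked: bool = False,
    allow_any_side: bool = False,
) -> PatchDataset:
    """One fixed-size patch per superpixel, in superpixel-id order.

    Each patch is the axis-aligned bounding-box crop of the superpixel,
    resized with bilinear interpolation to ``side``x``side``. By default
    neighboring-superpixel pixels inside the box are kept (local context);
    with ``masked=True`` they are replaced by the superpixel's mean color.
    """
    image = np.asarray(image)
    if image.shape[:2] != seg.label_raster.shape:
        raise ValueError("segmentation does not match image shape")
    if side not in PATCH_SIDES and not allow_any_side:
        raise ValueError(f"side must be one of {PATCH_SIDES} (or pass allow_any_side=True)")
    patches = np.empty((seg.n_superpixels, side, side, 3), dtype=np.uint8)
    ids = np.empty(seg.n_superpixels, dtype=np.int64)
    for i, rec in enumerate(sorted(seg.records, key=lambda r: r.id)):
        r0, c0, r1, c1 = rec.bounding_box
        crop = image[r0:r1, c0:c1]
        if masked:
            crop = crop.copy()
            inside = seg.label_raster[r0:r1, c0:c1] == rec.id
            mean_color = crop[inside].mean(axis=0)
            crop[~inside] = np.rint(mean_color).astype(np.uint8)
        if crop.shape[0] == side and crop.shape[1] == side:
            patch = crop
        else:
            patch = resize(
                crop.astype(np.float64),
                (side, side),
                order=1,
                mode="edge",
                anti_aliasing=False,
                preserve_range=True,
            )
            patch = np.clip(np.rint(patch), 0, 255).astype(np.uint8)
        patches[i] = patch
        ids[i] = rec.id
    return PatchDataset(patches=patches, source_ids=ids)


def physical_superpixel_size(mean_area_px: float, um_per_px: float) -> float:
    """Mean superpixel side in micrometers: sqrt(area) x pixel pitch."""
    if mean_area_px <= 0 or um_per_px <= 0:
        raise ValueError("inputs must be positive")
    return math.sqrt(mean_area_px) * um_per_px
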