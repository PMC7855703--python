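"""Seeded histology-like mosaic generator.

Real 5x H&E scans cannot ship with the package, so every pipeline stage is
exercised on synthetic mosaics: an image is partitioned into compact random
blobs (per-class low-pass-filtered noise fields with bias offsets fitted so
the argmax-class area fractions match their targets to well under a
percentage point), and each class region is filled with a texture — a base color plus Gaussian
jitter, dark elliptical "nuclei" spots for cell-rich classes, fibrous streaks
for stroma — so classes are separable at patch scale but not from a single
pixel, which is what forces the classifier to use texture.

Alongside the image the generator emits the full ground-truth class mask and
a non-exhaustive, pathologist-style annotation set: a few square sample
regions per class, each strictly interior to one ground-truth region.
"""

from __future__ import annotations

import hashlib
import json
import os
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import binary_erosion, gaussian_filter
from shapely.geometry import box

from .annotations import AnnotationSet, Region

__all__ = [
    "ClassTexture",
    "MosaicSpec",
    "Mosaic",
    "Corpus",
    "generate_mosaic",
    "generate_corpus",
    "melanoma_like_spec",
    "DEFAULT_PALETTE",
]


@dataclass(frozen=True)
class ClassTexture:
    """Appearance of one tissue class at 5x.

    ``spot_density`` is the expected number of nuclei spots per class pixel;
    cell-rich classes (tumor, lymphocyte clusters) get dense dark spots,
    paucicellular classes get none. ``streaks`` adds fibrous directional
    banding (stroma), ``lattice`` a faint membrane grid (fat).
    """

    name: str
    base_rgb: Tuple[int, int, int]
    jitter_std: float = 5.0
    spot_density: float = 0.0
    spot_rgb: Optional[Tuple[int, int, int]] = None
    spot_radius: int = 1
    streaks: bool = False
    lattice: bool = False


@dataclass(frozen=True)
class MosaicSpec:
    """Layout + texture recipe for one synthetic slide.

    ``fractions`` are target per-class area fractions (must sum to 1); the
    blob scale is set by ``smooth_sigma`` (pixels). Annotation sample squares
    of side ``annotation_side`` are placed strictly inside class regions,
    up to ``annotations_per_class`` per class.
    """

    image_size: Tuple[int, int]
    textures: Tuple[ClassTexture, ...]
    fractions: Tuple[float, ...]
    seed: int = 0
    smooth_sigma: float = 40.0
    annotation_side: int = 40
    annotations_per_class: int = 8

    def __post_init__(self) -> None:
        if len(self.textures) != len(self.fractions):
            raise ValueError("one fraction per texture required")
        if len(self.textures) < 2:
            raise ValueError("need at least 2 classes")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        if min(self.fractions) <= 0:
            raise ValueError("fractions must be positive")
        h, w = self.image_size
        min_area = min(self.fractions) * h * w
        if min_area < self.annotation_side**2:
            raise ValueError(
                "infeasible layout: smallest class area cannot hold one "
                "annotation square"
            )

    @property
    def class_names(self) -> List[str]:
        return [t.name for t in self.textures]


@dataclass
class Mosaic:
    """One generated slide: image, exact ground-truth mask, sample annotations."""

    image: np.ndarray  # (H, W, 3) uint8
    truth_mask: np.ndarray  # (H, W) int32 class indices
    annotations: AnnotationSet
    class_names: List[str]
    seed: int

    @property
    def legend(self) -> Dict[int, str]:
        return dict(enumerate(self.class_names))

    def sha256(self) -> str:
        return hashlib.sha256(self.image.tobytes()).hexdigest()

    def mask_fractions(self) -> np.ndarray:
        counts = np.bincount(self.truth_mask.ravel(), minlength=len(self.class_names))
        return counts / counts.sum()

    def save(self, directory: str, name: str = "slide") -> None:
        """PNG image, PNG mask + JSON legend, GeoJSON annotations."""
        os.makedirs(directory, exist_ok=True)
        Image.fromarray(self.image).save(os.path.join(directory, f"{name}.png"))
        Image.fromarray(self.truth_mask.astype(np.uint8)).save(
            os.path.join(directory, f"{name}_mask.png")
        )
        with open(os.path.join(directory, f"{name}_legend.json"), "w") as fh:
            json.dump({str(k): v for k, v in self.legend.items()}, fh)
        self.annotations.to_geojson(os.path.join(directory, f"{name}_annotations.geojson"))


@dataclass
class Corpus:
    """Train/test mosaic sets generated from disjoint seed streams."""

    train: List[Mosaic]
    test: List[Mosaic]
    class_names: List[str]

    def save(self, directory: str) -> None:
        rows = []
        for split, mosaics in (("train", self.train), ("test", self.test)):
            for i, m in enumerate(mosaics):
                name = f"{split}_{i:03d}"
                m.save(os.path.join(directory, split), name=name)
                rows.append({"split": split, "name": name, "seed": m.seed, "sha256": m.sha256()})
        pd.DataFrame(rows).to_csv(os.path.join(directory, "manifest.csv"), index=False)


#: layout fractions are fitted to within this tolerance (fraction units)
_LAYOUT_TOL = 0.004
_LAYOUT_MAX_ITER = 300


def _blob_layout(spec: MosaicSpec, rng: np.random.Generator) -> np.ndarray:
    """Partition the frame into compact per-class blobs hitting the fractions.

    One smooth random field per class (low-pass filtered white noise,
    Gaussian ``smooth_sigma``) is biased by a per-class offset and each pixel
    takes the argmax class. The offsets are fitted iteratively so the
    achieved area fractions land within ±0.4 percentage points of the
    targets; blob diameter scales with ``smooth_sigma``.
    """
    h, w = spec.image_size
    n_classes = len(spec.fractions)
    fields = np.stack(
        [gaussian_filter(rng.standard_normal((h, w)), sigma=spec.smooth_sigma) for _ in range(n_classes)]
    )
    fields = (fields - fields.mean(axis=(1, 2), keepdims=True)) / fields.std(
        axis=(1, 2), keepdims=True
    )
    targets = np.asarray(spec.fractions)
    bias = np.zeros(n_classes)
    for _ in range(_LAYOUT_MAX_ITER):
        mask = np.argmax(fields + bias[:, None, None], axis=0)
        frac = np.bincount(mask.ravel(), minlength=n_classes) / (h * w)
        err = targets - frac
        if np.abs(err).max() < _LAYOUT_TOL:
            return mask.astype(np.int32)
        bias += err
    raise ValueError(
        "infeasible layout: could not reach target fractions within "
        f"{_LAYOUT_MAX_ITER} iterations (smooth_sigma too large for the frame?)"
    )


_DISK_CACHE: Dict[int, np.ndarray] = {}


def _disk_offsets(radius: int) -> np.ndarray:
    if radius not in _DISK_CACHE:
        r = np.arange(-radius, radius + 1)
        dy, dx = np.meshgrid(r, r, indexing="ij")
        keep = dy**2 + dx**2 <= radius**2
        _DISK_CACHE[radius] = np.stack([dy[keep], dx[keep]], axis=1)
    return _DISK_CACHE[radius]


def _paint_class(
    img: np.ndarray,
    mask: np.ndarray,
    class_idx: int,
    tex: ClassTexture,
    rng: np.random.Generator,
) -> None:
    h, w, _ = img.shape
    region = mask == class_idx
    n_px = int(region.sum())
    base = np.asarray(tex.base_rgb, dtype=np.float64)
    img[region] = base + rng.normal(0.0, tex.jitter_std, size=(n_px, 3))

    yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    if tex.streaks:
        phase = rng.uniform(0, 2 * np.pi)
        wave = np.sin(2 * np.pi * (yy + xx) / 17.0 + phase)
        sel = region & (wave > 0.55)
        img[sel] *= 0.90
    if tex.lattice:
        phase = rng.uniform(0, 2 * np.pi)
        wave = np.sin(2 * np.pi * (yy - xx) / 11.0 + phase)
        sel = region & (wave > 0.9)
        img[sel] *= 0.92

    if tex.spot_density > 0 and n_px > 0:
        n_spots = int(round(tex.spot_density * n_px))
        if n_spots == 0:
            return
        flat = np.flatnonzero(region.ravel())
        centers = rng.choice(flat, size=n_spots, replace=True)
        cy, cx = np.divmod(centers, w)
        off = _disk_offsets(tex.spot_radius)
        rows = (cy[:, None] + off[None, :, 0]).ravel()
        cols = (cx[:, None] + off[None, :, 1]).ravel()
        ok = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
        rows, cols = rows[ok], cols[ok]
        same = mask[rows, cols] == class_idx  # never bleed into neighbors
        rows, cols = rows[same], cols[same]
        spot = np.asarray(tex.spot_rgb, dtype=np.float64)
        img[rows, cols] = spot + rng.normal(0.0, 3.0, size=(rows.size, 3))


def _sample_annotation_boxes(
    mask: np.ndarray,
    class_idx: int,
    side: int,
    k: int,
    rng: np.random.Generator,
):
    """Up to ``k`` side x side squares fully interior to the class region."""
    region = mask == class_idx
    s = side
    while s >= 8:
        interior = binary_erosion(region, structure=np.ones((s, s)))
        cand = np.flatnonzero(interior.ravel())
        if cand.size:
            break
        s -= 8  # shrink until a square fits
    else:
        return [], s
    w = mask.shape[1]
    half = s // 2
    chosen: List[Tuple[int, int]] = []
    order = rng.permutation(cand)
    for f in order:
        r, c = divmod(int(f), w)
        if all(abs(r - r0) >= s or abs(c - c0) >= s for r0, c0 in chosen):
            chosen.append((r, c))
            if len(chosen) == k:
                break
    boxes = [
        box(c - half + 0.5, r - half + 0.5, c + half - 0.5, r + half - 0.5)
        for r, c in chosen
    ]
    return boxes, s


def generate_mosaic(spec: MosaicSpec) -> Mosaic:
    """Deterministically generate one annotated mosaic from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    mask = _blob_layout(spec, rng)
    h, w = spec.image_size
    img = np.empty((h, w, 3), dtype=np.float64)
    for c, tex in enumerate(spec.textures):
        _paint_class(img, mask, c, tex, rng)
    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    regions: List[Region] = []
    for c, tex in enumerate(spec.textures):
        boxes, used_side = _sample_annotation_boxes(
            mask, c, spec.annotation_side, spec.annotations_per_class, rng
        )
        if not boxes:
            raise ValueError(
                f"infeasible layout: no interior annotation square fits class "
                f"{tex.name!r}"
            )
        if used_side < spec.annotation_side:
            warnings.warn(
                f"class {tex.name!r}: annotation squares shrunk to side {used_side}",
                stacklevel=2,
            )
        regions.extend(Region(class_name=tex.name, geometry=b) for b in boxes)
    ann = AnnotationSet(regions=regions, class_names=spec.class_names)
    return Mosaic(
        image=image,
        truth_mask=mask,
        annotations=ann,
        class_names=spec.class_names,
        seed=spec.seed,
    )


def generate_corpus(spec: MosaicSpec, n_train: int, n_test: int, seed: int = 0) -> Corpus:
    """Train/test mosaics from disjoint seed streams spawned from ``seed``."""
    if n_train < 1 or n_test < 1:
        raise ValueError("n_train and n_test must be >= 1")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_train + n_test)
    mosaics = [generate_mosaic(replace(spec, seed=int(s))) for s in child_seeds]
    return Corpus(
        train=mosaics[:n_train],
        test=mosaics[n_train:],
        class_names=spec.class_names,
    )


#: render palette for the default 6-class mosaic
DEFAULT_PALETTE = {
    "tumor": (200, 0, 0),
    "stroma": (255, 170, 0),
    "epidermis": (120, 60, 20),
    "lymphocytes": (0, 90, 200),
    "fat": (240, 220, 130),
    "empty_space": (230, 230, 230),
}


def melanoma_like_spec(
    image_size: Tuple[int, int] = (512, 512),
    seed: int = 0,
) -> MosaicSpec:
    """Default 6-class mosaic emulating the tissue categories of a melanoma
    slide at 5x: tumor, stroma, epidermis, lymphocyte clusters, fat and
    empty/white space."""
    textures = (
        ClassTexture("tumor", (165, 105, 185), jitter_std=6, spot_density=0.020,
                     spot_rgb=(125, 70, 150), spot_radius=2),
        ClassTexture("stroma", (235, 175, 195), jitter_std=5, streaks=True),
        ClassTexture("epidermis", (185, 125, 105), jitter_std=6, spot_density=0.008,
                     spot_rgb=(150, 95, 80), spot_radius=2),
        ClassTexture("lymphocytes", (110, 85, 170), jitter_std=6, spot_density=0.060,
                     spot_rgb=(85, 62, 140), spot_radius=1),
        ClassTexture("fat", (235, 215, 170), jitter_std=4, lattice=True),
        ClassTexture("empty_space", (250, 250, 250), jitter_std=2),
    )
    fractions = (0.28, 0.18, 0.10, 0.12, 0.14, 0.18)
    h, w = image_size
    return MosaicSpec(
        image_size=image_size,
        textures=textures,
        fractions=fractions,
        seed=seed,
        smooth_sigma=min(h, w) / 8.0,
    )
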