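"""Reinhard stain normalization.

Whole-slide H&E scans vary in stain intensity and hue between labs and
scanners. Before segmentation and classification every slide is color-matched
to a reference by the Reinhard method: the image is mapped into the
decorrelated log color space lαβ (Ruderman), each channel is shifted and
scaled so its mean and standard deviation equal the reference's, and the
result is mapped back to 8-bit RGB.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ColorStats",
    "rgb_to_lab",
    "lab_to_rgb",
    "compute_color_stats",
    "reinhard_normalize",
]

# Ruderman RGB -> LMS cone-response matrix, applied to RGB scaled to [0, 1].
_RGB2LMS = np.array(
    [
        [0.3811, 0.5783, 0.0402],
        [0.1967, 0.7244, 0.0782],
        [0.0241, 0.1288, 0.8444],
    ]
)
# Decorrelating rotation from log-LMS to lαβ.
_LMS2LAB = np.diag([1.0 / np.sqrt(3.0), 1.0 / np.sqrt(6.0), 1.0 / np.sqrt(2.0)]) @ np.array(
    [
        [1.0, 1.0, 1.0],
        [1.0, 1.0, -2.0],
        [1.0, -1.0, 0.0],
    ]
)
# Exact inverses so the round trip is lossless to float precision.
_LMS2RGB = np.linalg.inv(_RGB2LMS)
_LAB2LMS = np.linalg.inv(_LMS2LAB)

#: added before the log so pure-black pixels stay finite
LOG_EPSILON = 1e-6


@dataclass(frozen=True)
class ColorStats:
    """Per-channel mean/std of an image in lαβ space.

    The color space is named ``lab_ruderman`` in serialized form to
    distinguish it from CIELAB.
    """

    means: np.ndarray
    stds: np.ndarray
    n_pixels: int
    space: str = field(default="lab_ruderman")

    def __post_init__(self) -> None:
        object.__setattr__(self, "means", np.asarray(self.means, dtype=float).reshape(3))
        object.__setattr__(self, "stds", np.asarray(self.stds, dtype=float).reshape(3))
        if self.n_pixels < 1:
            raise ValueError("n_pixels must be >= 1")
        if np.any(self.stds < 0):
            raise ValueError("stds must be non-negative")

    def to_json(self) -> str:
        return json.dumps(
            {
                "means": self.means.tolist(),
                "stds": self.stds.tolist(),
                "n_pixels": int(self.n_pixels),
                "space": self.space,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ColorStats":
        d = json.loads(text)
        return cls(
            means=np.asarray(d["means"], dtype=float),
            stds=np.asarray(d["stds"], dtype=float),
            n_pixels=int(d["n_pixels"]),
            space=d.get("space", "lab_ruderman"),
        )


def _check_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty input")
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 RGB raster, got shape {image.shape}")
    return image


def rgb_to_lab(image: np.ndarray) -> np.ndarray:
    """Map an 8-bit RGB raster to the decorrelated log color space lαβ.

    RGB is scaled to [0, 1], projected to LMS cone responses, log10-compressed
    (with a small epsilon guarding zeros) and rotated into lαβ.
    """
    image = _check_rgb(image)
    rgb = image.astype(np.float64) / 255.0
    lms = rgb @ _RGB2LMS.T
    log_lms = np.log10(lms + LOG_EPSILON)
    return log_lms @ _LMS2LAB.T


def lab_to_rgb(lab: np.ndarray) -> np.ndarray:
    """Invert :func:`rgb_to_lab`, clipping to [0, 255] and rounding to uint8."""
    lab = np.asarray(lab, dtype=np.float64)
    log_lms = lab @ _LAB2LMS.T
    lms = np.power(10.0, log_lms) - LOG_EPSILON
    rgb = lms @ _LMS2RGB.T
    return np.clip(np.rint(rgb * 255.0), 0, 255).astype(np.uint8)


def compute_color_stats(
    image: np.ndarray,
    exclude_background: bool = False,
    background_luminance: float = 0.9,
) -> ColorStats:
    """Per-channel mean and standard deviation of ``image`` in lαβ space.

    Parameters
    ----------
    image
        8-bit RGB raster, at least one pixel.
    exclude_background
        If true, drop near-white pixels (mean RGB above
        ``background_luminance`` of the maximum) before computing statistics.
        Off by default: statistics are taken over every pixel.
    """
    image = _check_rgb(image)
    lab = rgb_to_lab(image).reshape(-1, 3)
    if exclude_background:
        lum = image.reshape(-1, 3).mean(axis=1) / 255.0
        keep = lum <= background_luminance
        if not np.any(keep):
            raise ValueError("background exclusion removed every pixel")
        lab = lab[keep]
    return ColorStats(
        means=lab.mean(axis=0),
        stds=lab.std(axis=0),
        n_pixels=lab.shape[0],
    )


#: source channels with std below this are treated as constant (shift only)
_STD_FLOOR = 1e-8


def reinhard_normalize(source: np.ndarray, target: ColorStats) -> np.ndarray:
    """Color-match ``source`` to ``target`` statistics in lαβ space.

    Each lαβ channel is centered on the source mean, rescaled by
    ``target_std / source_std`` and re-centered on the target mean. A source
    channel with (numerically) zero variance is shifted only, with a warning,
    since no scale can be inferred. Output is 8-bit RGB of the input's shape.
    """
    if not isinstance(target, ColorStats):
        raise TypeError("target must be a ColorStats")
    if np.any(~np.isfinite(target.means)) or np.any(~np.isfinite(target.stds)):
        raise ValueError("invalid target stats")
    source = _check_rgb(source)
    src_stats = compute_color_stats(source)
    lab = rgb_to_lab(source)
    out = np.empty_like(lab)
    for c in range(3):
        centered = lab[..., c] - src_stats.means[c]
        if src_stats.stds[c] < _STD_FLOOR:
            if target.stds[c] >= _STD_FLOOR:
                warnings.warn(
                    f"source channel {c} has zero variance; applying shift only",
                    stacklevel=2,
                )
            out[..., c] = centered + target.means[c]
        else:
            out[..., c] = centered * (target.stds[c] / src_stats.stds[c]) + target.means[c]
    return lab_to_rgb(out)
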