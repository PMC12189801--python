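"""Image enhancement: thresholding, binary morphology and marker extraction.

Operates on the grayscale of the hematoxylin-only image, where nuclei are
dark on a light background.  Produces the classic sure-foreground /
sure-background / unknown partition used to seed the segmentation of
touching nuclei: the sure foreground is the high end of the Euclidean
distance transform, the sure background is everything far from the dilated
mask, and the ring in between is unknown.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

from .errors import InputError

__all__ = [
    "StructuringElement",
    "MarkerSet",
    "to_gray",
    "binary_threshold",
    "morphology",
    "clear_borders",
    "distance_transform",
    "extract_markers",
]

#: 8-connectivity structure for component operations on blob-like nuclei.
STRUCTURE_8 = np.ones((3, 3), dtype=bool)


def _square_footprint(size: int) -> np.ndarray:
    return np.ones((size, size), dtype=bool)


@dataclass(frozen=True)
class StructuringElement:
    """Odd-sized boolean footprint applied ``iterations`` times."""

    footprint: np.ndarray = field(default_factory=lambda: _square_footprint(3))
    iterations: int = 1

    def __post_init__(self) -> None:
        fp = np.asarray(self.footprint, dtype=bool)
        if fp.ndim != 2 or fp.shape[0] % 2 == 0 or fp.shape[1] % 2 == 0:
            raise InputError("footprint must be a 2-D odd-sized boolean grid")
        if not fp[fp.shape[0] // 2, fp.shape[1] // 2]:
            raise InputError("footprint must contain its center")
        if self.iterations < 1:
            raise InputError("iterations must be >= 1")
        object.__setattr__(self, "footprint", fp)

    @classmethod
    def square(cls, size: int = 3, iterations: int = 1) -> "StructuringElement":
        return cls(_square_footprint(size), iterations)


@dataclass(frozen=True)
class MarkerSet:
    """Sure-foreground / sure-background / unknown partition of an image."""

    sure_fg: np.ndarray
    sure_bg: np.ndarray
    unknown: np.ndarray


def to_gray(image: np.ndarray) -> np.ndarray:
    """ITU-R 601 luminance, ``0.299 R + 0.587 G + 0.114 B``, range [0, 1]."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 3 or image.shape[2] != 3:
        raise InputError(f"expected an HxWx3 image, got shape {image.shape}")
    return image @ np.array([0.299, 0.587, 0.114])


def binary_threshold(
    gray: np.ndarray, method: str = "otsu", level: float | None = None
) -> np.ndarray:
    """Dark-is-foreground binary threshold, ``mask = gray < t``.

    Nuclei are hematoxylin-dark, so pixels *below* the threshold are
    foreground.  ``otsu`` maximizes between-class variance on a 256-bin
    histogram; ``fixed`` uses the supplied ``level``.  A constant image
    under Otsu yields an all-false mask with a warning.
    """
    gray = np.asarray(gray, dtype=float)
    if method == "fixed":
        if level is None:
            raise InputError("fixed thresholding requires a level")
        return gray < level
    if method != "otsu":
        raise InputError(f"unknown threshold method {method!r}")
    if np.ptp(gray) == 0:
        warnings.warn("constant image: Otsu threshold undefined, returning "
                      "an empty mask", stacklevel=2)
        return np.zeros(gray.shape, dtype=bool)
    t = threshold_otsu(gray, nbins=256)
    return gray < t


def morphology(
    mask: np.ndarray, op: str, se: StructuringElement | None = None
) -> np.ndarray:
    """Binary erosion / dilation / opening / closing.

    Out-of-frame pixels count as background for both erosion and dilation,
    so border foreground can be eroded away and dilation never imports
    foreground from outside the frame.
    """
    mask = np.asarray(mask, dtype=bool)
    se = se or StructuringElement()
    fp, n = se.footprint, se.iterations

    def erode(m):
        return ndi.binary_erosion(m, structure=fp, iterations=n, border_value=0)

    def dilate(m):
        return ndi.binary_dilation(m, structure=fp, iterations=n, border_value=0)

    if op == "erode":
        return erode(mask)
    if op == "dilate":
        return dilate(mask)
    if op == "open":
        return dilate(erode(mask))
    if op == "close":
        return erode(dilate(mask))
    raise InputError(f"unknown morphology op {op!r}")


def clear_borders(mask: np.ndarray) -> np.ndarray:
    """Remove every 8-connected foreground component touching an image edge."""
    mask = np.asarray(mask, dtype=bool)
    labels, _ = ndi.label(mask, structure=STRUCTURE_8)
    border = np.zeros_like(mask)
    border[0, :] = border[-1, :] = True
    border[:, 0] = border[:, -1] = True
    touching = np.unique(labels[border & mask])
    return mask & ~np.isin(labels, touching[touching > 0])


def distance_transform(mask: np.ndarray) -> np.ndarray:
    """Exact Euclidean distance from each foreground pixel to the background.

    Zero on background pixels.  An all-true mask has no background; a
    virtual background ring just outside the frame is assumed so the result
    stays finite (distance to the nearest border + 1).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.all():
        padded = np.pad(mask, 1, mode="constant", constant_values=False)
        return ndi.distance_transform_edt(padded)[1:-1, 1:-1]
    return ndi.distance_transform_edt(mask)


def extract_markers(
    mask: np.ndarray,
    dist: np.ndarray,
    fg_fraction: float = 0.5,
    bg_se: StructuringElement | None = None,
) -> MarkerSet:
    """Sure-foreground / sure-background / unknown partition.

    ``sure_fg`` keeps distance-transform values above ``fg_fraction`` of
    the maximum within each 8-connected component (the cores of nuclei; a
    per-component reference keeps small nuclei represented next to large
    ones), ``sure_bg`` is the complement of the dilated mask, and
    ``unknown`` is the dilated mask minus the sure foreground.  An empty
    mask gives an all-empty marker set.
    """
    if not 0 < fg_fraction < 1:
        raise InputError(f"fg_fraction must be in (0, 1), got {fg_fraction}")
    mask = np.asarray(mask, dtype=bool)
    dist = np.asarray(dist, dtype=float)
    if mask.shape != dist.shape:
        raise InputError("mask and distance field shapes differ")
    bg_se = bg_se or StructuringElement.square(3, iterations=3)
    if not mask.any():
        empty = np.zeros(mask.shape, dtype=bool)
        return MarkerSet(empty, np.ones_like(empty), empty.copy())
    comps, k = ndi.label(mask, structure=STRUCTURE_8)
    peak = ndi.maximum(dist, labels=comps, index=np.arange(1, k + 1))
    peak_of = np.concatenate([[np.inf], np.atleast_1d(peak)])[comps]
    sure_fg = dist > fg_fraction * peak_of
    dilated = morphology(mask, "dilate", bg_se)
    sure_bg = ~dilated
    unknown = dilated & ~sure_fg
    return MarkerSet(sure_fg, sure_bg, unknown)
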