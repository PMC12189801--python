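"""Connected-component analysis and Laplacian-of-Gaussian blob detection.

Connected components group foreground pixels into labeled binary masks;
each component is intersected with the sure-foreground markers so that a
single merged component covering several overlapping nuclei still yields
one seed per nucleus.  The LoG kernel

    LoG(x, y) = ((x^2 + y^2 - 2 sigma^2) / sigma^4) * exp(-(x^2 + y^2) / (2 sigma^2))

is an optional multi-scale detector of dark/bright blobs whose responses
are sigma^2-normalized for cross-scale comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.signal import fftconvolve

from .enhance import MarkerSet, distance_transform
from .errors import ConfigError, InputError

__all__ = [
    "LogKernel",
    "ComponentStats",
    "log_kernel",
    "detect_blobs",
    "label_components",
    "component_masks",
    "seed_markers_from_components",
]


@dataclass(frozen=True)
class LogKernel:
    sigma: float
    radius: int
    weights: np.ndarray


@dataclass(frozen=True)
class ComponentStats:
    label: int
    area: int
    centroid: tuple[float, float]
    bbox: tuple[int, int, int, int]  # half-open (r0, c0, r1, c1)
    mean_intensity: float


def log_kernel(sigma: float, radius: int) -> LogKernel:
    """Discrete LoG kernel of half-size ``radius``.

    The center weight is ``-2 / sigma^2`` and the kernel changes sign on the
    circle ``x^2 + y^2 = 2 sigma^2``; at radius >= 6 sigma the weights sum
    to (numerically) zero.
    """
    if sigma <= 0:
        raise ConfigError(f"sigma must be > 0, got {sigma}")
    if radius < int(np.ceil(3 * sigma)):
        raise ConfigError(
            f"radius {radius} too small for sigma {sigma}; need >= ceil(3 sigma)"
        )
    coords = np.arange(-radius, radius + 1, dtype=float)
    x, y = np.meshgrid(coords, coords, indexing="ij")
    r2 = x**2 + y**2
    weights = (r2 - 2 * sigma**2) / sigma**4 * np.exp(-r2 / (2 * sigma**2))
    return LogKernel(sigma=float(sigma), radius=int(radius), weights=weights)


def detect_blobs(
    gray: np.ndarray,
    sigmas: list[float],
    polarity: str = "dark",
    threshold: float = 0.05,
) -> list[tuple[int, int, float, float]]:
    """Multi-scale LoG blob detection.

    Keeps local extrema of the sigma^2-normalized scale space
    ``sigma^2 (Laplacian of Gaussian * I)`` over (row, col, sigma) whose
    magnitude exceeds ``threshold``.  The kernel from :func:`log_kernel`
    carries a ``1/sigma^4`` prefactor instead of the Gaussian's
    ``1/(2 pi sigma^2) 1/sigma^2``, so its raw convolution already equals
    ``2 pi sigma^2 (LoG * I)``: dividing by ``2 pi`` yields the normalized
    response directly.  Dark blobs produce positive responses, bright
    blobs negative ones.  Returns ``(row, col, sigma, response)`` tuples
    sorted by position.
    """
    gray = np.asarray(gray, dtype=float)
    if len(sigmas) == 0:
        raise InputError("sigmas must be nonempty")
    if any(b <= a for a, b in zip(sigmas, sigmas[1:])):
        raise InputError("sigmas must be strictly increasing")
    if polarity not in ("dark", "bright"):
        raise InputError(f"polarity must be 'dark' or 'bright', got {polarity!r}")

    stack = np.empty((len(sigmas),) + gray.shape)
    for i, sigma in enumerate(sigmas):
        k = log_kernel(sigma, int(np.ceil(3 * sigma)))
        padded = np.pad(gray, k.radius, mode="edge")
        stack[i] = fftconvolve(padded, k.weights, mode="valid") / (2 * np.pi)
    if polarity == "bright":
        stack = -stack

    footprint = np.ones((3, 3, 3), dtype=bool)
    local_max = ndi.maximum_filter(stack, footprint=footprint, mode="nearest")
    peaks = (stack == local_max) & (stack > threshold)
    out = []
    for i, r, c in zip(*np.nonzero(peaks)):
        resp = stack[i, r, c]
        out.append((int(r), int(c), float(sigmas[i]), float(resp)))
    out.sort(key=lambda t: (t[0], t[1], t[2]))
    return out


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 4:
        return np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
    if connectivity == 8:
        return np.ones((3, 3), dtype=bool)
    raise InputError(f"connectivity must be 4 or 8, got {connectivity}")


def label_components(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Label maximal connected foreground sets 1..K.

    Labels are assigned in row-major order of each component's first pixel,
    so the numbering is deterministic.
    """
    mask = np.asarray(mask, dtype=bool)
    labels, k = ndi.label(mask, structure=_structure(connectivity))
    if k == 0:
        return labels
    # renumber by first occurrence in row-major scan order
    flat = labels.ravel()
    first = np.full(k + 1, flat.size, dtype=np.int64)
    nz = np.nonzero(flat)[0]
    # reversed so earlier indices overwrite later ones
    first[flat[nz[::-1]]] = nz[::-1]
    order = np.argsort(first[1:], kind="stable")
    remap = np.zeros(k + 1, dtype=labels.dtype)
    remap[1 + order] = np.arange(1, k + 1)
    return remap[labels]


def component_masks(
    labels: np.ndarray,
    min_area: int = 20,
    intensity: np.ndarray | None = None,
) -> list[tuple[np.ndarray, ComponentStats]]:
    """One boolean mask + stats per component with area >= ``min_area``.

    ``mean_intensity`` is computed over ``intensity`` when given, else NaN.
    Components are returned in label order.
    """
    labels = np.asarray(labels)
    out: list[tuple[np.ndarray, ComponentStats]] = []
    for lbl in range(1, int(labels.max()) + 1):
        mask = labels == lbl
        area = int(mask.sum())
        if area == 0 or area < min_area:
            continue
        rows, cols = np.nonzero(mask)
        stats = ComponentStats(
            label=lbl,
            area=area,
            centroid=(float(rows.mean()), float(cols.mean())),
            bbox=(int(rows.min()), int(cols.min()),
                  int(rows.max()) + 1, int(cols.max()) + 1),
            mean_intensity=(
                float(np.asarray(intensity, dtype=float)[mask].mean())
                if intensity is not None else float("nan")
            ),
        )
        out.append((mask, stats))
    return out


def split_seeds_by_distance_peaks(
    seeds: np.ndarray,
    dist: np.ndarray,
    min_distance: int = 8,
) -> np.ndarray:
    """Split seed blobs that cover several nuclei.

    Two nuclei overlapping deeply enough share one sure-foreground blob
    (the neck of the merged distance field stays above the marker
    threshold), yet each nucleus keeps its own local distance maximum at
    its core with a saddle in between.  Every seed blob containing two or
    more distance peaks at least ``min_distance`` apart is therefore
    partitioned among the peaks by nearest-peak assignment; blobs with a
    single peak are returned unchanged.  Labels are renumbered
    deterministically in row-major order of each seed's first pixel.
    """
    from skimage.feature import peak_local_max

    seeds = np.asarray(seeds)
    dist = np.asarray(dist, dtype=float)
    out = np.zeros_like(seeds)
    next_label = 1
    for lbl in range(1, int(seeds.max()) + 1):
        blob = seeds == lbl
        if not blob.any():
            continue
        peaks = peak_local_max(
            np.where(blob, dist, 0.0),
            min_distance=min_distance,
            exclude_border=False,
        )
        if len(peaks) <= 1:
            out[blob] = next_label
            next_label += 1
            continue
        rows, cols = np.nonzero(blob)
        d2 = (
            (rows[:, None] - peaks[:, 0]) ** 2
            + (cols[:, None] - peaks[:, 1]) ** 2
        )
        nearest = np.argmin(d2, axis=1)
        for p in range(len(peaks)):
            sel = nearest == p
            if sel.any():
                out[rows[sel], cols[sel]] = next_label
                next_label += 1
    return _renumber(out)


def _renumber(labels: np.ndarray) -> np.ndarray:
    """Renumber positive labels in row-major order of first occurrence."""
    labels = np.asarray(labels)
    flat = labels.ravel()
    seen: dict[int, int] = {}
    remap = np.zeros(int(labels.max()) + 1, dtype=labels.dtype)
    for v in flat[flat > 0]:
        v = int(v)
        if v not in seen:
            seen[v] = len(seen) + 1
            remap[v] = seen[v]
    return remap[labels]


def seed_markers_from_components(
    masks: list[np.ndarray], markers: MarkerSet
) -> np.ndarray:
    """Build disjoint seed labels by intersecting components with sure_fg.

    A component containing m >= 2 disjoint sure-foreground blobs contributes
    m separate seeds — this is how a single merged component covering
    overlapping nuclei is split.  A component with no sure-foreground pixels
    falls back to a single-pixel seed at its distance-transform peak (with a
    warning) so no nucleus is dropped.
    """
    if not masks:
        return np.zeros(markers.sure_fg.shape, dtype=np.int32)
    shape = np.asarray(masks[0]).shape
    if shape != markers.sure_fg.shape:
        raise InputError("component masks and markers must share shape")
    seeds = np.zeros(shape, dtype=np.int32)
    next_label = 1
    for mask in masks:
        mask = np.asarray(mask, dtype=bool)
        inter = mask & markers.sure_fg
        if inter.any():
            blobs, k = ndi.label(inter, structure=_structure(8))
            for b in range(1, k + 1):
                seeds[blobs == b] = next_label
                next_label += 1
        else:
            warnings.warn(
                "component has no sure-foreground overlap; falling back to "
                "its distance-transform peak as a 1-pixel seed",
                stacklevel=2,
            )
            dist = distance_transform(mask)
            peak = np.unravel_index(int(np.argmax(dist)), shape)
            seeds[peak] = next_label
            next_label += 1
    return seeds
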