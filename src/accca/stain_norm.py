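"""Macenko stain-vector estimation and H&E stain separation.

Hematoxylin and eosin absorb light multiplicatively, so pixel intensities are
converted to optical density (base-10 absorbance), where the two stains mix
additively: ``OD ≈ M @ c`` with ``M`` a 3x2 matrix of unit stain color
vectors and ``c`` the per-pixel stain concentrations.  The stain vectors are
estimated from the data itself: near-transparent pixels are discarded, an SVD
of the remaining OD tuples gives the best-fit plane, and robust percentile
extremes of the projection angles recover the two stain directions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import yaml

from .errors import DegenerateStainError, InputError, NoTissueError

__all__ = [
    "NormalizationParams",
    "StainSeparation",
    "rgb_to_od",
    "od_to_rgb",
    "tissue_pixels",
    "estimate_stain_matrix",
    "compute_concentrations",
    "separate_stains",
    "stain_angle_deg",
    "save_stain_reference",
    "load_stain_reference",
]


@dataclass(frozen=True)
class NormalizationParams:
    """Parameters of Macenko stain estimation.

    alpha : robust percentile (percent) for the angle extremes; the stain
        directions are taken at the ``alpha`` and ``100 - alpha`` percentiles
        of the projection-angle distribution.
    beta : OD transparency threshold; a pixel enters the estimation only if
        at least one channel's OD exceeds ``beta``.
    epsilon : intensity floor applied before the logarithm, avoids log(0).
    reference_stains : optional 3x2 reference stain matrix used to re-render
        normalized output in a common color frame.
    reference_max_conc : optional length-2 robust maximum concentrations of
        the reference image, used to rescale concentrations.
    """

    alpha: float = 1.0
    beta: float = 0.15
    epsilon: float = 1e-6
    reference_stains: np.ndarray | None = None
    reference_max_conc: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 50:
            raise InputError(f"alpha must be in (0, 50), got {self.alpha}")
        if not self.beta > 0:
            raise InputError(f"beta must be > 0, got {self.beta}")
        if not 0 < self.epsilon < 1:
            raise InputError(f"epsilon must be in (0, 1), got {self.epsilon}")
        if self.reference_stains is not None:
            ref = np.asarray(self.reference_stains, dtype=float)
            validate_stain_matrix(ref)
            object.__setattr__(self, "reference_stains", ref)
        if self.reference_max_conc is not None:
            mc = np.asarray(self.reference_max_conc, dtype=float).reshape(2)
            if not np.all(mc > 0):
                raise InputError("reference_max_conc must be positive")
            object.__setattr__(self, "reference_max_conc", mc)


class StainSeparation(NamedTuple):
    """Output of :func:`separate_stains`."""

    normalized_he: np.ndarray
    h_only: np.ndarray
    e_only: np.ndarray
    stains: np.ndarray
    conc: np.ndarray
    max_conc: np.ndarray


def validate_rgb(image: np.ndarray) -> np.ndarray:
    """Check an H x W x 3 RGB grid with values in [0, 1]."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 3 or image.shape[2] != 3:
        raise InputError(f"expected an HxWx3 RGB image, got shape {image.shape}")
    if image.shape[0] < 1 or image.shape[1] < 1:
        raise InputError("image must have at least one pixel")
    if not np.all(np.isfinite(image)):
        raise InputError("image contains non-finite values")
    if image.min() < 0 or image.max() > 1:
        raise InputError("image values must lie in [0, 1]")
    return image


def validate_stain_matrix(stains: np.ndarray) -> np.ndarray:
    stains = np.asarray(stains, dtype=float)
    if stains.shape != (3, 2):
        raise InputError(f"stain matrix must be 3x2, got {stains.shape}")
    norms = np.linalg.norm(stains, axis=0)
    if not np.allclose(norms, 1.0, atol=1e-6):
        raise InputError("stain matrix columns must be unit vectors")
    if stains.min() < -1e-12:
        raise InputError("stain matrix entries must be nonnegative")
    cosang = float(np.clip(stains[:, 0] @ stains[:, 1], -1.0, 1.0))
    if np.degrees(np.arccos(cosang)) < 1.0:
        raise DegenerateStainError("stain vectors are (nearly) collinear")
    return stains


def rgb_to_od(image: np.ndarray, epsilon: float = 1e-6) -> np.ndarray:
    """Convert intensities in [0, 1] to optical density, ``-log10(I)``.

    Intensities are floored at ``epsilon`` before the logarithm so fully
    opaque pixels map to the finite OD ``-log10(epsilon)``.
    """
    image = validate_rgb(image)
    if not 0 < epsilon < 1:
        raise InputError(f"epsilon must be in (0, 1), got {epsilon}")
    return -np.log10(np.clip(image, epsilon, 1.0))


def od_to_rgb(od: np.ndarray) -> np.ndarray:
    """Invert :func:`rgb_to_od`: intensity ``10**(-OD)``, clamped to [0, 1]."""
    od = np.asarray(od, dtype=float)
    if not np.all(np.isfinite(od)):
        raise InputError("OD contains non-finite values")
    if od.min() < 0:
        raise InputError("OD values must be nonnegative")
    return np.clip(10.0 ** (-od), 0.0, 1.0)


def tissue_pixels(od: np.ndarray, beta: float = 0.15) -> np.ndarray:
    """Select the OD tuples that enter stain estimation.

    A pixel counts as tissue when any channel's OD exceeds ``beta``;
    near-transparent background (all channels at low absorbance) is
    discarded.  Returns an N x 3 array in row-major pixel order.
    """
    if not beta > 0:
        raise InputError(f"beta must be > 0, got {beta}")
    od = np.asarray(od, dtype=float)
    flat = od.reshape(-1, 3)
    keep = (flat > beta).any(axis=1)
    tuples = flat[keep]
    if tuples.shape[0] == 0:
        raise NoTissueError(f"no pixel exceeds OD {beta} in any channel")
    return tuples


def estimate_stain_matrix(
    od: np.ndarray, params: NormalizationParams | None = None
) -> np.ndarray:
    """Estimate the 3x2 H&E stain matrix from an OD image (Macenko).

    Steps: keep tissue pixels (``beta`` filter), SVD for the dominant OD
    plane, project tuples into the plane, take the ``alpha``/``100-alpha``
    percentile extremes of the projection angles, map the two extreme
    directions back to 3-D, and orient/normalize them.  The column with the
    larger blue-channel absorbance is assigned to hematoxylin.
    """
    params = params or NormalizationParams()
    tuples = tissue_pixels(od, params.beta)
    if tuples.shape[0] < 2:
        raise DegenerateStainError("need at least two tissue pixels")

    # plane of the two largest singular directions
    _, s, vt = np.linalg.svd(tuples, full_matrices=False)
    if s[1] <= max(1e-12, 1e-8 * s[0]):
        raise DegenerateStainError("tissue OD tuples are collinear (rank < 2)")
    basis = vt[:2]
    # deterministic sign: each basis vector has nonnegative entry sum
    for i in range(2):
        if basis[i].sum() < 0:
            basis[i] = -basis[i]

    proj = tuples @ basis.T
    angles = np.arctan2(proj[:, 1], proj[:, 0])
    lo, hi = np.percentile(angles, [params.alpha, 100.0 - params.alpha],
                           method="linear")

    def _direction(angle: float) -> np.ndarray:
        v = np.cos(angle) * basis[0] + np.sin(angle) * basis[1]
        if v.sum() < 0:
            v = -v
        v = np.clip(v, 0.0, None)
        n = np.linalg.norm(v)
        if n == 0:
            raise DegenerateStainError("degenerate extreme direction")
        return v / n

    v_min, v_max = _direction(lo), _direction(hi)
    stains = np.column_stack([v_min, v_max])
    # hematoxylin absorbs more blue than eosin; swap if needed
    if stains[2, 1] > stains[2, 0]:
        stains = stains[:, ::-1]
    cosang = float(np.clip(stains[:, 0] @ stains[:, 1], -1.0, 1.0))
    if np.degrees(np.arccos(cosang)) < 1.0:
        raise DegenerateStainError("estimated stain vectors are collinear")
    return stains


def compute_concentrations(od: np.ndarray, stains: np.ndarray) -> np.ndarray:
    """Per-pixel least-squares stain concentrations, clamped to >= 0.

    Solves ``min_c || M c - od ||_2`` for every pixel and clips negatives;
    exact when the OD lies in the nonnegative span of the stain columns.
    """
    stains = validate_stain_matrix(stains)
    od = np.asarray(od, dtype=float)
    shape = od.shape[:-1]
    pinv = np.linalg.pinv(stains)
    conc = od.reshape(-1, 3) @ pinv.T
    return np.clip(conc, 0.0, None).reshape(*shape, 2)


def separate_stains(
    image: np.ndarray, params: NormalizationParams | None = None
) -> StainSeparation:
    """Estimate stains and render normalized H&E, H-only and E-only images.

    Per-stain robust maximum concentrations are taken at the 99th
    percentile.  When the params carry a reference stain matrix and
    reference maxima, concentrations are rescaled to the reference and the
    output is rendered with the reference colors; otherwise the estimated
    matrix is used and concentrations are left unscaled.
    """
    params = params or NormalizationParams()
    image = validate_rgb(image)
    od = rgb_to_od(image, params.epsilon)
    stains = estimate_stain_matrix(od, params)
    conc = compute_concentrations(od, stains)

    flat = conc.reshape(-1, 2)
    max_conc = np.percentile(flat, 99.0, axis=0, method="linear")
    max_conc = np.maximum(max_conc, 1e-8)

    if params.reference_max_conc is not None:
        scale = params.reference_max_conc / max_conc
    else:
        scale = np.ones(2)
    render_stains = (
        params.reference_stains if params.reference_stains is not None else stains
    )
    scaled = flat * scale

    he_od = scaled @ render_stains.T
    h_od = np.outer(scaled[:, 0], render_stains[:, 0])
    e_od = np.outer(scaled[:, 1], render_stains[:, 1])
    shape = image.shape
    normalized_he = od_to_rgb(he_od.reshape(shape))
    h_only = od_to_rgb(h_od.reshape(shape))
    e_only = od_to_rgb(e_od.reshape(shape))
    return StainSeparation(normalized_he, h_only, e_only, stains, conc, max_conc)


def stain_angle_deg(a: np.ndarray, b: np.ndarray) -> float:
    """Angle in degrees between two stain color vectors."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    cosang = float(
        np.clip(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)), -1.0, 1.0)
    )
    return float(np.degrees(np.arccos(cosang)))


def save_stain_reference(path, stains: np.ndarray, max_conc: np.ndarray) -> None:
    """Write a stain matrix + robust maxima as a small YAML sidecar."""
    stains = validate_stain_matrix(stains)
    payload = {
        "stain_matrix": [[float(x) for x in row] for row in stains],
        "max_concentration": [float(x) for x in np.asarray(max_conc).reshape(2)],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh)


def load_stain_reference(path) -> tuple[np.ndarray, np.ndarray]:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    stains = validate_stain_matrix(np.asarray(payload["stain_matrix"], dtype=float))
    max_conc = np.asarray(payload["max_concentration"], dtype=float).reshape(2)
    return stains, max_conc
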