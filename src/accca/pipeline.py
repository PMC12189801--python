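"""End-to-end orchestration: augmentation, splitting, and the full pipeline.

The pipeline chains the stages in order: stain separation -> grayscale of
the hematoxylin-only image -> binary threshold -> opening + border clearing
-> Euclidean distance transform -> sure-fg/bg markers -> connected
components -> per-nucleus seeds -> geodesic active contours -> contour
extraction, with per-stage structured logging and optional evaluation
against a ground-truth label map.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage as ndi

from . import io as accca_io
from .components import (
    component_masks,
    label_components,
    seed_markers_from_components,
    split_seeds_by_distance_peaks,
)
from .enhance import (
    MarkerSet,
    StructuringElement,
    binary_threshold,
    clear_borders,
    distance_transform,
    extract_markers,
    morphology,
    to_gray,
)
from .errors import AcccaError, ConfigError, NoTissueError
from .gac import ContourSet, GacParams, run_gac
from .stain_norm import NormalizationParams, separate_stains, validate_rgb
from .synth import SegmentationMetrics, evaluate

logger = logging.getLogger("accca")

__all__ = [
    "EnhanceParams",
    "PipelineConfig",
    "PipelineResult",
    "StageRecord",
    "augment",
    "split",
    "run",
    "save_result",
]


@dataclass(frozen=True)
class EnhanceParams:
    """Threshold / morphology / marker parameters."""

    threshold_method: str = "otsu"
    threshold_level: float | None = None
    se_size: int = 3
    open_iterations: int = 2
    bg_dilate_iterations: int = 3
    fg_fraction: float = 0.5
    min_area: int = 20
    clear_border: bool = True
    split_seed_blobs: bool = True
    peak_min_distance: int = 8


@dataclass(frozen=True)
class PipelineConfig:
    normalization: NormalizationParams = field(default_factory=NormalizationParams)
    enhance: EnhanceParams = field(default_factory=EnhanceParams)
    gac: GacParams = field(default_factory=GacParams)
    rotations: tuple = (0.0,)
    shifts: tuple = ((0.0, 0.0),)
    scales: tuple = (1.0,)
    train_fraction: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ConfigError("train_fraction must be in (0, 1)")
        if any(s <= 0 for s in self.scales):
            raise ConfigError("scales must be positive")

    def to_yaml(self, path) -> None:
        payload = dataclasses.asdict(self)
        # frozen numpy fields are not YAML-native
        norm = payload["normalization"]
        for key in ("reference_stains", "reference_max_conc"):
            if norm[key] is not None:
                norm[key] = np.asarray(norm[key]).tolist()
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        norm = payload.pop("normalization", {})
        for key in ("reference_stains", "reference_max_conc"):
            if norm.get(key) is not None:
                norm[key] = np.asarray(norm[key], dtype=float)
        enh = payload.pop("enhance", {})
        gac_d = payload.pop("gac", {})
        payload["rotations"] = tuple(payload.get("rotations", (0.0,)))
        payload["shifts"] = tuple(
            tuple(s) for s in payload.get("shifts", ((0.0, 0.0),))
        )
        payload["scales"] = tuple(payload.get("scales", (1.0,)))
        return cls(
            normalization=NormalizationParams(**norm),
            enhance=EnhanceParams(**enh),
            gac=GacParams(**gac_d),
            **payload,
        )


@dataclass(frozen=True)
class StageRecord:
    stage: str
    duration_s: float
    summary: str


@dataclass
class PipelineResult:
    normalized_he: np.ndarray | None = None
    h_only: np.ndarray | None = None
    e_only: np.ndarray | None = None
    stains: np.ndarray | None = None
    gray: np.ndarray | None = None
    mask: np.ndarray | None = None
    cleaned_mask: np.ndarray | None = None
    dist: np.ndarray | None = None
    markers: MarkerSet | None = None
    components: np.ndarray | None = None
    component_stats: list = field(default_factory=list)
    seeds: np.ndarray | None = None
    labels: np.ndarray | None = None
    contours: ContourSet = field(default_factory=lambda: ContourSet([]))
    metrics: SegmentationMetrics | None = None
    log: list = field(default_factory=list)


def augment(image: np.ndarray, config: PipelineConfig) -> list[np.ndarray]:
    """Deterministic augmentation grid: rotations x shifts x scales.

    Each transform is applied about the image center with reflection
    padding and bilinear interpolation; shifts are fractions of the image
    height/width.  The output count is the product of the three lists.
    """
    image = validate_rgb(image)
    if any(s <= 0 for s in config.scales):
        raise ConfigError("scales must be positive")
    h, w = image.shape[:2]
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    out = []
    for angle in config.rotations:
        theta = np.deg2rad(angle)
        rot_inv = np.array(
            [[np.cos(theta), np.sin(theta)], [-np.sin(theta), np.cos(theta)]]
        )
        for shift in config.shifts:
            t = np.array([shift[0] * h, shift[1] * w])
            for scale in config.scales:
                matrix = rot_inv / scale
                offset = center - matrix @ (center + t)
                channels = [
                    ndi.affine_transform(
                        image[..., ch], matrix, offset=offset,
                        order=1, mode="reflect",
                    )
                    for ch in range(3)
                ]
                out.append(np.clip(np.stack(channels, axis=-1), 0.0, 1.0))
    return out


def split(n: int, train_fraction: float = 0.75) -> tuple[int, int]:
    """Deterministic train/test counts: floor on the training side."""
    if n < 0:
        raise ConfigError("n must be >= 0")
    if not 0 < train_fraction < 1:
        raise ConfigError("train_fraction must be in (0, 1)")
    n_train = int(np.floor(n * train_fraction))
    return n_train, n - n_train


def _empty_result(shape, log) -> PipelineResult:
    return PipelineResult(
        mask=np.zeros(shape, dtype=bool),
        labels=np.zeros(shape, dtype=np.int32),
        contours=ContourSet([]),
        log=log,
    )


def run(
    image: np.ndarray,
    config: PipelineConfig | None = None,
    truth: np.ndarray | None = None,
) -> PipelineResult:
    """Execute the full segmentation pipeline on one RGB image.

    A no-tissue input (for example a blank white image) yields an
    empty-but-valid result instead of an error.  Stage failures propagate
    with the stage name attached.
    """
    config = config or PipelineConfig()
    image = validate_rgb(image)
    result = PipelineResult()
    log: list[StageRecord] = []
    result.log = log

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            value = fn()
        except AcccaError as exc:
            raise type(exc)(f"[stage {name}] {exc}") from exc
        dt = time.perf_counter() - t0
        rec = StageRecord(stage=name, duration_s=dt, summary=_summary(value))
        log.append(rec)
        logger.info("stage %-12s %.3fs %s", name, dt, rec.summary)
        return value

    try:
        sep = stage("normalize", lambda: separate_stains(image, config.normalization))
    except NoTissueError:
        logger.warning("no tissue found; returning empty result")
        return _empty_result(image.shape[:2], log)
    result.normalized_he, result.h_only, result.e_only = sep[:3]
    result.stains = sep.stains

    result.gray = stage("gray", lambda: to_gray(sep.h_only))
    enh = config.enhance
    result.mask = stage(
        "threshold",
        lambda: binary_threshold(result.gray, enh.threshold_method,
                                 enh.threshold_level),
    )
    se = StructuringElement.square(enh.se_size, enh.open_iterations)

    def _clean():
        m = morphology(result.mask, "open", se)
        return clear_borders(m) if enh.clear_border else m

    result.cleaned_mask = stage("morphology", _clean)
    result.dist = stage("distance", lambda: distance_transform(result.cleaned_mask))
    bg_se = StructuringElement.square(enh.se_size, enh.bg_dilate_iterations)
    result.markers = stage(
        "markers",
        lambda: extract_markers(result.cleaned_mask, result.dist,
                                enh.fg_fraction, bg_se),
    )
    result.components = stage(
        "components", lambda: label_components(result.cleaned_mask, 8)
    )
    comp = stage(
        "component_masks",
        lambda: component_masks(result.components, enh.min_area, result.gray),
    )
    result.component_stats = [s for _, s in comp]
    def _seeds():
        raw = seed_markers_from_components([m for m, _ in comp], result.markers)
        if enh.split_seed_blobs:
            raw = split_seeds_by_distance_peaks(raw, result.dist,
                                                enh.peak_min_distance)
        return raw

    result.seeds = stage("seeds", _seeds)
    if not (result.seeds > 0).any():
        logger.warning("no seeds found; returning empty segmentation")
        result.labels = np.zeros(image.shape[:2], dtype=np.int32)
        result.contours = ContourSet([])
    else:
        labels, contours = stage(
            "gac", lambda: run_gac(result.gray, result.seeds, config.gac)
        )
        result.labels = labels
        result.contours = contours

    if truth is not None:
        result.metrics = stage("evaluate", lambda: evaluate(result.labels, truth))
    return result


def _summary(value) -> str:
    if isinstance(value, np.ndarray):
        if value.dtype == bool:
            return f"mask {value.shape}, {int(value.sum())} fg px"
        return f"array {value.shape} dtype={value.dtype}"
    if isinstance(value, tuple) and len(value) == 2 and isinstance(
        value[0], np.ndarray
    ):
        k = len(np.unique(value[0][value[0] > 0]))
        return f"{k} labels, {len(value[1])} contours"
    if isinstance(value, MarkerSet):
        return f"sure_fg {int(value.sure_fg.sum())} px"
    if isinstance(value, SegmentationMetrics):
        return f"dice={value.dice:.3f} count_err={value.count_error}"
    if isinstance(value, list):
        return f"{len(value)} items"
    return type(value).__name__


def save_result(result: PipelineResult, out_dir) -> None:
    """Persist every available stage artifact under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if result.normalized_he is not None:
        accca_io.write_image(out / "normalized_he.png", result.normalized_he)
        accca_io.write_image(out / "h_only.png", result.h_only)
        accca_io.write_image(out / "e_only.png", result.e_only)
    if result.mask is not None:
        accca_io.write_mask(out / "mask.png", result.mask)
    if result.cleaned_mask is not None:
        accca_io.write_mask(out / "cleaned_mask.png", result.cleaned_mask)
    if result.dist is not None:
        accca_io.write_float_field(out / "distance.tif", result.dist)
    if result.markers is not None:
        accca_io.write_mask(out / "sure_fg.png", result.markers.sure_fg)
        accca_io.write_mask(out / "sure_bg.png", result.markers.sure_bg)
        accca_io.write_mask(out / "unknown.png", result.markers.unknown)
    if result.components is not None:
        accca_io.write_labelmap(out / "components.tif", result.components)
        accca_io.components_to_csv(out / "components.csv", result.component_stats)
    if result.seeds is not None:
        accca_io.write_labelmap(out / "seeds.tif", result.seeds)
    if result.labels is not None:
        accca_io.write_labelmap(out / "labels.tif", result.labels)
    accca_io.contours_to_csv(out / "contours.csv", result.contours)
    if result.normalized_he is not None:
        overlay = accca_io.draw_contour_overlay(
            result.normalized_he, result.contours
        )
        accca_io.write_image(out / "overlay.png", overlay)
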