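"""Reading and writing images, label maps and tables."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .errors import InputError


def read_image(path) -> np.ndarray:
    """Read a PNG/TIFF image as float RGB in [0, 1].

    8-bit channels are divided by 255, 16-bit by 65535.  Grayscale input is
    replicated to three channels; an alpha channel is dropped.
    """
    arr = iio.imread(Path(path))
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    if arr.shape[-1] != 3:
        raise InputError(f"cannot interpret image with shape {arr.shape}")
    if arr.dtype == np.uint8:
        return arr.astype(float) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(float) / 65535.0
    arr = arr.astype(float)
    if arr.max() > 1.0:
        raise InputError("float image must already be scaled to [0, 1]")
    return arr


def write_image(path, image: np.ndarray) -> None:
    """Write a float image in [0, 1] as 8-bit PNG/TIFF."""
    data = (np.clip(np.asarray(image, dtype=float), 0, 1) * 255).round()
    iio.imwrite(Path(path), data.astype(np.uint8))


def write_mask(path, mask: np.ndarray) -> None:
    """Write a boolean mask as 0/255 8-bit PNG."""
    iio.imwrite(Path(path), np.where(np.asarray(mask, dtype=bool), 255, 0)
                .astype(np.uint8))


def write_labelmap(path, labels: np.ndarray) -> None:
    """Write an integer label map as 16-bit PNG or TIFF (by extension)."""
    path = Path(path)
    data = np.asarray(labels)
    if data.min() < 0 or data.max() > np.iinfo(np.uint16).max:
        raise InputError("labels out of uint16 range")
    data = data.astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
    else:
        iio.imwrite(path, data)


def read_labelmap(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return tifffile.imread(path).astype(np.int32)
    return iio.imread(path).astype(np.int32)


def write_float_field(path, field: np.ndarray) -> None:
    """Write a real-valued field (distance transform, level set) as float TIFF."""
    tifffile.imwrite(Path(path), np.asarray(field, dtype=np.float32))


def contours_to_csv(path, contours) -> None:
    """Write a ContourSet as (contour_id, vertex_index, row, col) CSV."""
    records = []
    for cid, chain in enumerate(contours):
        for vi, (r, c) in enumerate(np.asarray(chain)):
            records.append((cid, vi, float(r), float(c)))
    pd.DataFrame(
        records, columns=["contour_id", "vertex_index", "row", "col"]
    ).to_csv(path, index=False)


def components_to_csv(path, stats_list) -> None:
    """Write ComponentStats records as a CSV table."""
    rows = [
        {
            "label": s.label,
            "area": s.area,
            "centroid_r": s.centroid[0],
            "centroid_c": s.centroid[1],
            "bbox_r0": s.bbox[0],
            "bbox_c0": s.bbox[1],
            "bbox_r1": s.bbox[2],
            "bbox_c1": s.bbox[3],
            "mean_intensity": s.mean_intensity,
        }
        for s in stats_list
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def nuclei_to_csv(path, nuclei) -> None:
    rows = [
        {
            "center_r": n.center[0], "center_c": n.center[1],
            "axis_a": n.axes[0], "axis_b": n.axes[1],
            "angle": n.angle, "h_conc": n.h_conc, "e_conc": n.e_conc,
        }
        for n in nuclei
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def draw_contour_overlay(image: np.ndarray, contours,
                         color=(0.0, 1.0, 0.0)) -> np.ndarray:
    """Burn contour polylines into a copy of an RGB image."""
    out = np.asarray(image, dtype=float).copy()
    h, w = out.shape[:2]
    for chain in contours:
        pts = np.asarray(chain)
        rr = np.clip(np.round(pts[:, 0]).astype(int), 0, h - 1)
        cc = np.clip(np.round(pts[:, 1]).astype(int), 0, w - 1)
        out[rr, cc] = color
    return out
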