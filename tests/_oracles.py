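"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from the mathematical definition (per-pixel
scans, flood fill, exhaustive search) on purpose — none of it shares code
with the package.
"""

from __future__ import annotations

import numpy as np


def minkowski_erode(mask: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    """Per-pixel neighborhood scan; out-of-bounds counts as background."""
    h, w = mask.shape
    fh, fw = footprint.shape
    cr, cc = fh // 2, fw // 2
    out = np.zeros_like(mask, dtype=bool)
    for r in range(h):
        for c in range(w):
            ok = True
            for i in range(fh):
                for j in range(fw):
                    if not footprint[i, j]:
                        continue
                    rr, cc2 = r + i - cr, c + j - cc
                    if not (0 <= rr < h and 0 <= cc2 < w) or not mask[rr, cc2]:
                        ok = False
                        break
                if not ok:
                    break
            out[r, c] = ok
    return out


def minkowski_dilate(mask: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    h, w = mask.shape
    fh, fw = footprint.shape
    cr, cc = fh // 2, fw // 2
    out = np.zeros_like(mask, dtype=bool)
    for r in range(h):
        for c in range(w):
            hit = False
            for i in range(fh):
                for j in range(fw):
                    if not footprint[i, j]:
                        continue
                    rr, cc2 = r - (i - cr), c - (j - cc)
                    if 0 <= rr < h and 0 <= cc2 < w and mask[rr, cc2]:
                        hit = True
                        break
                if hit:
                    break
            out[r, c] = hit
    return out


def repeat(op, mask, footprint, iterations):
    out = mask
    for _ in range(iterations):
        out = op(out, footprint)
    return out


def flood_fill_labels(mask: np.ndarray, connectivity: int) -> np.ndarray:
    """Connected components by explicit BFS flood fill."""
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(i, j) for i in (-1, 0, 1) for j in (-1, 0, 1)
                if (i, j) != (0, 0)]
    h, w = mask.shape
    labels = np.zeros((h, w), dtype=int)
    current = 0
    for r in range(h):
        for c in range(w):
            if mask[r, c] and labels[r, c] == 0:
                current += 1
                queue = [(r, c)]
                labels[r, c] = current
                while queue:
                    rr, cc = queue.pop()
                    for dr, dc in nbrs:
                        r2, c2 = rr + dr, cc + dc
                        if (0 <= r2 < h and 0 <= c2 < w and mask[r2, c2]
                                and labels[r2, c2] == 0):
                            labels[r2, c2] = current
                            queue.append((r2, c2))
    return labels


def border_components(mask: np.ndarray) -> np.ndarray:
    """Mask minus every 8-connected component touching the frame."""
    labels = flood_fill_labels(mask, 8)
    touching = set(labels[0, :]) | set(labels[-1, :]) \
        | set(labels[:, 0]) | set(labels[:, -1])
    touching.discard(0)
    out = mask.copy()
    for lbl in touching:
        out[labels == lbl] = False
    return out


def brute_force_edt(mask: np.ndarray) -> np.ndarray:
    """O(N^2) nearest-false search via an explicit distance matrix."""
    h, w = mask.shape
    out = np.zeros((h, w), dtype=float)
    bg = np.argwhere(~mask)
    if len(bg) == 0:
        # virtual background ring just outside the frame
        ring = []
        for c in range(-1, w + 1):
            ring.append((-1, c))
            ring.append((h, c))
        for r in range(h):
            ring.append((r, -1))
            ring.append((r, w))
        bg = np.array(ring)
    fg = np.argwhere(mask)
    for r, c in fg:
        out[r, c] = np.sqrt(((bg - (r, c)) ** 2).sum(axis=1).min())
    return out


def signed_boundary_distance(inside: np.ndarray) -> np.ndarray:
    """Signed pixel-grid distance: -d(nearest outside) in, +d(nearest inside) out."""
    h, w = inside.shape
    out = np.zeros((h, w), dtype=float)
    ins = np.argwhere(inside)
    outs = np.argwhere(~inside)
    for r in range(h):
        for c in range(w):
            if inside[r, c]:
                out[r, c] = -np.sqrt(((outs - (r, c)) ** 2).sum(axis=1).min())
            else:
                out[r, c] = np.sqrt(((ins - (r, c)) ** 2).sum(axis=1).min())
    return out


def otsu_threshold_256(gray: np.ndarray) -> float:
    """Exhaustive search over 256 histogram bin edges maximizing
    between-class variance."""
    lo, hi = float(gray.min()), float(gray.max())
    edges = np.linspace(lo, hi, 257)
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts, _ = np.histogram(gray.ravel(), bins=edges)
    best, best_t = -1.0, centers[0]
    total = counts.sum()
    for k in range(1, 256):
        w0 = counts[:k].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        m0 = (counts[:k] * centers[:k]).sum() / w0
        m1 = (counts[k:] * centers[k:]).sum() / w1
        var = w0 * w1 * (m0 - m1) ** 2
        if var > best:
            best, best_t = var, edges[k]
    return best_t
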