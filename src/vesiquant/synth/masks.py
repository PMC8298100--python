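"""Synthetic mitochondrial masks: thin curvilinear network strokes vs
near-circular aggregated blobs.

Objects are placed on a coarse grid with margins so the requested number of
connected components is guaranteed.  Ground truth records each object's
analytic area (disc: pi*r^2; stroke: length * width).
"""

from __future__ import annotations

import numpy as np
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line
from skimage.morphology import dilation, disk as disk_selem

__all__ = ["simulate_mito_masks"]

_CELL = 48  # px grid cell per object; strokes/blobs stay well inside


def _stroke(rng: np.random.Generator, cell: np.ndarray) -> float:
    """Random-walk polyline of width ~3 px, aspect >= 5:1.  Returns area."""
    n = cell.shape[0]
    width = 3
    n_seg = 4
    seg_len = 9.0
    pos = np.array([n / 2.0, n / 2.0])
    theta = rng.uniform(0, 2 * np.pi)
    canvas = np.zeros_like(cell, dtype=bool)
    total_len = 0.0
    for _ in range(n_seg):
        theta += rng.normal(0, 0.5)
        nxt = pos + seg_len * np.array([np.cos(theta), np.sin(theta)])
        nxt = np.clip(nxt, width + 1, n - width - 2)
        rr, cc = draw_line(
            int(round(pos[0])), int(round(pos[1])),
            int(round(nxt[0])), int(round(nxt[1])),
        )
        canvas[rr, cc] = True
        total_len += float(np.hypot(*(nxt - pos)))
        pos = nxt
    canvas = dilation(canvas, disk_selem(width // 2))
    cell |= canvas
    return total_len * width


def _blob(rng: np.random.Generator, cell: np.ndarray) -> float:
    n = cell.shape[0]
    r = rng.uniform(6.0, 12.0)
    rr, cc = draw_disk((n / 2.0, n / 2.0), r, shape=cell.shape)
    cell[rr, cc] = True
    return float(np.pi * r**2)


def simulate_mito_masks(
    mode: str,
    n_objects: int,
    pixel_size: float = 0.065,
    seed: int = 0,
) -> tuple[np.ndarray, list[dict]]:
    """Binary mask plus ground-truth object list.

    ``mode='network'`` draws elongated strokes (low circularity);
    ``mode='aggregated'`` draws near-circular blobs (high circularity).
    Ground truth entries carry ``area_px2``, ``area_um2`` and ``mode``.
    """
    if mode not in {"network", "aggregated"}:
        raise ValueError(f"unknown mode {mode!r}; use 'network' or 'aggregated'")
    if n_objects < 1:
        raise ValueError("n_objects must be >= 1")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    rng = np.random.default_rng(seed)
    n_cols = int(np.ceil(np.sqrt(n_objects)))
    n_rows = int(np.ceil(n_objects / n_cols))
    image = np.zeros((n_rows * _CELL, n_cols * _CELL), dtype=bool)
    truth = []
    for k in range(n_objects):
        r, c = divmod(k, n_cols)
        cell = image[r * _CELL : (r + 1) * _CELL, c * _CELL : (c + 1) * _CELL]
        area_px = _stroke(rng, cell) if mode == "network" else _blob(rng, cell)
        truth.append(
            {
                "label": k + 1,
                "mode": mode,
                "area_px2": area_px,
                "area_um2": area_px * pixel_size**2,
            }
        )
    return image, truth
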