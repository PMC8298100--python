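"""File I/O: multi-frame TIFF stacks with sidecar metadata, ROI lists."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile
import yaml

from vesiquant.stvariance import FrameStack, ROI

__all__ = ["read_stack", "write_stack", "read_rois", "write_rois"]


def write_stack(stack: FrameStack, path: str | Path) -> None:
    """Write a multi-frame TIFF plus a ``<name>.yaml`` metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack.data.astype(np.float32), photometric="minisblack")
    sidecar = path.with_suffix(".yaml")
    sidecar.write_text(
        yaml.safe_dump(
            {
                "frame_interval_s": float(stack.frame_interval),
                "pixel_size_um": float(stack.pixel_size),
            }
        )
    )


def read_stack(
    path: str | Path,
    frame_interval: float | None = None,
    pixel_size: float | None = None,
) -> FrameStack:
    """Read a multi-frame TIFF; metadata from arguments or the yaml sidecar."""
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    sidecar = path.with_suffix(".yaml")
    if (frame_interval is None or pixel_size is None) and sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text()) or {}
        if frame_interval is None:
            frame_interval = meta.get("frame_interval_s")
        if pixel_size is None:
            pixel_size = meta.get("pixel_size_um")
    if frame_interval is None or pixel_size is None:
        raise ValueError(
            f"frame_interval and pixel_size required (no sidecar at {sidecar})"
        )
    return FrameStack(
        data=np.asarray(data, dtype=float),
        frame_interval=float(frame_interval),
        pixel_size=float(pixel_size),
    )


def read_rois(path: str | Path) -> list[ROI]:
    """Read ROIs from delimited text: one ``x,y,w,h`` per line ('#' comments)."""
    rois = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = [int(p) for p in line.replace(",", " ").split()]
        if len(parts) != 4:
            raise ValueError(f"expected 'x,y,w,h', got {line!r}")
        rois.append(ROI(*parts))
    return rois


def write_rois(rois: list[ROI], path: str | Path) -> None:
    lines = ["# x,y,w,h"] + [f"{r.x},{r.y},{r.width},{r.height}" for r in rois]
    Path(path).write_text("\n".join(lines) + "\n")
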