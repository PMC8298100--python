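"""Spatiotemporal variance scoring of live-cell movies.

A cell associated with fast-moving subresolution vesicles shows large
frame-to-frame intensity fluctuations in the cytoplasm, while a diffusely
localized protein does not.  The score is the mean, over ROI pixels, of each
pixel's temporal variance after per-frame mean normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "FrameStack",
    "ROI",
    "VarianceMap",
    "normalize_frames",
    "temporal_variance_map",
    "spatiotemporal_variance",
    "auto_select_rois",
]


@dataclass(frozen=True)
class FrameStack:
    """A single-channel time-lapse movie.

    Parameters
    ----------
    data
        T x H x W array of intensities.
    frame_interval
        Time between frames in seconds.
    pixel_size
        Pixel size in micrometres per pixel.
    """

    data: np.ndarray
    frame_interval: float
    pixel_size: float

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 3:
            raise ValueError(f"stack must be T x H x W, got shape {data.shape}")
        if data.shape[0] < 2:
            raise ValueError("stack must have at least 2 frames")
        if not np.all(np.isfinite(data)):
            raise ValueError("stack intensities must be finite")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        object.__setattr__(self, "data", data)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]


@dataclass(frozen=True)
class ROI:
    """Rectangular region of interest; 0-based, half-open pixel indexing."""

    x: int
    y: int
    width: int = 20
    height: int = 20

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("ROI width and height must be positive")
        if self.x < 0 or self.y < 0:
            raise ValueError("ROI origin must be non-negative")

    def validate(self, frame_shape: tuple[int, int]) -> None:
        h, w = frame_shape
        if self.x + self.width > w or self.y + self.height > h:
            raise ValueError(
                f"ROI {self} extends beyond frame of shape {frame_shape}"
            )

    def slices(self) -> tuple[slice, slice]:
        return (slice(self.y, self.y + self.height), slice(self.x, self.x + self.width))

    def overlaps(self, other: "ROI") -> bool:
        return not (
            self.x + self.width <= other.x
            or other.x + other.width <= self.x
            or self.y + self.height <= other.y
            or other.y + other.height <= self.y
        )


@dataclass(frozen=True)
class VarianceMap:
    """Per-pixel temporal variances over one ROI."""

    values: np.ndarray = field()

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("variance map must be 2-D")
        if np.any(values < 0):
            raise ValueError("variances must be non-negative")
        object.__setattr__(self, "values", values)


def normalize_frames(stack: FrameStack) -> FrameStack:
    """Divide each frame by its own mean pixel intensity.

    Removes global brightness changes; every output frame has mean exactly 1.

    Raises
    ------
    ValueError
        If any frame has non-positive mean (degenerate input).
    """
    means = stack.data.mean(axis=(1, 2))
    if np.any(means <= 0):
        bad = int(np.argmax(means <= 0))
        raise ValueError(
            f"frame {bad} has non-positive mean ({means[bad]}); cannot normalize"
        )
    return replace(stack, data=stack.data / means[:, None, None])


def temporal_variance_map(
    stack: FrameStack, roi: ROI, *, ddof: int = 1
) -> VarianceMap:
    """Per-pixel variance across time within ``roi``.

    ``ddof=1`` (sample variance) is the default; set ``ddof=0`` for the
    population variance.  The stack is expected to be normalized already.
    """
    if stack.n_frames < 2:
        raise ValueError("need at least 2 frames for a temporal variance")
    roi.validate(stack.frame_shape)
    ys, xs = roi.slices()
    values = stack.data[:, ys, xs].var(axis=0, ddof=ddof)
    return VarianceMap(values)


def spatiotemporal_variance(
    stack: FrameStack,
    rois: list[ROI],
    *,
    ddof: int = 1,
    pooling: str = "pixels",
) -> float:
    """Per-cell scalar: mean temporal variance pooled over all ROI pixels.

    ``pooling='pixels'`` averages every pixel of every ROI map (identical to
    the mean of per-ROI means when all ROIs are equal-sized);
    ``pooling='rois'`` averages the per-ROI map means.
    """
    if not rois:
        raise ValueError("at least one ROI is required")
    maps = [temporal_variance_map(stack, roi, ddof=ddof) for roi in rois]
    if pooling == "pixels":
        return float(np.concatenate([m.values.ravel() for m in maps]).mean())
    if pooling == "rois":
        return float(np.mean([m.values.mean() for m in maps]))
    raise ValueError(f"unknown pooling {pooling!r}")


def auto_select_rois(
    stack: FrameStack,
    n: int,
    size: int = 20,
    brightness_band: tuple[float, float] = (25.0, 75.0),
    *,
    seed: int | None = 0,
) -> list[ROI]:
    """Choose ``n`` non-overlapping square ROIs away from bright structures.

    Candidate positions lie on a non-overlapping grid.  A candidate qualifies
    if its time-averaged mean intensity falls within the stated percentile
    band of the candidate means on the first frame — bright structures pull
    their tile into the upper tail and are excluded.  Selection among
    qualifying candidates is deterministic for a fixed ``seed``.

    Intended as a stand-in for manual ROI placement; explicit ROI lists
    should be preferred when available.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    h, w = stack.frame_shape
    if size > h or size > w:
        raise ValueError(f"ROI size {size} does not fit frame {stack.frame_shape}")
    mean_img = stack.data.mean(axis=0)
    grid = [
        (x, y)
        for y in range(0, h - size + 1, size)
        for x in range(0, w - size + 1, size)
    ]
    first_means = np.array(
        [stack.data[0, y : y + size, x : x + size].mean() for x, y in grid]
    )
    lo, hi = np.percentile(first_means, brightness_band)
    candidates = []
    for (x, y), _ in zip(grid, first_means):
        if lo <= mean_img[y : y + size, x : x + size].mean() <= hi:
            candidates.append(ROI(x, y, size, size))
    if len(candidates) < n:
        raise ValueError(
            f"only {len(candidates)} qualifying ROI positions found, need {n}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(candidates), size=n, replace=False)
    return [candidates[i] for i in sorted(idx)]
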