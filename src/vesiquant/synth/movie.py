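"""Simulated movies of diffusing diffraction-limited puncta.

Puncta are rendered as isotropic Gaussians evaluated on the pixel grid
(no sub-pixel integration) on a constant background, with Gaussian read
noise.  Motile puncta perform a 2D Brownian walk with per-axis step SD
``sqrt(2 * D * dt)`` and periodic wrap at the field edges, so punctum
density stays constant over the movie.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from vesiquant.stvariance import FrameStack

__all__ = ["VesicleMovieParams", "simulate_vesicle_movie", "brownian_positions"]


@dataclass(frozen=True)
class VesicleMovieParams:
    n_puncta: int = 40
    diffusion_coeff: float = 0.5  # um^2/s
    psf_sigma: float = 0.13  # um (diffraction-limited width)
    punctum_amplitude: float = 200.0
    background: float = 100.0
    noise_sd: float = 5.0
    frames: int = 30
    frame_interval: float = 0.3  # s (0.1775 for the faster acquisitions)
    pixel_size: float = 0.065  # um/px
    field_size: tuple[int, int] = (128, 128)  # (H, W) px
    motile: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frames < 2:
            raise ValueError("frames must be >= 2")
        if self.n_puncta < 0:
            raise ValueError("n_puncta must be >= 0")
        for name in (
            "diffusion_coeff",
            "psf_sigma",
            "punctum_amplitude",
            "background",
            "noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.frame_interval <= 0 or self.pixel_size <= 0:
            raise ValueError("frame_interval and pixel_size must be positive")
        h, w = self.field_size
        if h <= 0 or w <= 0:
            raise ValueError("field_size must be positive")


def _render(positions: np.ndarray, params: VesicleMovieParams) -> np.ndarray:
    """One frame: Gaussians at ``positions`` (um) on the pixel grid."""
    h, w = params.field_size
    frame = np.full((h, w), params.background, dtype=float)
    if len(positions) == 0:
        return frame
    sigma_px = params.psf_sigma / params.pixel_size
    ys = np.arange(h)[:, None]
    xs = np.arange(w)[None, :]
    for px, py in positions / params.pixel_size:
        frame += params.punctum_amplitude * np.exp(
            -((xs - px) ** 2 + (ys - py) ** 2) / (2.0 * sigma_px**2)
        )
    return frame


def brownian_positions(params: VesicleMovieParams) -> np.ndarray:
    """Unwrapped punctum trajectories, shape (frames, n_puncta, 2) in um.

    Per-axis Brownian steps have SD ``sqrt(2 * D * dt)``; frozen scenes
    (``motile=False``) repeat the initial positions.  Wrapping into the
    field is applied only at render time, so displacement statistics can be
    measured directly on the returned array.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.field_size
    extent = np.array([w, h]) * params.pixel_size  # (x, y) in um
    start = rng.uniform(0, 1, size=(params.n_puncta, 2)) * extent
    if not params.motile or params.n_puncta == 0:
        return np.broadcast_to(start, (params.frames, params.n_puncta, 2)).copy()
    step_sd = np.sqrt(2.0 * params.diffusion_coeff * params.frame_interval)
    steps = rng.normal(
        0.0, step_sd, size=(params.frames - 1, params.n_puncta, 2)
    )
    return np.concatenate(
        [start[None], start[None] + np.cumsum(steps, axis=0)], axis=0
    )


def simulate_vesicle_movie(params: VesicleMovieParams) -> FrameStack:
    """Simulate a punctate (or frozen) movie as a :class:`FrameStack`."""
    h, w = params.field_size
    extent = np.array([w, h]) * params.pixel_size
    trajectories = brownian_positions(params)
    # separate noise stream so the walk is unchanged by the noise setting
    noise_rng = np.random.default_rng(np.random.SeedSequence([params.seed, 1]))
    frames = np.empty((params.frames, h, w))
    for t in range(params.frames):
        frames[t] = _render(np.mod(trajectories[t], extent), params)
    if params.noise_sd > 0:
        frames += noise_rng.normal(0.0, params.noise_sd, size=frames.shape)
    return FrameStack(
        data=frames,
        frame_interval=params.frame_interval,
        pixel_size=params.pixel_size,
    )
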