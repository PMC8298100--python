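"""Persistent-random-walk track simulator with per-experiment effects.

Each cell's heading angle performs Brownian angular diffusion with
coefficient ``1 / persistence_time``, so the direction autocorrelation
decays as ``exp(-lag / persistence_time)``.  Per-cell base speeds are drawn
around the experiment mean, which itself is offset from the cohort mean by
a per-experiment random effect — the structure superplot summaries assume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from vesiquant.migration import Track

__all__ = ["TrackSimParams", "simulate_tracks"]


@dataclass(frozen=True)
class TrackSimParams:
    n_cells: int = 50
    n_experiments: int = 1
    mean_speed: float = 0.4  # um/min
    speed_sd_between_cells: float = 0.05
    experiment_effect_sd: float = 0.0
    persistence_time: float = 10.0  # min; math.inf for straight runs
    frame_interval: float = 10.0  # min
    duration: float = 600.0  # min
    positional_noise_sd: float = 0.0  # um
    condition: str = "default"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1 or self.n_experiments < 1:
            raise ValueError("n_cells and n_experiments must be >= 1")
        if self.persistence_time <= 0:
            raise ValueError("persistence_time must be positive")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.duration / self.frame_interval < 2:
            raise ValueError("duration must cover at least 2 steps")
        for name in ("mean_speed", "speed_sd_between_cells", "experiment_effect_sd",
                     "positional_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def simulate_tracks(params: TrackSimParams) -> list[Track]:
    """Simulate ``n_cells`` PRW tracks split evenly across experiments."""
    rng = np.random.default_rng(params.seed)
    n_steps = int(round(params.duration / params.frame_interval))
    dt = params.frame_interval
    angle_sd = (
        0.0
        if math.isinf(params.persistence_time)
        else np.sqrt(2.0 * dt / params.persistence_time)
    )
    exp_effects = rng.normal(0.0, params.experiment_effect_sd, params.n_experiments)

    tracks: list[Track] = []
    for i in range(params.n_cells):
        exp_idx = i % params.n_experiments
        speed = rng.normal(
            params.mean_speed + exp_effects[exp_idx], params.speed_sd_between_cells
        )
        speed = max(speed, 0.0)
        theta0 = rng.uniform(0.0, 2.0 * np.pi)
        theta = theta0 + np.concatenate(
            [[0.0], np.cumsum(rng.normal(0.0, angle_sd, n_steps - 1))]
        )
        steps = speed * dt * np.column_stack([np.cos(theta), np.sin(theta)])
        xy = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
        if params.positional_noise_sd > 0:
            xy = xy + rng.normal(0.0, params.positional_noise_sd, xy.shape)
        tracks.append(
            Track(
                cell_id=f"cell{i:04d}",
                experiment_id=f"exp{exp_idx + 1}",
                condition=params.condition,
                t=np.arange(n_steps + 1) * dt,
                xy=xy,
                frame_interval=dt,
            )
        )
    return tracks
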