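"""Perturbed-ellipse contour simulator with controllable mirror asymmetry.

The radius function is the ellipse radius times
``1 + amp * sum_k (a_k cos(k t) + asym * b_k sin(k t))`` in the ellipse
parameter ``t``.  Cosine terms are even about the major axis and keep the
contour mirror-symmetric; sine terms are odd, so ``asymmetry`` scales the
departure from mirror symmetry (0 = symmetric).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon

from vesiquant.shape import Contour

__all__ = ["ContourSimParams", "simulate_contour"]

_MAX_RETRIES = 8


@dataclass(frozen=True)
class ContourSimParams:
    base_major: float = 30.0  # um, semi-axis a
    base_minor: float = 15.0  # um, semi-axis b
    n_vertices: int = 128
    fourier_orders: int = 4
    perturbation_amplitude: float = 0.1  # fraction of radius
    asymmetry: float = 0.0  # in [0, 1]
    cell_id: str = "cell"
    experiment_id: str = "exp1"
    condition: str = "default"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.base_major >= self.base_minor > 0:
            raise ValueError("need base_major >= base_minor > 0")
        if self.n_vertices < 8:
            raise ValueError("n_vertices must be >= 8")
        if self.fourier_orders < 0:
            raise ValueError("fourier_orders must be >= 0")
        if self.perturbation_amplitude < 0:
            raise ValueError("perturbation_amplitude must be >= 0")
        if not 0.0 <= self.asymmetry <= 1.0:
            raise ValueError("asymmetry must be in [0, 1]")


def simulate_contour(params: ContourSimParams) -> Contour:
    """Simulate one simple closed contour; retries with damped perturbation.

    Self-intersecting draws are retried with the perturbation halved each
    time; after a bounded number of retries an error is raised.
    """
    rng = np.random.default_rng(params.seed)
    a, b = params.base_major, params.base_minor
    t = np.linspace(0.0, 2.0 * np.pi, params.n_vertices, endpoint=False)
    base = np.column_stack([a * np.cos(t), b * np.sin(t)])
    radius = np.hypot(base[:, 0], base[:, 1])
    theta = np.arctan2(base[:, 1], base[:, 0])

    cos_coef = rng.normal(0.0, 1.0, params.fourier_orders)
    sin_coef = rng.normal(0.0, 1.0, params.fourier_orders)

    amp = params.perturbation_amplitude
    for _ in range(_MAX_RETRIES):
        modulation = np.zeros_like(t)
        for k in range(1, params.fourier_orders + 1):
            # 1/k falloff keeps the outline smooth at higher orders
            modulation += cos_coef[k - 1] * np.cos(k * t) / k
            modulation += params.asymmetry * sin_coef[k - 1] * np.sin(k * t) / k
        r = radius * (1.0 + amp * modulation)
        if np.all(r > 0):
            verts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
            if Polygon(verts).is_valid:
                return Contour(
                    vertices=verts,
                    cell_id=params.cell_id,
                    experiment_id=params.experiment_id,
                    condition=params.condition,
                )
        amp *= 0.5
    raise RuntimeError(
        f"could not generate a simple contour after {_MAX_RETRIES} damped retries"
    )
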