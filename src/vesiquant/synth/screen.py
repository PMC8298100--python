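"""Synthetic vesicle-capture screen measurement tables.

Per cell, a pre-rerouting mitochondrial intensity is drawn around a
baseline and the post intensity is ``F_pre * (true_ratio + noise)``, giving
per-cell F_post/F_pre ratios centred on the planted effect for each
(construct, rab) pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ScreenSimParams", "simulate_screen"]


@dataclass(frozen=True)
class ScreenSimParams:
    constructs: tuple[str, ...] = ("TPD52", "TPD53")
    rabs: tuple[str, ...] = ("control", "rabA", "rabB")
    control_rab: str = "control"
    true_ratio: dict = field(default_factory=dict)  # (construct, rab) -> ratio
    default_ratio: float = 1.0
    cell_noise_sd: float = 0.2
    n_cells_per_condition: int = 20
    baseline: float = 100.0
    baseline_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells_per_condition < 3:
            raise ValueError("n_cells_per_condition must be >= 3")
        if self.cell_noise_sd < 0 or self.baseline_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.baseline <= 0:
            raise ValueError("baseline must be positive")
        if self.control_rab not in self.rabs:
            raise ValueError("control_rab must be among rabs")
        for (c, r), v in self.true_ratio.items():
            if c not in self.constructs or r not in self.rabs:
                raise ValueError(f"true_ratio key ({c!r}, {r!r}) not in labels")
            if v <= 0:
                raise ValueError("true ratios must be positive")

    def ratio_for(self, construct: str, rab: str) -> float:
        return self.true_ratio.get((construct, rab), self.default_ratio)


def simulate_screen(params: ScreenSimParams) -> pd.DataFrame:
    """Tidy table with columns construct, rab, cell_id, F_pre, F_post."""
    rng = np.random.default_rng(params.seed)
    rows = []
    for construct in params.constructs:
        for rab in params.rabs:
            ratio = params.ratio_for(construct, rab)
            n = params.n_cells_per_condition
            f_pre = np.abs(rng.normal(params.baseline, params.baseline_sd, n))
            f_pre = np.maximum(f_pre, 1e-6)
            ratios = ratio + rng.normal(0.0, params.cell_noise_sd, n)
            for i in range(n):
                rows.append(
                    {
                        "construct": construct,
                        "rab": rab,
                        "cell_id": f"{construct}_{rab}_{i:03d}",
                        "F_pre": f_pre[i],
                        "F_post": f_pre[i] * ratios[i],
                    }
                )
    return pd.DataFrame(rows)
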