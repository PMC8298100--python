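"""Non-imaging quantifications: 3D invasion depth fraction, liposome-binding
densitometry correction, and the amplification co-occurrence statistic."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "DepthProfile",
    "CooccurrenceTable",
    "invasion_fraction",
    "normalize_invasion",
    "liposome_binding",
    "cooccurrence_stats",
]


@dataclass(frozen=True, eq=False)
class DepthProfile:
    """Total fluorescence per confocal slice down an invasion plug."""

    slice_depths: np.ndarray  # um, strictly increasing
    intensities: np.ndarray  # a.u., >= 0
    well_id: str = "well"
    condition: str = "default"

    def __post_init__(self) -> None:
        d = np.asarray(self.slice_depths, dtype=float)
        i = np.asarray(self.intensities, dtype=float)
        if d.ndim != 1 or d.shape != i.shape:
            raise ValueError("depths and intensities must be matching 1-D arrays")
        if np.any(d < 0) or np.any(np.diff(d) <= 0):
            raise ValueError("depths must be non-negative and strictly increasing")
        if np.any(i < 0):
            raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "slice_depths", d)
        object.__setattr__(self, "intensities", i)


@dataclass(frozen=True)
class CooccurrenceTable:
    """Amplification co-occurrence counts: A and B amplified among n_total."""

    n_total: int
    n_a: int
    n_b: int
    n_ab: int

    def __post_init__(self) -> None:
        if min(self.n_total, self.n_a, self.n_b, self.n_ab) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_ab > min(self.n_a, self.n_b):
            raise ValueError("n_ab cannot exceed either margin")
        if self.n_a + self.n_b - self.n_ab > self.n_total:
            raise ValueError("margins exceed the total")

    def cells(self) -> tuple[int, int, int, int]:
        """(both, A-only, B-only, neither)."""
        return (
            self.n_ab,
            self.n_a - self.n_ab,
            self.n_b - self.n_ab,
            self.n_total - self.n_a - self.n_b + self.n_ab,
        )


def invasion_fraction(profile: DepthProfile, threshold_depth: float = 45.0) -> float:
    """Fraction of total fluorescence at depths >= ``threshold_depth`` um."""
    total = profile.intensities.sum()
    if total <= 0:
        raise ValueError("total intensity is zero; fraction undefined")
    deep = profile.intensities[profile.slice_depths >= threshold_depth].sum()
    return float(deep / total)


def normalize_invasion(fractions: pd.DataFrame, control: str) -> pd.DataFrame:
    """Express each well's invasion fraction relative to the control mean.

    ``fractions`` needs columns condition and fraction; a ``relative``
    column is added.  The control-condition mean maps to exactly 1.
    """
    for col in ("condition", "fraction"):
        if col not in fractions.columns:
            raise ValueError(f"table missing column {col!r}")
    ctrl = fractions.loc[fractions["condition"] == control, "fraction"]
    if len(ctrl) == 0:
        raise ValueError(f"control condition {control!r} not found")
    ctrl_mean = ctrl.mean()
    if ctrl_mean <= 0:
        raise ValueError("control mean must be positive")
    return fractions.assign(relative=fractions["fraction"] / ctrl_mean)


def liposome_binding(
    quants: pd.DataFrame,
    pelleting_efficiency: dict[int, float],
    reference: tuple[str, int] = ("WT", 100),
) -> pd.DataFrame:
    """Background- and pelleting-corrected liposome binding per condition.

    ``quants`` needs columns protein, diameter_nm (0 or NaN for the
    no-liposome control lane), band_density and lane_background.  Per
    protein, the corrected band is
    ``band - lane_background - no_liposome_band``; it is divided by the
    pelleting efficiency of that diameter (fraction relative to the 100 nm
    size) and finally by the same quantity for the reference
    (protein, diameter) pair.  Negative corrected bands are clipped to 0
    and flagged in the ``clipped`` column.
    """
    needed = {"protein", "diameter_nm", "band_density", "lane_background"}
    if not needed <= set(quants.columns):
        raise ValueError(f"gel table must have columns {sorted(needed)}")
    for d, eff in pelleting_efficiency.items():
        if eff <= 0:
            raise ValueError(f"pelleting efficiency for {d} nm must be > 0")

    df = quants.copy()
    df["diameter_nm"] = df["diameter_nm"].fillna(0).astype(int)
    df["net"] = df["band_density"] - df["lane_background"]

    rows = []
    for protein, g in df.groupby("protein", sort=True):
        ctrl = g.loc[g["diameter_nm"] == 0, "net"]
        if len(ctrl) == 0:
            raise ValueError(f"no no-liposome control lane for protein {protein!r}")
        ctrl_net = ctrl.mean()
        for _, row in g[g["diameter_nm"] != 0].iterrows():
            d = int(row["diameter_nm"])
            if d not in pelleting_efficiency:
                raise ValueError(f"no pelleting efficiency for diameter {d} nm")
            corrected = (row["net"] - ctrl_net) / pelleting_efficiency[d]
            clipped = corrected < 0
            rows.append(
                {
                    "protein": protein,
                    "diameter_nm": d,
                    "corrected": max(corrected, 0.0),
                    "clipped": clipped,
                }
            )
    out = pd.DataFrame(rows)
    ref_prot, ref_diam = reference
    ref_rows = out[(out["protein"] == ref_prot) & (out["diameter_nm"] == ref_diam)]
    if len(ref_rows) == 0:
        raise ValueError(f"reference condition {reference} not present")
    ref_val = ref_rows["corrected"].mean()
    if ref_val <= 0:
        raise ValueError("reference corrected band must be positive")
    out["binding"] = out["corrected"] / ref_val
    if out["clipped"].any():
        logger.warning(
            "%d corrected band(s) were negative and clipped to 0",
            int(out["clipped"].sum()),
        )
    return out.drop(columns="corrected")


def cooccurrence_stats(
    table: CooccurrenceTable, alternative: str = "two-sided"
) -> dict:
    """Odds-ratio and Fisher-exact statistics for a 2x2 co-occurrence table.

    Returns a dict with log2_odds_ratio, odds_ratio, fisher_p,
    percent_a, percent_b, percent_ab, and a haldane flag (True when a zero
    cell forced the 0.5 continuity correction).
    """
    both, a_only, b_only, neither = table.cells()
    cells = np.array([[both, a_only], [b_only, neither]], dtype=float)
    haldane = bool((cells == 0).any())
    if haldane:
        logger.warning("zero cell in 2x2 table; applying Haldane 0.5 correction")
        cells = cells + 0.5
    odds = (cells[0, 0] * cells[1, 1]) / (cells[0, 1] * cells[1, 0])
    fisher_p = float(
        stats.fisher_exact(
            [[both, a_only], [b_only, neither]], alternative=alternative
        ).pvalue
    )
    return {
        "odds_ratio": float(odds),
        "log2_odds_ratio": float(math.log2(odds)),
        "fisher_p": fisher_p,
        "percent_a": 100.0 * table.n_a / table.n_total,
        "percent_b": 100.0 * table.n_b / table.n_total,
        "percent_ab": 100.0 * table.n_ab / table.n_total,
        "haldane": haldane,
    }
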