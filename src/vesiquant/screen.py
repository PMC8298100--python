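"""Vesicle-capture screen statistics.

Corerouting of a candidate marker to mitochondria is scored per cell as the
ratio of mean mitochondrial fluorescence after vs before the rerouting
trigger (F_post/F_pre).  Per-condition effects are tested many-to-one
against a fluorophore control (Dunnett), estimated with BCa bootstrap
confidence intervals, standardized into a screen matrix, clustered, and
classified into marker-set membership classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from vesiquant.stvariance import ROI

__all__ = [
    "EffectEstimate",
    "ScreenMatrix",
    "mito_intensity_ratio",
    "dunnett_vs_control",
    "bootstrap_bca_diff",
    "build_screen_matrix",
    "cluster_screen",
    "classify_populations",
]


@dataclass(frozen=True)
class EffectEstimate:
    """Mean difference vs control with a bootstrap confidence interval."""

    mean_difference: float
    ci_low: float
    ci_high: float
    n_boot: int
    group_n: int
    control_n: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.degenerate and not (
            self.ci_low <= self.mean_difference <= self.ci_high
        ):
            raise ValueError("CI must bracket the point estimate")


@dataclass(frozen=True)
class ScreenMatrix:
    """Mean per-condition ratios (rows = rabs, cols = constructs) with z-scores."""

    values: pd.DataFrame
    zscores: pd.DataFrame


def mito_intensity_ratio(
    pre_image: np.ndarray, post_image: np.ndarray, rois: list[ROI]
) -> float:
    """F_post/F_pre pooled over all ROI pixels on the mitochondria.

    The numerator and denominator are grand means over every pixel of every
    ROI (identical to the mean of per-ROI means for equal-sized ROIs).
    """
    pre = np.asarray(pre_image, dtype=float)
    post = np.asarray(post_image, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post images must have the same shape")
    if not rois:
        raise ValueError("at least one ROI is required")
    pre_pix, post_pix = [], []
    for roi in rois:
        roi.validate(pre.shape)
        ys, xs = roi.slices()
        pre_pix.append(pre[ys, xs].ravel())
        post_pix.append(post[ys, xs].ravel())
    pre_mean = float(np.concatenate(pre_pix).mean())
    if pre_mean == 0:
        raise ValueError("pre-rerouting ROI mean is zero; ratio undefined")
    return float(np.concatenate(post_pix).mean()) / pre_mean


def dunnett_vs_control(
    groups: dict[str, np.ndarray], control: str, alpha: float = 0.05
) -> pd.Series:
    """Two-sided Dunnett many-to-one test of every group against ``control``.

    Uses pooled variance and the equicorrelated multivariate-t distribution
    with correlations derived from the (possibly unbalanced) group sizes.
    Returns adjusted p-values indexed by group label (control excluded).
    ``alpha`` is recorded for callers making hit calls; it does not affect
    the p-values.
    """
    if control not in groups:
        raise ValueError(f"control label {control!r} not among groups")
    if len(groups) < 2:
        raise ValueError("need at least one non-control group")
    labels = [k for k in groups if k != control]
    samples = [np.asarray(groups[k], dtype=float) for k in labels]
    ctrl = np.asarray(groups[control], dtype=float)
    for name, s in zip(labels + [control], samples + [ctrl]):
        if len(s) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
    if len(samples) == 1:
        # one comparison: the multivariate-t adjustment degenerates exactly
        # to the pooled-variance two-sided t test; computing it directly
        # avoids the CDF integration error of the general path
        p = stats.ttest_ind(samples[0], ctrl, equal_var=True).pvalue
        return pd.Series([float(p)], index=labels, name="p_adj")
    res = stats.dunnett(*samples, control=ctrl, alternative="two-sided", rng=0)
    return pd.Series(np.clip(res.pvalue, 0.0, 1.0), index=labels, name="p_adj")


def _bca_interval(
    boot: np.ndarray, observed: float, jack: np.ndarray, level: float
) -> tuple[float, float]:
    alpha = 1.0 - level
    # bias term from the bootstrap distribution's position relative to the
    # observed statistic; ties counted half
    prop = (np.sum(boot < observed) + 0.5 * np.sum(boot == observed)) / len(boot)
    prop = min(max(prop, 1.0 / (2 * len(boot))), 1.0 - 1.0 / (2 * len(boot)))
    z0 = stats.norm.ppf(prop)
    dev = jack.mean() - jack
    denom = np.sum(dev**2) ** 1.5
    a = np.sum(dev**3) / (6.0 * denom) if denom > 0 else 0.0
    lo_hi = []
    for q in (alpha / 2.0, 1.0 - alpha / 2.0):
        z = stats.norm.ppf(q)
        adj = stats.norm.cdf(z0 + (z0 + z) / (1.0 - a * (z0 + z)))
        lo_hi.append(float(np.quantile(boot, adj)))
    return lo_hi[0], lo_hi[1]


def bootstrap_bca_diff(
    group: np.ndarray,
    control: np.ndarray,
    n_boot: int = 100_000,
    level: float = 0.95,
    seed: int | None = None,
) -> EffectEstimate:
    """BCa bootstrap interval for ``mean(group) - mean(control)``.

    The two arms are resampled independently with replacement.  The
    acceleration is computed from the pooled per-arm jackknife of the
    statistic (leave-one-out within each arm, other arm fixed).
    """
    group = np.asarray(group, dtype=float)
    control = np.asarray(control, dtype=float)
    if len(group) < 2 or len(control) < 2:
        raise ValueError("both samples need n >= 2")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    rng = np.random.default_rng(seed)
    observed = float(group.mean() - control.mean())

    boot_g = rng.choice(group, size=(n_boot, len(group)), replace=True).mean(axis=1)
    boot_c = rng.choice(control, size=(n_boot, len(control)), replace=True).mean(axis=1)
    boot = boot_g - boot_c

    if np.ptp(boot) == 0:
        return EffectEstimate(
            mean_difference=observed,
            ci_low=observed,
            ci_high=observed,
            n_boot=n_boot,
            group_n=len(group),
            control_n=len(control),
            degenerate=True,
        )

    # leave-one-out over each arm, pooled into one jackknife vector
    jack_g = (group.sum() - group) / (len(group) - 1) - control.mean()
    jack_c = group.mean() - (control.sum() - control) / (len(control) - 1)
    jack = np.concatenate([jack_g, jack_c])

    lo, hi = _bca_interval(boot, observed, jack, level)
    return EffectEstimate(
        mean_difference=observed,
        ci_low=min(lo, observed),
        ci_high=max(hi, observed),
        n_boot=n_boot,
        group_n=len(group),
        control_n=len(control),
    )


def build_screen_matrix(
    measurements: pd.DataFrame, standardize: str = "column"
) -> ScreenMatrix:
    """Aggregate per-cell F_post/F_pre ratios into a rab x construct matrix.

    ``measurements`` must have columns construct, rab, F_pre, F_post.
    Z-scores are computed per ``standardize`` axis: ``'column'`` (per
    construct screen, the default), ``'row'`` (per rab) or ``'global'``.
    """
    required = {"construct", "rab", "F_pre", "F_post"}
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"measurement table missing columns {sorted(missing)}")
    if (measurements["F_pre"] <= 0).any():
        raise ValueError("F_pre must be strictly positive")
    df = measurements.assign(ratio=measurements["F_post"] / measurements["F_pre"])
    values = df.pivot_table(
        index="rab", columns="construct", values="ratio", aggfunc="mean"
    )
    if values.isna().any().any():
        holes = [
            (r, c)
            for r in values.index
            for c in values.columns
            if pd.isna(values.loc[r, c])
        ]
        raise ValueError(f"missing (rab, construct) combinations: {holes}")

    if standardize == "column":
        sd = values.std(axis=0, ddof=1)
        if (sd == 0).any():
            bad = list(sd.index[sd == 0])
            raise ValueError(
                f"constant column(s) {bad}: column z-score undefined; "
                "use standardize='global'"
            )
        z = (values - values.mean(axis=0)) / sd
    elif standardize == "row":
        sd = values.std(axis=1, ddof=1)
        if (sd == 0).any():
            bad = list(sd.index[sd == 0])
            raise ValueError(
                f"constant row(s) {bad}: row z-score undefined; "
                "use standardize='global'"
            )
        z = values.sub(values.mean(axis=1), axis=0).div(sd, axis=0)
    elif standardize == "global":
        sd = values.values.std(ddof=1)
        if sd == 0:
            raise ValueError("matrix is constant; z-scores undefined")
        z = (values - values.values.mean()) / sd
    else:
        raise ValueError(f"unknown standardize axis {standardize!r}")
    return ScreenMatrix(values=values, zscores=z)


def cluster_screen(
    matrix: ScreenMatrix,
    linkage: str = "complete",
    metric: str = "euclidean",
    n_clusters: int = 2,
    use_zscores: bool = True,
) -> dict:
    """Hierarchically cluster screen rows (rabs).

    Returns a dict with the linkage matrix (``'linkage'``), deterministic
    leaf order (``'leaf_order'``, lower original index first on ties) and
    flat cluster labels at ``n_clusters`` (``'clusters'``, a Series indexed
    by rab).
    """
    data = matrix.zscores if use_zscores else matrix.values
    X = data.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    if not np.all(np.isfinite(X)):
        raise ValueError("matrix contains non-finite values")
    if linkage not in {"complete", "average", "ward"}:
        raise ValueError(f"unsupported linkage {linkage!r}")
    Z = hierarchy.linkage(pdist(X, metric=metric), method=linkage)
    leaf_order = [data.index[i] for i in hierarchy.leaves_list(Z)]
    flat = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    return {
        "linkage": Z,
        "leaf_order": leaf_order,
        "clusters": pd.Series(flat, index=data.index, name="cluster"),
    }


def classify_populations(hits: pd.DataFrame) -> dict[frozenset, set]:
    """Group hit rabs by the set of constructs in which they were significant.

    ``hits`` is a boolean DataFrame (rows = rabs, columns = constructs) of
    Dunnett hit calls (adjusted p < alpha vs fluorophore control).  Returns
    a mapping from frozenset of construct labels to the set of rabs with
    exactly that membership; rabs significant nowhere are excluded.
    """
    classes: dict[frozenset, set] = {}
    for rab, row in hits.iterrows():
        members = frozenset(c for c in hits.columns if bool(row[c]))
        if members:
            classes.setdefault(members, set()).add(rab)
    return classes
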