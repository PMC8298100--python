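"""2D cell-migration track statistics.

Operates on manually tracked nuclear positions.  All statistics work in
micrometres and minutes; the reader converts pixels/frames at ingest.
Lag-based statistics (MSD, direction autocorrelation) are time-averaged
over overlapping windows within each track and then summarized across
cells as mean +/- SEM.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Track",
    "read_tracks",
    "instantaneous_speed",
    "cumulative_distance",
    "average_speed",
    "directionality_ratio",
    "msd",
    "direction_autocorrelation",
    "turning_angles",
    "fastest_segment_time",
    "superplot_summary",
    "superplot_figure",
]


@dataclass(frozen=True, eq=False)
class Track:
    """Ordered timestamped 2D positions for one cell.

    ``t`` is in minutes and strictly increasing; ``xy`` is an (n, 2) array
    in micrometres.
    """

    cell_id: str
    t: np.ndarray
    xy: np.ndarray
    experiment_id: str = "exp1"
    condition: str = "default"
    frame_interval: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        xy = np.asarray(self.xy, dtype=float)
        if t.ndim != 1 or len(t) < 2:
            raise ValueError("track needs at least 2 timestamped points")
        if np.any(np.diff(t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if xy.shape != (len(t), 2):
            raise ValueError("xy must be (n, 2) matching t")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(xy))):
            raise ValueError("track coordinates must be finite")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "xy", xy)
        if self.frame_interval is None:
            object.__setattr__(self, "frame_interval", float(np.median(np.diff(t))))

    @property
    def n_points(self) -> int:
        return len(self.t)

    def steps(self) -> np.ndarray:
        return np.diff(self.xy, axis=0)

    def step_lengths(self) -> np.ndarray:
        d = self.steps()
        return np.hypot(d[:, 0], d[:, 1])


def instantaneous_speed(track: Track) -> np.ndarray:
    """Per-step speed: Euclidean displacement over step duration (um/min)."""
    dt = np.diff(track.t)
    return track.step_lengths() / dt


def cumulative_distance(track: Track) -> np.ndarray:
    """Running path length, starting at 0 (one value per track point)."""
    return np.concatenate([[0.0], np.cumsum(track.step_lengths())])


def average_speed(track: Track) -> float:
    """Total path length divided by total elapsed time (um/min)."""
    elapsed = track.t[-1] - track.t[0]
    if elapsed <= 0:
        raise ValueError("zero elapsed time")
    return float(track.step_lengths().sum() / elapsed)


def directionality_ratio(track: Track) -> np.ndarray:
    """Net displacement from start over cumulative path length, per time point.

    Entries before the first nonzero-path point are NaN (undefined), so the
    first element is always NaN.
    """
    cum = cumulative_distance(track)
    net = np.hypot(*(track.xy - track.xy[0]).T)
    out = np.full(track.n_points, np.nan)
    ok = cum > 0
    out[ok] = net[ok] / cum[ok]
    return out


def _track_msd(track: Track, max_lag: int) -> np.ndarray:
    """Time-averaged MSD over overlapping pairs for lags 1..max_lag."""
    xy = track.xy
    out = np.empty(max_lag)
    for k in range(1, max_lag + 1):
        d = xy[k:] - xy[:-k]
        out[k - 1] = np.mean(d[:, 0] ** 2 + d[:, 1] ** 2)
    return out


def msd(
    tracks: list[Track], max_lag_fraction: float = 0.5
) -> pd.DataFrame:
    """Cohort mean +/- SEM of per-track time-averaged MSD by lag.

    Lags run from 1 step up to ``max_lag_fraction`` of each track's length;
    tracks too short for a lag are excluded at that lag.  Returns a tidy
    frame with columns lag (steps), lag_time (min), mean, sem, n.
    """
    if not tracks:
        raise ValueError("at least one track required")
    per_track = []
    for tr in tracks:
        max_lag = max(1, int((tr.n_points - 1) * max_lag_fraction))
        per_track.append(_track_msd(tr, max_lag))
    n_lags = max(len(v) for v in per_track)
    dt = float(np.median([tr.frame_interval for tr in tracks]))
    rows = []
    for k in range(1, n_lags + 1):
        vals = np.array([v[k - 1] for v in per_track if len(v) >= k])
        rows.append(
            {
                "lag": k,
                "lag_time": k * dt,
                "mean": vals.mean(),
                "sem": stats.sem(vals) if len(vals) > 1 else np.nan,
                "n": len(vals),
            }
        )
    return pd.DataFrame(rows)


def _unit_steps(track: Track) -> np.ndarray:
    d = track.steps()
    lengths = np.hypot(d[:, 0], d[:, 1])
    keep = lengths > 0
    return d[keep] / lengths[keep, None]


def direction_autocorrelation(
    tracks: list[Track], max_lag_fraction: float = 0.5
) -> pd.DataFrame:
    """Cohort mean +/- SEM of step-direction cosine similarity by lag.

    For lag k the per-track value is the mean of cos(theta) between step
    unit vectors i and i+k over all overlapping pairs (zero-length steps
    skipped).  Lag 0 is identically 1.
    """
    if not tracks:
        raise ValueError("at least one track required")
    per_track = []
    for tr in tracks:
        u = _unit_steps(tr)
        max_lag = max(1, int(len(u) * max_lag_fraction))
        vals = np.full(max_lag + 1, np.nan)
        vals[0] = 1.0
        for k in range(1, max_lag + 1):
            if len(u) > k:
                vals[k] = np.mean(np.sum(u[k:] * u[:-k], axis=1))
        per_track.append(vals)
    n_lags = max(len(v) for v in per_track)
    dt = float(np.median([tr.frame_interval for tr in tracks]))
    rows = []
    for k in range(n_lags):
        vals = np.array(
            [v[k] for v in per_track if len(v) > k and np.isfinite(v[k])]
        )
        if len(vals) == 0:
            continue
        rows.append(
            {
                "lag": k,
                "lag_time": k * dt,
                "mean": vals.mean(),
                "sem": stats.sem(vals) if len(vals) > 1 else np.nan,
                "n": len(vals),
            }
        )
    return pd.DataFrame(rows)


def turning_angles(tracks: list[Track]) -> np.ndarray:
    """Signed angles between consecutive step vectors, pooled across tracks.

    Angles are in (-pi, pi]; zero-length steps are skipped.  Tracks with
    fewer than 3 points contribute nothing.
    """
    angles = []
    for tr in tracks:
        u = _unit_steps(tr)
        if len(u) < 2:
            continue
        a, b = u[:-1], u[1:]
        cross = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
        dot = np.sum(a * b, axis=1)
        theta = np.arctan2(cross, dot)
        # atan2 returns [-pi, pi]; map -pi to +pi for the (-pi, pi] convention
        theta[theta == -np.pi] = np.pi
        angles.append(theta)
    if not angles:
        return np.empty(0)
    return np.concatenate(angles)


def fastest_segment_time(track: Track, segment_length: float = 25.0) -> float:
    """Minimum elapsed time over windows whose path length reaches ``segment_length``.

    Windows are runs of consecutive points (no sub-step interpolation).
    Returns NaN if the whole track's path is shorter than ``segment_length``.
    """
    cum = cumulative_distance(track)
    if cum[-1] < segment_length:
        return float("nan")
    best = np.inf
    j = 0
    for i in range(track.n_points):
        j = max(j, i + 1)
        while j < track.n_points and cum[j] - cum[i] < segment_length:
            j += 1
        if j >= track.n_points:
            break
        best = min(best, track.t[j] - track.t[i])
    return float(best)


def superplot_summary(
    per_cell: pd.DataFrame,
    value: str,
    control: str | None = None,
) -> dict:
    """Replicate-aware summary: per-experiment means + between-condition test.

    ``per_cell`` must have columns condition, experiment_id and ``value``.
    With two conditions a two-sided Student's t test on experiment means is
    used (experiments are the sampling unit); with more, Dunnett against
    ``control``.  Returns a dict with 'experiment_means' (tidy frame) and
    'test' (statistic name, p-value(s), difference(s)).
    """
    for col in ("condition", "experiment_id", value):
        if col not in per_cell.columns:
            raise ValueError(f"per-cell table missing column {col!r}")
    exp_means = (
        per_cell.groupby(["condition", "experiment_id"], sort=True)[value]
        .mean()
        .reset_index()
    )
    conditions = sorted(exp_means["condition"].unique())
    if len(conditions) < 2:
        raise ValueError("need at least 2 conditions")
    groups = {
        c: exp_means.loc[exp_means["condition"] == c, value].to_numpy()
        for c in conditions
    }
    if len(conditions) == 2:
        a, b = (groups[c] for c in conditions)
        if len(a) < 2 or len(b) < 2:
            raise ValueError(
                "Student's t on experiment means needs >= 2 experiments per condition"
            )
        if np.ptp(np.concatenate([a, b])) == 0:
            t_res = (0.0, 1.0)  # identical experiment means everywhere
        else:
            r = stats.ttest_ind(a, b)
            t_res = (float(r.statistic), float(r.pvalue))
        test = {
            "method": "student_t_experiment_means",
            "conditions": conditions,
            "difference": float(a.mean() - b.mean()),
            "statistic": t_res[0],
            "p": t_res[1],
        }
    else:
        if control is None or control not in groups:
            raise ValueError(">2 conditions require a valid control label")
        from vesiquant.screen import dunnett_vs_control

        p = dunnett_vs_control(groups, control=control)
        diffs = {c: float(groups[c].mean() - groups[control].mean()) for c in p.index}
        test = {
            "method": "dunnett_experiment_means",
            "control": control,
            "difference": diffs,
            "p": p.to_dict(),
        }
    return {"experiment_means": exp_means, "test": test}


def superplot_figure(
    per_cell: pd.DataFrame,
    value: str,
    ax=None,
):
    """Superplot: per-cell dots colour-coded by experiment, experiment means
    as large markers, grouped by condition.  Returns the matplotlib axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    conditions = sorted(per_cell["condition"].unique())
    experiments = sorted(per_cell["experiment_id"].unique())
    cmap = plt.get_cmap("tab10")
    rng = np.random.default_rng(0)  # fixed jitter for reproducible figures
    for xi, cond in enumerate(conditions):
        for ei, exp in enumerate(experiments):
            vals = per_cell.loc[
                (per_cell["condition"] == cond)
                & (per_cell["experiment_id"] == exp),
                value,
            ]
            if vals.empty:
                continue
            jitter = rng.uniform(-0.15, 0.15, len(vals))
            ax.scatter(xi + jitter, vals, s=12, alpha=0.4, color=cmap(ei % 10))
            ax.scatter(
                [xi], [vals.mean()], s=120, color=cmap(ei % 10),
                edgecolor="black", zorder=3,
            )
    ax.set_xticks(range(len(conditions)))
    ax.set_xticklabels(conditions)
    ax.set_ylabel(value)
    return ax


# ---------------------------------------------------------------------------
# readers


def _tracks_from_tidy(df: pd.DataFrame, frame_interval: float) -> list[Track]:
    tracks = []
    for (cell, exp, cond), g in df.groupby(
        ["cell_id", "experiment_id", "condition"], sort=True
    ):
        g = g.sort_values("frame")
        tracks.append(
            Track(
                cell_id=str(cell),
                experiment_id=str(exp),
                condition=str(cond),
                t=g["frame"].to_numpy(dtype=float) * frame_interval,
                xy=g[["x_um", "y_um"]].to_numpy(dtype=float),
                frame_interval=frame_interval,
            )
        )
    return tracks


def read_tracks(
    path_or_buffer,
    frame_interval: float,
    pixel_size: float = 1.0,
    experiment_id: str = "exp1",
    condition: str = "default",
) -> list[Track]:
    """Read tracks from tidy text or a Fiji Manual Tracking export.

    The native tidy dialect has columns cell_id, experiment_id, condition,
    frame, x_um, y_um.  The Fiji Manual Tracking dialect is auto-detected
    from columns containing "Track" and "Slice" (positions in pixels,
    converted with ``pixel_size``; ``experiment_id``/``condition`` label all
    tracks in the file).  ``frame_interval`` is in minutes.
    """
    if frame_interval <= 0:
        raise ValueError("frame_interval must be positive")
    df = pd.read_csv(path_or_buffer, sep=None, engine="python")
    cols = {c.strip().lower(): c for c in df.columns}
    if "cell_id" in cols and "x_um" in cols:
        df = df.rename(columns={v: k for k, v in cols.items()})
        return _tracks_from_tidy(df, frame_interval)
    track_col = next((cols[k] for k in cols if "track" in k), None)
    slice_col = next(
        (cols[k] for k in cols if "slice" in k or "frame" in k), None
    )
    x_col = next((cols[k] for k in cols if k.rstrip(" °no.") == "x"), None)
    y_col = next((cols[k] for k in cols if k.rstrip(" °no.") == "y"), None)
    if None in (track_col, slice_col, x_col, y_col):
        raise ValueError(
            "unrecognized track table: expected tidy columns "
            "(cell_id, experiment_id, condition, frame, x_um, y_um) or a "
            "Manual Tracking export (Track, Slice, X, Y)"
        )
    tracks = []
    for tid, g in df.groupby(track_col, sort=True):
        g = g.sort_values(slice_col)
        tracks.append(
            Track(
                cell_id=str(tid),
                experiment_id=experiment_id,
                condition=condition,
                t=g[slice_col].to_numpy(dtype=float) * frame_interval,
                xy=g[[x_col, y_col]].to_numpy(dtype=float) * pixel_size,
                frame_interval=frame_interval,
            )
        )
    return tracks


def write_tracks(tracks: list[Track], path) -> None:
    """Write tracks in the native tidy dialect (frame inferred from t)."""
    rows = []
    for tr in tracks:
        frames = np.round(tr.t / tr.frame_interval).astype(int)
        for f, (x, y) in zip(frames, tr.xy):
            rows.append(
                {
                    "cell_id": tr.cell_id,
                    "experiment_id": tr.experiment_id,
                    "condition": tr.condition,
                    "frame": f,
                    "x_um": x,
                    "y_um": y,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
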