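"""Cell-shape descriptors from closed outline polygons.

All geometry is exact polygon arithmetic (shoelace moments, polygon
clipping via shapely); nothing is rasterized unless clipping fails on a
pathological input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely import affinity
from shapely.geometry import Point, Polygon

logger = logging.getLogger(__name__)

__all__ = [
    "Contour",
    "ShapeDescriptors",
    "polygon_area_perimeter",
    "principal_axes",
    "symmetry",
    "convexity_metrics",
    "center_distances",
    "describe",
    "shape_table",
]


@dataclass(frozen=True, eq=False)
class Contour:
    """Closed, simple planar polygon of a cell outline (um).

    Vertices are normalized to counterclockwise orientation at ingest; the
    closing vertex is implicit (do not repeat the first point).
    """

    vertices: np.ndarray
    cell_id: str = "cell"
    experiment_id: str = "exp1"
    condition: str = "default"

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("contour needs an (n>=3, 2) vertex array")
        if not np.all(np.isfinite(v)):
            raise ValueError("vertices must be finite")
        if np.allclose(v[0], v[-1]):
            v = v[:-1]
        if v.shape[0] < 3:
            raise ValueError("contour needs at least 3 distinct vertices")
        poly = Polygon(v)
        if not poly.is_valid or poly.area == 0:
            raise ValueError("contour must be simple with nonzero area")
        # normalize to counterclockwise (positive signed area)
        signed = 0.5 * np.sum(
            v[:, 0] * np.roll(v[:, 1], -1) - np.roll(v[:, 0], -1) * v[:, 1]
        )
        if signed < 0:
            v = v[::-1].copy()
        object.__setattr__(self, "vertices", v)

    def polygon(self) -> Polygon:
        return Polygon(self.vertices)


@dataclass(frozen=True)
class ShapeDescriptors:
    area: float
    perimeter: float
    major_axis: float
    minor_axis: float
    aspect_ratio: float  # minor / major
    symmetry: float
    convex_area: float
    solidity: float
    extent: float
    max_center_distance: float
    min_center_distance: float


def polygon_area_perimeter(contour: Contour) -> tuple[float, float]:
    """Shoelace area (absolute) and closed-perimeter length."""
    v = contour.vertices
    nxt = np.roll(v, -1, axis=0)
    area = 0.5 * abs(np.sum(v[:, 0] * nxt[:, 1] - nxt[:, 0] * v[:, 1]))
    if area == 0:
        raise ValueError("degenerate zero-area polygon")
    perimeter = float(np.hypot(*(nxt - v).T).sum())
    return float(area), perimeter


def _polygon_moments(v: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Signed area, centroid, and central second-moment (covariance) matrix.

    Exact area-weighted moments of the polygon interior via the standard
    shoelace extensions.
    """
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    A = 0.5 * cross.sum()
    if A == 0:
        raise ValueError("degenerate polygon")
    cx = np.sum((x + xn) * cross) / (6.0 * A)
    cy = np.sum((y + yn) * cross) / (6.0 * A)
    # raw second moments about the origin
    ixx = np.sum((x**2 + x * xn + xn**2) * cross) / 12.0
    iyy = np.sum((y**2 + y * yn + yn**2) * cross) / 12.0
    ixy = np.sum((x * yn + 2 * x * y + 2 * xn * yn + xn * y) * cross) / 24.0
    # central, normalized by area -> covariance of the uniform interior
    cov = np.array(
        [
            [ixx / A - cx**2, ixy / A - cx * cy],
            [ixy / A - cx * cy, iyy / A - cy**2],
        ]
    )
    return A, np.array([cx, cy]), cov


def principal_axes(contour: Contour) -> tuple[float, float, float]:
    """Equivalent-ellipse axis lengths and orientation.

    Returns (major_axis, minor_axis, orientation_rad); axis length is
    ``4 * sqrt(eigenvalue)`` of the interior covariance so that an ellipse
    with semi-axes (a, b) yields (2a, 2b).  Orientation is the major
    eigenvector angle in radians; arbitrary (0) for isotropic shapes.
    """
    _, _, cov = _polygon_moments(contour.vertices)
    evals, evecs = np.linalg.eigh(cov)
    major = 4.0 * np.sqrt(evals[1])
    minor = 4.0 * np.sqrt(evals[0])
    if np.isclose(evals[0], evals[1]):
        logger.debug("isotropic contour %s: orientation arbitrary", contour.cell_id)
        return float(major), float(minor), 0.0
    vx, vy = evecs[:, 1]
    return float(major), float(minor), float(np.arctan2(vy, vx))


def symmetry(contour: Contour, variant: str = "overlap") -> float:
    """Mirror symmetry about the major axis through the centroid.

    ``'overlap'`` (default): area(original & reflected) / area(original) —
    1 iff mirror-symmetric.  ``'union'``: area / area(original | reflected).
    """
    _, centroid, _ = _polygon_moments(contour.vertices)
    _, _, theta = principal_axes(contour)
    poly = contour.polygon()
    origin = tuple(centroid)
    # reflect across the major-axis line: rotate it onto x, flip y, rotate back
    rot = affinity.rotate(poly, -np.degrees(theta), origin=origin)
    mirrored = affinity.scale(rot, xfact=1, yfact=-1, origin=origin)
    reflected = affinity.rotate(mirrored, np.degrees(theta), origin=origin)
    try:
        if variant == "overlap":
            return float(poly.intersection(reflected).area / poly.area)
        if variant == "union":
            return float(poly.area / poly.union(reflected).area)
    except Exception as exc:  # pragma: no cover - shapely failure path
        raise ValueError(f"reflection overlap failed: {exc}") from exc
    raise ValueError(f"unknown symmetry variant {variant!r}")


def convexity_metrics(contour: Contour) -> tuple[float, float, float]:
    """(convex_area, solidity, extent).

    Solidity is area over convex-hull area; extent is area over the
    axis-aligned bounding-box area (image frame, not principal frame).
    """
    poly = contour.polygon()
    hull_area = poly.convex_hull.area
    minx, miny, maxx, maxy = poly.bounds
    bbox_area = (maxx - minx) * (maxy - miny)
    # both ratios are <= 1 mathematically; clip float-epsilon overshoot
    return (
        float(hull_area),
        min(float(poly.area / hull_area), 1.0),
        min(float(poly.area / bbox_area), 1.0),
    )


def center_distances(contour: Contour) -> tuple[float, float]:
    """(max, min) distance from the area centroid to the outline.

    Max over vertices; min over boundary segments.  Computed (and logged)
    even when the centroid falls outside the polygon.
    """
    _, centroid, _ = _polygon_moments(contour.vertices)
    poly = contour.polygon()
    pt = Point(centroid)
    if not poly.contains(pt):
        logger.warning(
            "centroid of contour %s lies outside the polygon", contour.cell_id
        )
    dmax = float(np.hypot(*(contour.vertices - centroid).T).max())
    dmin = float(poly.exterior.distance(pt))
    return dmax, dmin


def describe(contour: Contour, symmetry_variant: str = "overlap") -> ShapeDescriptors:
    """All shape descriptors for one contour."""
    area, perim = polygon_area_perimeter(contour)
    major, minor, _ = principal_axes(contour)
    sym = symmetry(contour, variant=symmetry_variant)
    convex_area, solidity, extent = convexity_metrics(contour)
    dmax, dmin = center_distances(contour)
    return ShapeDescriptors(
        area=area,
        perimeter=perim,
        major_axis=major,
        minor_axis=minor,
        aspect_ratio=minor / major,
        symmetry=sym,
        convex_area=convex_area,
        solidity=solidity,
        extent=extent,
        max_center_distance=dmax,
        min_center_distance=dmin,
    )


def shape_table(
    contours: list[Contour], symmetry_variant: str = "overlap"
) -> pd.DataFrame:
    """One descriptor row per cell; failing contours are logged and skipped."""
    if not contours:
        raise ValueError("at least one contour required")
    rows = []
    for c in contours:
        try:
            d = describe(c, symmetry_variant=symmetry_variant)
        except ValueError as exc:
            logger.warning("contour %s skipped: %s", c.cell_id, exc)
            continue
        rows.append(
            {
                "cell_id": c.cell_id,
                "experiment_id": c.experiment_id,
                "condition": c.condition,
                **d.__dict__,
            }
        )
    return pd.DataFrame(rows)


def read_contours(path_or_buffer) -> list[Contour]:
    """Read contours from delimited text.

    Expected columns: cell_id, vertex_index, x_um, y_um and optionally
    experiment_id, condition.
    """
    df = pd.read_csv(path_or_buffer, sep=None, engine="python")
    needed = {"cell_id", "vertex_index", "x_um", "y_um"}
    if not needed <= set(df.columns):
        raise ValueError(f"contour table must have columns {sorted(needed)}")
    out = []
    for cid, g in df.groupby("cell_id", sort=True):
        g = g.sort_values("vertex_index")
        out.append(
            Contour(
                vertices=g[["x_um", "y_um"]].to_numpy(dtype=float),
                cell_id=str(cid),
                experiment_id=str(g["experiment_id"].iloc[0])
                if "experiment_id" in g
                else "exp1",
                condition=str(g["condition"].iloc[0]) if "condition" in g else "default",
            )
        )
    return out


def write_contours(contours: list[Contour], path) -> None:
    rows = []
    for c in contours:
        for i, (x, y) in enumerate(c.vertices):
            rows.append(
                {
                    "cell_id": c.cell_id,
                    "experiment_id": c.experiment_id,
                    "condition": c.condition,
                    "vertex_index": i,
                    "x_um": x,
                    "y_um": y,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
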