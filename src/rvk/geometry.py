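"""Annular and ventricular geometry from crystal coordinates.

Scalar geometry at a time point: tricuspid annular area (TAA, mm^2), percent
annular area reduction between states, convex-hull volume over all crystals
(ml), and per-parallel cross-sectional area (CSA, mm^2) and radius of
curvature (ROC, mm).

Planarity handling: the annulus and the free-wall parallels are not planar,
so areas are measured on the orthogonal projection onto the least-squares
plane of the points (an alternative 3-D centroid-fan triangulation is
available via ``method='fan'`` for sensitivity checks).  ROC is a 2-D circle
fit in the row's best-fit plane: a Kasa algebraic fit refined by one
geometric Gauss-Newton pass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .cycles import AveragedBeat
from .errors import DegeneracyError, ParameterError, SchemaError
from .recording import ChannelRecording, CrystalLayout

__all__ = [
    "fit_plane",
    "polygon_area_3d",
    "annular_area",
    "percent_area_reduction",
    "convex_hull_volume",
    "cross_sectional_area",
    "fit_circle_radius",
    "StateGeometry",
    "GeometrySummary",
    "geometry_summary",
]

MM3_PER_ML = 1000.0


def _frame_points(
    obj: AveragedBeat | ChannelRecording | Mapping[str, np.ndarray],
    labels: Sequence[str],
    timepoint,
) -> np.ndarray:
    """Positions of ``labels`` at ``timepoint`` as an (n, 3) array."""
    if isinstance(obj, AveragedBeat):
        frame = obj.frame(timepoint)
    elif isinstance(obj, ChannelRecording):
        frame = obj.frame(int(timepoint))
    else:
        frame = obj
    try:
        return np.array([frame[lab] for lab in labels], dtype=float)
    except KeyError as e:
        raise SchemaError(f"missing crystal {e.args[0]!r}") from e


def fit_plane(
    points: np.ndarray, orient_axis: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Total-least-squares plane through >= 3 points: ``(centroid, unit normal)``.

    Minimizes the sum of squared orthogonal distances (SVD of the centered
    points).  The normal sign is fixed deterministically: along
    ``orient_axis`` when given, otherwise so that its largest-magnitude
    component is positive.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 3:
        raise ParameterError("need >= 3 points of dimension 3")
    centroid = pts.mean(axis=0)
    _, s, vt = np.linalg.svd(pts - centroid, full_matrices=False)
    if s[0] <= 0 or s[1] <= 1e-9 * s[0]:
        raise DegeneracyError("points are collinear or coincident; no unique plane")
    normal = vt[2]
    if orient_axis is not None:
        if np.dot(normal, orient_axis) < 0:
            normal = -normal
    elif normal[np.argmax(np.abs(normal))] < 0:
        normal = -normal
    return centroid, normal


def _plane_coords(points: np.ndarray) -> np.ndarray:
    """2-D coordinates of points projected onto their best-fit plane."""
    pts = np.asarray(points, dtype=float)
    centroid = pts.mean(axis=0)
    _, s, vt = np.linalg.svd(pts - centroid, full_matrices=False)
    if s[0] <= 0 or s[1] <= 1e-9 * s[0]:
        raise DegeneracyError("points are collinear or coincident")
    return (pts - centroid) @ vt[:2].T


def _segments_intersect(p, q, r, s) -> bool:
    def orient(a, b, c):
        return np.sign(
            (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
        )

    return (
        orient(p, q, r) * orient(p, q, s) < 0
        and orient(r, s, p) * orient(r, s, q) < 0
    )


def polygon_area_3d(
    ordered_points: np.ndarray, *, check_self_intersection: bool = True
) -> float:
    """Area (mm^2) of a closed polygon of 3-D points in circumferential order.

    The points are orthogonally projected onto their least-squares plane and
    the shoelace area of the projected polygon is returned (non-negative).  A
    self-intersecting projection triggers a warning but still returns the
    shoelace value.
    """
    pts = np.asarray(ordered_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 3:
        raise ParameterError("polygon needs >= 3 points of dimension 3")
    uv = _plane_coords(pts)
    x, y = uv[:, 0], uv[:, 1]
    area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    if check_self_intersection and len(uv) > 3:
        n = len(uv)
        for i in range(n):
            a, b = uv[i], uv[(i + 1) % n]
            for j in range(i + 2, n):
                if i == 0 and j == n - 1:
                    continue
                c, d = uv[j], uv[(j + 1) % n]
                if _segments_intersect(a, b, c, d):
                    warnings.warn("projected polygon is self-intersecting")
                    return area
    return area


def _fan_area_3d(pts: np.ndarray) -> float:
    """Sum of 3-D triangle areas fanned from the centroid (non-planar variant)."""
    centroid = pts.mean(axis=0)
    a = pts - centroid
    b = np.roll(pts, -1, axis=0) - centroid
    return float(0.5 * np.linalg.norm(np.cross(a, b), axis=1).sum())


def annular_area(
    obj, layout: CrystalLayout, timepoint="ED", method: str = "plane"
) -> float:
    """Tricuspid annular area (mm^2) from the 6 ordered annular crystals.

    ``method='plane'`` (default) projects onto the annular best-fit plane;
    ``method='fan'`` sums 3-D centroid-fan triangle areas (sensitivity check
    for annular non-planarity).
    """
    pts = _frame_points(obj, layout.annular, timepoint)
    if method == "plane":
        return polygon_area_3d(pts)
    if method == "fan":
        return _fan_area_3d(pts)
    raise ParameterError(f"unknown method {method!r}")


def percent_area_reduction(area_baseline: float, area_tra: float) -> float:
    """Percent area reduction ``100 * (1 - A_tra / A_baseline)``."""
    if area_baseline <= 0 or area_tra <= 0:
        raise ParameterError("areas must be > 0")
    return 100.0 * (1.0 - area_tra / area_baseline)


def convex_hull_volume(points: np.ndarray) -> float:
    """Convex-hull volume of >= 4 non-coplanar 3-D points, in ml (mm^3/1000)."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 4:
        raise ParameterError("hull needs >= 4 points of dimension 3")
    try:
        hull = ConvexHull(pts)
    except QhullError as e:
        raise DegeneracyError(f"degenerate point set for convex hull: {e}") from e
    return hull.volume / MM3_PER_ML


def rv_hull_volume(obj, layout: CrystalLayout, timepoint="ED") -> float:
    """RV hull volume (ml) over all 20 crystals (annular + free wall + apex)."""
    pts = _frame_points(obj, layout.all_labels, timepoint)
    return convex_hull_volume(pts)


def cross_sectional_area(obj, layout: CrystalLayout, row: str, timepoint="ED") -> float:
    """Cross-sectional area (mm^2) of one free-wall parallel.

    The row's crystals cover the free wall only, so the polygon is closed by
    the chord between the end crystals (a documented convention).  Collinear
    rows return 0 with a warning.
    """
    if row not in layout.parallels:
        raise ParameterError(f"layout has no row {row!r}")
    labels = layout.parallels[row]
    if len(labels) < 3:
        raise ParameterError(f"row {row!r} has {len(labels)} crystals, need >= 3")
    pts = _frame_points(obj, labels, timepoint)
    try:
        return polygon_area_3d(pts)
    except DegeneracyError:
        warnings.warn(f"row {row!r} crystals are collinear; CSA set to 0")
        return 0.0


def fit_circle_radius(points: np.ndarray) -> float:
    """Radius (mm) of the least-squares circle through >= 3 points.

    Points are projected onto their best-fit plane; a Kasa algebraic fit is
    refined by one geometric Gauss-Newton step.  Exact on noise-free circular
    data (for n = 3 this is the circumscribed circle).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 3:
        raise ParameterError("circle fit needs >= 3 points of dimension 3")
    uv = _plane_coords(pts)
    x, y = uv[:, 0], uv[:, 1]
    A = np.column_stack([x, y, np.ones_like(x)])
    b = x * x + y * y
    try:
        sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    except np.linalg.LinAlgError as e:  # pragma: no cover
        raise DegeneracyError(str(e)) from e
    cx, cy = sol[0] / 2.0, sol[1] / 2.0
    r2 = sol[2] + cx * cx + cy * cy
    if not np.isfinite(r2) or r2 <= 0:
        raise DegeneracyError("circle fit degenerate")
    r = float(np.sqrt(r2))
    # one Gauss-Newton pass on sum((|p - c| - r)^2)
    d = np.hypot(x - cx, y - cy)
    if np.all(d > 0):
        ux, uy = (x - cx) / d, (y - cy) / d
        J = np.column_stack([-ux, -uy, -np.ones_like(d)])
        res = d - r
        step, *_ = np.linalg.lstsq(J, -res, rcond=None)
        cx, cy, r = cx + step[0], cy + step[1], r + step[2]
    if r <= 0 or not np.isfinite(r):
        raise DegeneracyError("circle fit did not converge to a positive radius")
    return float(r)


def radius_of_curvature(obj, layout: CrystalLayout, row: str, timepoint="ED") -> float:
    """In-plane radius of curvature (mm) of one free-wall parallel."""
    if row not in layout.parallels:
        raise ParameterError(f"layout has no row {row!r}")
    pts = _frame_points(obj, layout.parallels[row], timepoint)
    return fit_circle_radius(pts)


@dataclass(frozen=True)
class StateGeometry:
    """Scalar geometry of one state at one timepoint; absent rows are None."""

    state_tag: str
    timepoint: str
    taa_mm2: float
    edv_ml: float
    csa_mm2: dict[str, float | None]
    roc_mm: dict[str, float | None]


@dataclass(frozen=True)
class GeometrySummary:
    """Baseline/TRA geometry pair with deltas and percent annular reduction."""

    baseline: StateGeometry
    tra: StateGeometry
    taa_reduction_pct: float
    deltas: dict[str, float | None]


def _state_geometry(beat: AveragedBeat, layout: CrystalLayout,
                    timepoint: str) -> StateGeometry:
    csa: dict[str, float | None] = {}
    roc: dict[str, float | None] = {}
    for row in ("basal", "mid", "lower"):
        if row in layout.parallels and len(layout.parallels[row]) >= 3:
            csa[row] = cross_sectional_area(beat, layout, row, timepoint)
            roc[row] = radius_of_curvature(beat, layout, row, timepoint)
        else:
            csa[row] = None
            roc[row] = None
    return StateGeometry(
        state_tag=beat.state_tag,
        timepoint=timepoint,
        taa_mm2=annular_area(beat, layout, timepoint),
        edv_ml=rv_hull_volume(beat, layout, timepoint),
        csa_mm2=csa,
        roc_mm=roc,
    )


def geometry_summary(
    baseline: AveragedBeat,
    tra: AveragedBeat,
    layout: CrystalLayout,
    timepoint: str = "ED",
) -> GeometrySummary:
    """Paired geometry summary at one timepoint (default ED).

    Returns TAA, hull EDV, and per-row CSA/ROC for both states, the percent
    annular area reduction, and TRA-minus-Baseline deltas (None where a row is
    absent from the layout).
    """
    base = _state_geometry(baseline, layout, timepoint)
    post = _state_geometry(tra, layout, timepoint)
    deltas: dict[str, float | None] = {
        "taa_mm2": post.taa_mm2 - base.taa_mm2,
        "edv_ml": post.edv_ml - base.edv_ml,
    }
    for row in ("basal", "mid", "lower"):
        for name, b, t in (
            (f"csa_{row}_mm2", base.csa_mm2[row], post.csa_mm2[row]),
            (f"roc_{row}_mm", base.roc_mm[row], post.roc_mm[row]),
        ):
            deltas[name] = None if b is None or t is None else t - b
    return GeometrySummary(
        baseline=base,
        tra=post,
        taa_reduction_pct=percent_area_reduction(base.taa_mm2, post.taa_mm2),
        deltas=deltas,
    )
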