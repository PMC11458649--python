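"""Landmark-derived geometry of a fundus photograph.

All quantities are computed from manually placed landmarks: the fovea, points
on the optic nerve head (disc) edge, and the crossing points of the four major
temporal vessels (supratemporal/infratemporal artery and vein).

Coordinate convention (stated once, used everywhere): image raster coordinates
with the origin at the top-left corner, x increasing rightward (columns), y
increasing downward (rows), 0-based floating-point pixels. "Superior" on the
retina is therefore *decreasing* y.

Angle conventions:

* All vessel angles are unsigned magnitudes in [0, 180] degrees, measured from
  the *temporal horizontal* — the horizontal ray from the disc center toward
  the side the fovea is on. Using the fovea to orient the reference makes the
  same code handle right and left eyes.
* The papillomacular position (PMP) is the signed angle between the horizontal
  and the disc-center→fovea line; positive when the fovea sits inferior to
  (image-y greater than) the disc center.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, NamedTuple, Sequence

import numpy as np
from scipy.spatial import ConvexHull

from .errors import (
    DegenerateGeometryError,
    InvalidLandmarksError,
    UndefinedTemporalError,
)

__all__ = [
    "Point2D",
    "LandmarkSet",
    "DiscGeometry",
    "RoiConfig",
    "RoiLayout",
    "PERIPAPILLARY_LOCATIONS",
    "LOCATIONS",
    "disc_geometry",
    "temporal_direction",
    "vessel_angle",
    "pmp_angle",
    "roi_layout",
]


class Point2D(NamedTuple):
    """A location on the image raster, in 0-based floating-point pixels."""

    x: float
    y: float


#: The eight peripapillary compass locations, in placement order: starting at
#: temporal and stepping 45 degrees through supratemporal (i.e. toward
#: superior, decreasing image-y).
PERIPAPILLARY_LOCATIONS: tuple[str, ...] = (
    "temporal",
    "supratemporal",
    "superior",
    "supranasal",
    "nasal",
    "infranasal",
    "inferior",
    "infratemporal",
)

#: All nine sampled locations (the eight peripapillary ones plus the fovea).
LOCATIONS: tuple[str, ...] = PERIPAPILLARY_LOCATIONS + ("fovea",)


def _as_points(points: Iterable[Sequence[float]]) -> np.ndarray:
    arr = np.asarray(list(points), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise InvalidLandmarksError(f"expected an (N, 2) point array, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise InvalidLandmarksError("landmark coordinates must be finite")
    return arr


@dataclass(frozen=True)
class LandmarkSet:
    """Manual annotations for one eye.

    Parameters
    ----------
    fovea
        Foveal center.
    disc_boundary
        At least 8 points on the optic nerve head edge.
    crossing_st_artery, crossing_it_artery, crossing_st_vein, crossing_it_vein
        Clicked points on the supratemporal / infratemporal major retinal
        artery and vein.
    laterality
        Which eye the image shows. Used only for consistency warnings; the
        temporal direction itself is always derived from the fovea position.
    """

    fovea: Point2D
    disc_boundary: tuple[Point2D, ...]
    crossing_st_artery: Point2D
    crossing_it_artery: Point2D
    crossing_st_vein: Point2D
    crossing_it_vein: Point2D
    laterality: Literal["right", "left"] = "right"

    def __post_init__(self) -> None:
        object.__setattr__(self, "fovea", Point2D(*map(float, self.fovea)))
        object.__setattr__(
            self,
            "disc_boundary",
            tuple(Point2D(*map(float, p)) for p in self.disc_boundary),
        )
        for name in ("crossing_st_artery", "crossing_it_artery", "crossing_st_vein", "crossing_it_vein"):
            object.__setattr__(self, name, Point2D(*map(float, getattr(self, name))))
        if self.laterality not in ("right", "left"):
            raise InvalidLandmarksError(f"laterality must be 'right' or 'left', got {self.laterality!r}")
        self.validate()

    @property
    def crossings(self) -> dict[str, Point2D]:
        return {
            "st_artery": self.crossing_st_artery,
            "it_artery": self.crossing_it_artery,
            "st_vein": self.crossing_st_vein,
            "it_vein": self.crossing_it_vein,
        }

    def validate(self) -> None:
        """Check the landmark contract; raise :class:`InvalidLandmarksError`."""
        boundary = _as_points(self.disc_boundary)
        if len(boundary) < 8:
            raise InvalidLandmarksError(
                f"disc boundary needs at least 8 points, got {len(boundary)}"
            )
        center = boundary.mean(axis=0)
        scale = max(1.0, float(np.abs(boundary - center).max()))
        for name, p in self.crossings.items():
            if np.hypot(p.x - center[0], p.y - center[1]) <= 1e-9 * scale:
                raise InvalidLandmarksError(f"crossing point {name} coincides with the disc center")
        if _point_in_convex_hull(np.array(self.fovea, dtype=float), boundary):
            raise InvalidLandmarksError("fovea lies inside the disc boundary convex hull")

    def mirrored(self, width: float) -> "LandmarkSet":
        """The same landmarks on the horizontally mirrored image of given width.

        Maps x -> (width - 1) - x and flips the laterality tag, which is the
        raster transform taking a right eye to the equivalent left eye.
        """
        flip = lambda p: Point2D(width - 1.0 - p.x, p.y)  # noqa: E731
        return LandmarkSet(
            fovea=flip(self.fovea),
            disc_boundary=tuple(flip(p) for p in self.disc_boundary),
            crossing_st_artery=flip(self.crossing_st_artery),
            crossing_it_artery=flip(self.crossing_it_artery),
            crossing_st_vein=flip(self.crossing_st_vein),
            crossing_it_vein=flip(self.crossing_it_vein),
            laterality="left" if self.laterality == "right" else "right",
        )


@dataclass(frozen=True)
class DiscGeometry:
    """Optic disc summary: centroid, mean radius, and ovality ratio (max/min
    Feret diameter of the boundary point set, always >= 1)."""

    center: Point2D
    radius: float
    ovality: float


@dataclass(frozen=True)
class RoiConfig:
    """Geometry of the sampling circles, in units of the disc radius.

    ``center_dist_mult`` — distance of the eight peripapillary ROI centers
    from the disc center; ``roi_radius_mult`` — radius of every sampling
    circle. Defaults put eight non-overlapping circles in a ring just outside
    the disc.
    """

    center_dist_mult: float = 1.7
    roi_radius_mult: float = 0.5

    def __post_init__(self) -> None:
        if not (self.center_dist_mult > 0 and self.roi_radius_mult > 0):
            raise ValueError("RoiConfig multipliers must be positive")


@dataclass(frozen=True)
class RoiLayout:
    """Centers and common radius of the nine sampling circles."""

    peripapillary_centers: tuple[Point2D, ...]  # ordered as PERIPAPILLARY_LOCATIONS
    fovea_center: Point2D
    roi_radius: float

    @property
    def centers(self) -> dict[str, Point2D]:
        out = dict(zip(PERIPAPILLARY_LOCATIONS, self.peripapillary_centers))
        out["fovea"] = self.fovea_center
        return out


def _point_in_convex_hull(point: np.ndarray, points: np.ndarray, tol: float = 1e-9) -> bool:
    """True if ``point`` lies inside (or on) the convex hull of ``points``."""
    try:
        hull = ConvexHull(points)
    except Exception:
        # Degenerate (collinear) boundary: treat as "not containing" and let
        # disc_geometry raise the more specific error.
        return False
    # hull.equations: rows [a, b, c] with a*x + b*y + c <= 0 inside.
    return bool(np.all(hull.equations[:, :2] @ point + hull.equations[:, 2] <= tol))


def max_feret_diameter(points: np.ndarray) -> float:
    """Longest caliper diameter: the maximum pairwise distance of the set."""
    points = _as_points(points)
    if len(points) > 64:
        # the diameter endpoints are hull vertices; restrict to those
        try:
            points = points[ConvexHull(points).vertices]
        except Exception:
            pass
    if len(points) > 2048:
        # very dense boundaries: keep only directional extremes (0.25-degree
        # grid), which bracket the diameter pair to ~1e-9 relative error
        theta = np.deg2rad(np.arange(0.0, 180.0, 0.25))
        dirs = np.stack([np.cos(theta), np.sin(theta)], axis=1)
        proj = points @ dirs.T
        keep = np.unique(np.concatenate([proj.argmax(axis=0), proj.argmin(axis=0)]))
        points = points[keep]
    diff = points[:, None, :] - points[None, :, :]
    return float(np.sqrt((diff**2).sum(-1)).max())


def min_feret_width(points: np.ndarray, step_deg: float = 0.5) -> float:
    """Narrowest caliper width: minimum over directions of the projection extent.

    Directions are sampled every ``step_deg`` degrees over a half turn, which
    bounds the relative overestimate by ``1 - cos(step/2)`` (< 1e-5 at the
    default step).
    """
    points = _as_points(points)
    theta = np.deg2rad(np.arange(0.0, 180.0, step_deg))
    dirs = np.stack([np.cos(theta), np.sin(theta)], axis=1)  # (K, 2)
    proj = points @ dirs.T  # (N, K)
    widths = proj.max(axis=0) - proj.min(axis=0)
    return float(widths.min())


def disc_geometry(landmarks_or_boundary) -> DiscGeometry:
    """Summarize the optic disc from its boundary points.

    Accepts either a :class:`LandmarkSet` or a bare sequence of boundary
    points. The center is the arithmetic centroid, the radius the mean
    centroid-to-boundary distance, and the ovality ratio the maximum Feret
    diameter divided by the minimum Feret width of the point set — the
    operational form of "maximum disc diameter / minimum disc diameter" for a
    clicked boundary.
    """
    if isinstance(landmarks_or_boundary, LandmarkSet):
        boundary = _as_points(landmarks_or_boundary.disc_boundary)
    else:
        boundary = _as_points(landmarks_or_boundary)
    if len(boundary) < 8:
        raise InvalidLandmarksError(f"disc boundary needs at least 8 points, got {len(boundary)}")
    center = boundary.mean(axis=0)
    radius = float(np.hypot(*(boundary - center).T).mean())
    if radius <= 0:
        raise DegenerateGeometryError("disc boundary points are coincident")
    sv = np.linalg.svd(boundary - center, compute_uv=False)
    if sv[-1] <= 1e-12 * sv[0]:
        raise DegenerateGeometryError("disc boundary is collinear (zero minimum Feret width)")
    width = min_feret_width(boundary)
    if width <= 0:
        raise DegenerateGeometryError("disc boundary is collinear (zero minimum Feret width)")
    ovality = max_feret_diameter(boundary) / width
    return DiscGeometry(center=Point2D(*center), radius=radius, ovality=float(ovality))


def temporal_direction(disc_center: Point2D, fovea: Point2D) -> np.ndarray:
    """Unit vector of the temporal horizontal: (+1, 0) when the fovea lies to
    the right of the disc center, (-1, 0) when to the left."""
    dx = fovea[0] - disc_center[0]
    if dx == 0:
        raise UndefinedTemporalError(
            "fovea is vertically aligned with the disc center; temporal side undefined"
        )
    return np.array([1.0 if dx > 0 else -1.0, 0.0])


def vessel_angle(disc_center: Point2D, crossing: Point2D, temporal: np.ndarray) -> float:
    """Unsigned angle (degrees, [0, 180]) between the disc-center→crossing ray
    and the temporal horizontal."""
    v = np.array([crossing[0] - disc_center[0], crossing[1] - disc_center[1]], dtype=float)
    norm = np.hypot(*v)
    if norm == 0:
        raise DegenerateGeometryError("vessel crossing point coincides with the disc center")
    t = np.asarray(temporal, dtype=float)
    cosang = float(np.clip(np.dot(v, t) / (norm * np.hypot(*t)), -1.0, 1.0))
    return float(np.degrees(np.arccos(cosang)))


def pmp_angle(disc_center: Point2D, fovea: Point2D, temporal: np.ndarray | None = None) -> float:
    """Papillomacular position: signed angle (degrees, (-90, 90)) between the
    horizontal and the disc-center→fovea line.

    Positive when the fovea is inferior to the disc center (greater image-y).
    The magnitude uses |dx|, so the value is invariant under horizontal
    mirroring (laterality change).
    """
    dx = fovea[0] - disc_center[0]
    dy = fovea[1] - disc_center[1]
    if dx == 0:
        raise UndefinedTemporalError(
            "fovea is vertically aligned with the disc center; PMP undefined"
        )
    return float(np.degrees(np.arctan2(dy, abs(dx))))


def roi_layout(
    disc: DiscGeometry,
    temporal: np.ndarray,
    fovea: Point2D,
    config: RoiConfig | None = None,
) -> RoiLayout:
    """Place the nine sampling circles.

    The eight peripapillary centers sit at ``center_dist_mult * disc.radius``
    from the disc center, 45 degrees apart, starting at the temporal direction
    and stepping through supratemporal (toward superior, i.e. decreasing
    image-y). The ninth circle is centered on the fovea. All circles share
    radius ``roi_radius_mult * disc.radius``.
    """
    config = config or RoiConfig()
    tx = float(np.sign(np.asarray(temporal, dtype=float)[0]))
    if tx == 0:
        raise UndefinedTemporalError("temporal direction has no horizontal component")
    dist = config.center_dist_mult * disc.radius
    centers = []
    for k in range(8):
        ang = np.deg2rad(45.0 * k)
        # rotate from temporal toward superior (-y); nasal side mirrors in x
        direction = np.array([tx * np.cos(ang), -np.sin(ang)])
        c = np.array(disc.center) + dist * direction
        centers.append(Point2D(*c))
    return RoiLayout(
        peripapillary_centers=tuple(centers),
        fovea_center=Point2D(*fovea),
        roi_radius=config.roi_radius_mult * disc.radius,
    )
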