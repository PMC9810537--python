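"""In-plane contour geometry shared by the slicing and estimator layers.

A :class:`Contour2D` is the open endocardial boundary of one apical view:
an ordered polyline running from one basal (mitral-annulus) corner, around
the apex, to the other basal corner.  The basal segment — the chord between
the two endpoints — closes the cavity conceptually but is never traced, which
matches clinical practice where the annulus line closes the tracing.

All coordinates are millimetres.  Angles cross the public interface in
degrees and are converted to radians internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString, Polygon

__all__ = ["Contour2D", "ContourError"]


class ContourError(ValueError):
    """Raised when a contour violates its geometric invariants."""


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ContourError(f"expected an (N, 2) point array, got shape {pts.shape}")
    return pts


@dataclass(frozen=True)
class Contour2D:
    """Open in-plane endocardial boundary of one apical view.

    Parameters
    ----------
    points
        Ordered (N, 2) array, basal corner 1 → apex region → basal corner 2.
        The polyline must be simple (non-self-intersecting) and have at
        least 10 points.

    Derived geometry (all lazy properties):

    * ``basal_corners`` — the two endpoints.
    * ``basal_midpoint`` — midpoint of the basal chord.
    * ``apex`` — contour point farthest from the basal midpoint.
    * ``long_axis_length`` — ``L_view``, apex to basal midpoint.
    * ``slant_angle_deg`` — ``bθ_view``, signed angle between the basal chord
      and the perpendicular to the apex → basal-midpoint line; positive when
      corner 2 sits higher (closer to the apex side) than corner 1.
    """

    points: np.ndarray
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __init__(self, points, validate: bool = True):
        object.__setattr__(self, "points", _as_points(points))
        object.__setattr__(self, "_cache", {})
        if validate:
            self.validate()

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        pts = self.points
        if len(pts) < 10:
            raise ContourError(f"contour needs >= 10 points, got {len(pts)}")
        if not np.all(np.isfinite(pts)):
            raise ContourError("contour contains NaN/inf coordinates")
        if not LineString(pts).is_simple:
            raise ContourError("contour polyline self-intersects")
        if self.long_axis_length <= 0:
            raise ContourError("degenerate contour: zero apex-to-base length")
        if abs(self.slant_angle_deg) >= 45.0:
            raise ContourError(
                f"basal slant {self.slant_angle_deg:.1f} deg out of range (|b| < 45)"
            )

    # -- landmarks -------------------------------------------------------

    @property
    def basal_corners(self) -> tuple[np.ndarray, np.ndarray]:
        return self.points[0], self.points[-1]

    @property
    def basal_midpoint(self) -> np.ndarray:
        c1, c2 = self.basal_corners
        return 0.5 * (c1 + c2)

    @property
    def apex_index(self) -> int:
        """Contour point farthest from the basal midpoint.

        Near-ties (e.g. a semicircular tracing, where every point is
        equidistant from the midpoint) are broken by the perpendicular
        distance from the basal chord line.
        """
        if "apex_index" not in self._cache:
            d = np.linalg.norm(self.points - self.basal_midpoint, axis=1)
            dmax = d.max()
            cand = np.flatnonzero(d >= dmax * (1.0 - 1e-6))
            if len(cand) > 1:
                c1, c2 = self.basal_corners
                chord = c2 - c1
                nrm = np.linalg.norm(chord)
                if nrm > 0:
                    n = np.array([-chord[1], chord[0]]) / nrm
                    depth = np.abs((self.points[cand] - c1) @ n)
                    cand = cand[[int(np.argmax(depth))]]
            self._cache["apex_index"] = int(cand[0])
        return self._cache["apex_index"]

    @property
    def apex(self) -> np.ndarray:
        return self.points[self.apex_index]

    @property
    def long_axis_length(self) -> float:
        """L_view: distance apex → basal midpoint (mm)."""
        return float(np.linalg.norm(self.apex - self.basal_midpoint))

    @property
    def long_axis_dir(self) -> np.ndarray:
        """Unit vector apex → basal midpoint."""
        v = self.basal_midpoint - self.apex
        return v / np.linalg.norm(v)

    @property
    def lateral_dir(self) -> np.ndarray:
        """Unit vector perpendicular to the long axis (90° CCW from it)."""
        u = self.long_axis_dir
        return np.array([-u[1], u[0]])

    @property
    def basal_chord_length(self) -> float:
        c1, c2 = self.basal_corners
        return float(np.linalg.norm(c2 - c1))

    @property
    def slant_angle_deg(self) -> float:
        """Signed in-plane basal slant bθ_view (degrees).

        Angle between the basal chord and the perpendicular to the
        apex → basal-midpoint line.  Positive when corner 2 is nearer the
        apex side than corner 1.
        """
        c1, c2 = self.basal_corners
        chord = c2 - c1
        u = self.long_axis_dir  # points from apex toward base
        # Height toward apex is -u; corner 2 "higher" means chord has a
        # component along -u.
        along = float(np.dot(chord, -u))
        across = float(np.dot(chord, self.lateral_dir))
        if across < 0:  # measure against the chord direction, not its sign
            across, along = -across, -along
        return float(np.degrees(np.arctan2(along, across)))

    @property
    def basal_height(self) -> float:
        """H_view: perpendicular distance from the apex to the basal chord line."""
        c1, c2 = self.basal_corners
        chord = c2 - c1
        nrm = np.linalg.norm(chord)
        if nrm == 0:
            return self.long_axis_length
        n = np.array([-chord[1], chord[0]]) / nrm
        return abs(float(np.dot(self.apex - c1, n)))

    @property
    def basal_normal_dir(self) -> np.ndarray:
        """Unit vector from apex toward the basal chord, perpendicular to it."""
        c1, c2 = self.basal_corners
        chord = c2 - c1
        n = np.array([-chord[1], chord[0]])
        n = n / np.linalg.norm(n)
        if np.dot(self.basal_midpoint - self.apex, n) < 0:
            n = -n
        return n

    # -- closed region & chords ------------------------------------------

    @property
    def polygon(self) -> Polygon:
        """The cavity region: polyline closed by the basal chord."""
        if "polygon" not in self._cache:
            poly = Polygon(self.points)
            if not poly.is_valid:
                poly = poly.buffer(0)
            self._cache["polygon"] = poly
        return self._cache["polygon"]

    def max_extent_along(self, origin: np.ndarray, direction: np.ndarray) -> float:
        """Largest projection of any contour point onto ``direction`` from ``origin``."""
        return float(np.max((self.points - origin) @ direction))

    def chord_length(
        self, point: np.ndarray, direction: np.ndarray, warn_multi: bool = True
    ) -> float:
        """Length of the cavity chord through ``point`` along ``direction``.

        The chord is the intersection of an infinite line with the closed
        cavity polygon.  A mildly non-convex contour can yield several
        segments; the outermost pair of intersection points is used and a
        warning is emitted.  Returns 0 when the line misses the cavity.
        """
        d = np.asarray(direction, float)
        d = d / np.linalg.norm(d)
        p = np.asarray(point, float)
        # span long enough to cross the whole contour
        half = 4.0 * (np.ptp(self.points, axis=0).max() + 1.0)
        line = LineString([p - half * d, p + half * d])
        inter = self.polygon.intersection(line)
        if inter.is_empty:
            return 0.0
        if inter.geom_type == "LineString":
            return float(inter.length)
        if inter.geom_type in ("MultiLineString", "GeometryCollection"):
            coords = []
            for g in getattr(inter, "geoms", []):
                coords.extend(np.asarray(g.coords))
            if not coords:
                return 0.0
            if warn_multi:
                warnings.warn(
                    "non-convex contour: chord crosses the boundary more than "
                    "twice; using outermost intersection pair",
                    stacklevel=2,
                )
            t = np.asarray(coords) @ d
            return float(t.max() - t.min())
        return 0.0  # point/degenerate touch

    # -- transforms -------------------------------------------------------

    def transformed(self, rotation_deg: float = 0.0, translation=(0.0, 0.0),
                    scale: float = 1.0) -> "Contour2D":
        """Rigidly moved / uniformly scaled copy (for invariance testing)."""
        th = np.radians(rotation_deg)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        pts = scale * (self.points @ R.T) + np.asarray(translation, float)
        return Contour2D(pts, validate=False)

    def mirrored(self) -> "Contour2D":
        """Left-right mirror (x → −x), point order preserved."""
        pts = self.points.copy()
        pts[:, 0] = -pts[:, 0]
        return Contour2D(pts, validate=False)

    def __len__(self) -> int:
        return len(self.points)
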