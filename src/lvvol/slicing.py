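"""Extract standardized apical-view contours from 3-D LV surface meshes.

A longitudinal view plane is defined by a :class:`ViewFrame`: it contains
the long axis (mitral-valve/base center → apex) and is rotated about it by
an azimuth measured from the RV direction (the unit vector from LV to RV
center, projected orthogonal to the long axis).  The standard apical views
follow echocardiographic convention: the A4C plane sits 18° counterclockwise
from the RV direction, with the A2C and A3C a further 60° and 90°
counterclockwise.  Counterclockwise is defined looking from the base toward
the apex; the synthetic phantoms used for validation are symmetric under
the opposite convention.

In-plane coordinates: y runs along the long axis with the base center at
y = 0 and the apex at positive y; x is lateral along the rotated reference
direction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import trimesh

from .geometry import Contour2D

__all__ = ["ViewFrame", "standard_view_planes", "slice_contour", "foreshorten",
           "SlicingError"]

# A4C azimuth from the RV direction, then A2C/A3C offsets (degrees CCW)
A4C_AZIMUTH = 18.0
VIEW_OFFSETS = {"A4C": 0.0, "A2C": 60.0, "A3C": 90.0}

_WELD_TOL = 1e-9  # mm, duplicate-point welding in section polylines


class SlicingError(RuntimeError):
    """Plane/mesh intersection did not produce a single usable loop."""


def _unit(v, name="vector"):
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError(f"{name} has zero length")
    return v / n


def _rotate_about(v, axis, angle_deg):
    """Rodrigues rotation of v about a unit axis."""
    th = np.radians(angle_deg)
    axis = _unit(axis)
    return (v * np.cos(th) + np.cross(axis, v) * np.sin(th)
            + axis * np.dot(axis, v) * (1.0 - np.cos(th)))


@dataclass(frozen=True)
class ViewFrame:
    """A longitudinal slicing plane anchored at the base center.

    ``azimuth_deg`` rotates the in-plane lateral direction counterclockwise
    from ``reference_dir`` about ``long_axis`` (CCW as seen looking from
    base toward apex).
    """

    origin: np.ndarray        # base center, mm
    long_axis: np.ndarray     # unit, base -> apex
    reference_dir: np.ndarray  # unit, RV direction projected in-plane
    azimuth_deg: float = 0.0

    def __init__(self, origin, long_axis, reference_dir, azimuth_deg=0.0):
        u = _unit(long_axis, "long_axis")
        r = np.asarray(reference_dir, dtype=float)
        r = r - np.dot(r, u) * u  # project orthogonal to the long axis
        if np.linalg.norm(r) < 1e-12:
            raise ValueError("reference direction is parallel to the long axis")
        object.__setattr__(self, "origin", np.asarray(origin, dtype=float))
        object.__setattr__(self, "long_axis", u)
        object.__setattr__(self, "reference_dir", r / np.linalg.norm(r))
        object.__setattr__(self, "azimuth_deg", float(azimuth_deg))

    @property
    def lateral_dir(self) -> np.ndarray:
        """In-plane lateral direction at this frame's azimuth."""
        # CCW seen from base toward apex = right-handed about -long_axis
        return _rotate_about(self.reference_dir, -self.long_axis,
                             self.azimuth_deg)

    @property
    def plane_normal(self) -> np.ndarray:
        return _unit(np.cross(self.long_axis, self.lateral_dir))

    def to_plane(self, points_3d: np.ndarray) -> np.ndarray:
        """Project 3-D points into (x lateral, y along-long-axis) coords."""
        rel = np.atleast_2d(points_3d) - self.origin
        return np.column_stack([rel @ self.lateral_dir, rel @ self.long_axis])


def standard_view_planes(base_center, apex, rv_dir) -> dict[str, ViewFrame]:
    """The A4C / A2C / A3C view frames for one ventricle.

    A4C is 18° counterclockwise from the RV direction about the long axis;
    A2C and A3C are a further 60° and 90° counterclockwise.
    """
    base_center = np.asarray(base_center, dtype=float)
    long_axis = _unit(np.asarray(apex, dtype=float) - base_center, "long axis")
    rv = np.asarray(rv_dir, dtype=float)
    if np.linalg.norm(np.cross(rv, long_axis)) < 1e-12 * np.linalg.norm(rv):
        raise ValueError("RV direction is parallel to the long axis")
    return {
        name: ViewFrame(base_center, long_axis, rv,
                        azimuth_deg=A4C_AZIMUTH + offset)
        for name, offset in VIEW_OFFSETS.items()
    }


# ---------------------------------------------------------------------------
# slicing


def _section_loop(mesh: trimesh.Trimesh, frame: ViewFrame) -> np.ndarray:
    section = mesh.section(plane_origin=frame.origin,
                           plane_normal=frame.plane_normal)
    if section is None:
        raise SlicingError("slicing plane does not intersect the mesh")
    loops = section.discrete
    if len(loops) != 1:
        raise SlicingError(
            f"expected one intersection loop, found {len(loops)}")
    loop = np.asarray(loops[0])
    if np.allclose(loop[0], loop[-1], atol=_WELD_TOL):
        loop = loop[:-1]
    # weld consecutive duplicates
    keep = np.ones(len(loop), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(loop, axis=0), axis=1) > _WELD_TOL
    return loop[keep]


def _open_at_base(points_2d: np.ndarray, basal_band: float = 0.15,
                  corner_angle_deg: float = 20.0) -> np.ndarray:
    """Open a closed section loop at the basal chord.

    Candidate basal corners are the loop vertices within the basal
    ``basal_band`` fraction of the y-range (nearest the base, y ≈ 0).  On a
    capped mesh the cap rim shows as the two sharpest turns of the loop, so
    the two candidates with the largest turning angle (≥ ``corner_angle_deg``,
    and not neighbours) become the corners; on smooth caps (e.g. a sphere)
    the farthest candidate pair is used instead.  The arc containing the
    apex (max-y point) is kept, ordered corner → apex → corner.
    """
    y = points_2d[:, 1]
    n = len(points_2d)
    lo = y.min() + basal_band * (y.max() - y.min())
    cand = np.flatnonzero(y <= lo)
    if len(cand) < 2:
        cand = np.sort(np.argsort(y)[:max(2, n // 10)])

    v1 = points_2d[cand] - points_2d[(cand - 1) % n]
    v2 = points_2d[(cand + 1) % n] - points_2d[cand]
    cross = v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0]
    dot = (v1 * v2).sum(axis=1)
    turn = np.abs(np.degrees(np.arctan2(cross, dot)))

    corners = None
    sharp = np.argsort(-turn)
    if turn[sharp[0]] >= corner_angle_deg:
        first = int(cand[sharp[0]])
        min_sep = 2  # corners may be near-adjacent when the cap section is short
        for k in sharp[1:]:
            second = int(cand[k])
            sep = min(abs(second - first), n - abs(second - first))
            if turn[k] >= corner_angle_deg and sep >= min_sep:
                corners = (first, second)
                break
    if corners is None:  # smooth cap: farthest pair among candidates
        sub = points_2d[cand]
        d2 = ((sub[:, None, :] - sub[None, :, :]) ** 2).sum(-1)
        i, j = np.unravel_index(np.argmax(d2), d2.shape)
        corners = (int(cand[i]), int(cand[j]))

    i1, i2 = sorted(corners)
    apex_idx = int(np.argmax(y))
    inner = np.arange(i1, i2 + 1)            # arc i1..i2
    outer = np.r_[np.arange(i2, n), np.arange(0, i1 + 1)]  # arc i2..i1 (wrap)
    arc = inner if apex_idx in inner[1:-1] else outer
    return points_2d[arc]


def slice_contour(mesh: trimesh.Trimesh, frame: ViewFrame,
                  basal_band: float = 0.15) -> Contour2D:
    """Intersect the mesh with the view plane and return the open contour.

    The single intersection loop is projected to in-plane coordinates and
    opened at the basal chord (see :func:`_open_at_base`); the apex is the
    contour point farthest from the basal midpoint.
    """
    loop = _section_loop(mesh, frame)
    pts = frame.to_plane(loop)
    opened = _open_at_base(pts, basal_band=basal_band)
    return Contour2D(opened, validate=False)


def foreshorten(frame: ViewFrame, offset_mm: float = 0.0,
                tilt_deg: float = 0.0) -> ViewFrame:
    """A deliberately misaligned frame that misses the true apex.

    ``offset_mm`` translates the plane along its normal (a chord plane);
    ``tilt_deg`` rotates the long axis about the in-plane lateral direction
    through the base center.  Zero arguments return an identical frame.
    """
    if offset_mm == 0.0 and tilt_deg == 0.0:
        return replace(frame)
    lateral = frame.lateral_dir
    origin = frame.origin + offset_mm * frame.plane_normal
    long_axis = _rotate_about(frame.long_axis, lateral, tilt_deg)
    return ViewFrame(origin, long_axis, lateral, azimuth_deg=0.0)
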