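"""Idealized left-ventricle phantoms: elliptical-cross-section paraboloids.

The phantom is the surface ``z = H0 * (x^2/A^2 + y^2/B^2)`` (apex at the
origin, long axis = z), cropped by a basal cutting plane through the
long-axis point ``(0, 0, H0)``.  Because the cavity has an exact parametric
description, ground-truth volumes and view contours are available
analytically — the workbench isolates formulation error from segmentation
and acquisition error.

Basal slanting comes in two flavours:

* axis-aligned — the plane tilts by ``bθ`` about the major (x) or minor (y)
  cross-sectional axis, so a single azimuth sees the full slant;
* view-coupled (:meth:`ParaboloidSpec.for_view_slant`) — the plane gradient
  is solved so that *both* acquisition azimuths see an in-plane basal slant
  of exactly ``bθ``.  This matches how basal slanting is quantified
  clinically: as the angle visible in each apical view.

Parameters that drive biplane-formula error:

* ``A`` (mm) — major semiaxis of the basal cross-section,
* ``μ >= 1`` — eccentricity, major/minor axis ratio (``B = A/μ``; μ = 1 is
  a circular cross-section),
* ``H0`` (mm) — apex-to-base height before slanting,
* ``bθ`` (deg) — basal slanting angle,
* ``Am`` / ``vθ`` (deg) — view orientation and inter-view angle (see
  :class:`ViewConfig`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from scipy import integrate

from .geometry import Contour2D

__all__ = [
    "ParaboloidSpec",
    "ViewConfig",
    "make_paraboloid",
    "truth_volume",
    "analytic_view_contour",
    "view_pair",
]

MM3_PER_ML = 1000.0


@dataclass(frozen=True)
class ViewConfig:
    """Azimuths of the biplane acquisition.

    ``orientation_deg`` (Am) rotates the primary view away from the *minor*
    cross-sectional axis: Am = 0° puts the primary plane through the minor
    axis (its chords measure the minor diameter exactly), Am = 90° through
    the major axis.  ``viewing_angle_deg`` (vθ) is the azimuth between the
    primary and secondary planes: 90° is the ideal orthogonal pair (A4C–A3C);
    ~60° approximates A4C–A2C.  With μ > 1 and vθ < 90°, Am = 0 biases
    biplane volumes low (the major axis is missed) and Am = 90 biases them
    high (the minor axis is missed).
    """

    orientation_deg: float = 0.0     # Am
    viewing_angle_deg: float = 90.0  # v_theta

    def __post_init__(self):
        if not (0.0 <= self.orientation_deg <= 90.0):
            raise ValueError("orientation angle Am must be in [0, 90] deg")
        if not (0.0 < self.viewing_angle_deg <= 90.0):
            raise ValueError("viewing angle v_theta must be in (0, 90] deg")

    @property
    def azimuths(self) -> tuple[float, float]:
        """View-plane azimuths measured from the cross-section major axis."""
        primary = 90.0 + self.orientation_deg
        return (primary, primary + self.viewing_angle_deg)


@dataclass(frozen=True)
class ParaboloidSpec:
    """Parametric synthetic LV: paraboloid plus slanted basal cutting plane.

    ``tilt`` is the cut-plane gradient ``(tx, ty)``: the plane is
    ``z = H0 + tx*x + ty*y``.  It is normally derived from
    ``slant_angle_deg`` and ``slant_axis``; pass it explicitly (or use
    :meth:`for_view_slant`) for planes not aligned with an ellipse axis.
    """

    base_major_semiaxis: float = 25.0  # A, mm
    eccentricity: float = 1.0          # mu, dimensionless >= 1
    length: float = 80.0               # H0, mm, apex to unslanted base
    slant_angle_deg: float = 0.0       # b_theta
    slant_axis: str = "minor"          # axis the cutting plane tilts about
    n_boundary: int = 256              # meshing resolution (azimuthal)
    n_rings: int = 128                 # meshing resolution (radial)
    tilt: tuple[float, float] | None = None  # explicit plane gradient

    def __post_init__(self):
        if self.base_major_semiaxis <= 0:
            raise ValueError("base_major_semiaxis must be > 0")
        if self.length <= 0:
            raise ValueError("length must be > 0")
        if self.eccentricity < 1:
            raise ValueError("eccentricity mu must be >= 1")
        if not (0.0 <= self.slant_angle_deg < 45.0):
            raise ValueError("slant angle must satisfy 0 <= b_theta < 45 deg")
        if self.slant_axis not in ("major", "minor"):
            raise ValueError("slant_axis must be 'major' or 'minor'")
        if self.n_boundary < 16 or self.n_rings < 4:
            raise ValueError("mesh resolution too coarse")
        if self.tilt is not None:
            if np.hypot(*self.tilt) >= 1.0:  # tan 45 deg
                raise ValueError("tilt gradient too steep (plane slope >= 45 deg)")

    @classmethod
    def for_view_slant(cls, slant_angle_deg: float, view: ViewConfig,
                       **kwargs) -> "ParaboloidSpec":
        """Spec whose cutting plane shows in-plane slant ``bθ`` in *both* views.

        Solves the plane gradient (tx, ty) from the two view azimuths so the
        basal chord of each extracted contour makes the angle
        ``slant_angle_deg`` with the horizontal.
        """
        g = np.tan(np.radians(slant_angle_deg))
        a1, a2 = np.radians(view.azimuths)
        M = np.array([[np.cos(a1), np.sin(a1)], [np.cos(a2), np.sin(a2)]])
        if abs(np.linalg.det(M)) < 1e-12:
            raise ValueError("view azimuths coincide; slant gradient undetermined")
        tx, ty = np.linalg.solve(M, [g, g])
        return cls(slant_angle_deg=slant_angle_deg, tilt=(float(tx), float(ty)),
                   **kwargs)

    # -- derived geometry -------------------------------------------------

    @property
    def A(self) -> float:
        return self.base_major_semiaxis

    @property
    def B(self) -> float:
        """Minor semiaxis, A / mu."""
        return self.base_major_semiaxis / self.eccentricity

    @property
    def H0(self) -> float:
        return self.length

    @property
    def tilt_vector(self) -> np.ndarray:
        """Cut-plane gradient (tx, ty): plane z = H0 + tx*x + ty*y."""
        if self.tilt is not None:
            return np.asarray(self.tilt, float)
        t = np.tan(np.radians(self.slant_angle_deg))
        # tilting about the minor (y) axis makes height vary along x
        return np.array([t, 0.0]) if self.slant_axis == "minor" \
            else np.array([0.0, t])

    def cut_height(self, x, y):
        """z of the cutting plane above footprint point (x, y)."""
        tx, ty = self.tilt_vector
        return self.H0 + tx * np.asarray(x, float) + ty * np.asarray(y, float)

    def surface_height(self, x, y):
        """z of the paraboloid surface at (x, y)."""
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        return self.H0 * (x**2 / self.A**2 + y**2 / self.B**2)

    def footprint(self) -> tuple[np.ndarray, float, float]:
        """Ellipse (center, semi_x, semi_y) where the cavity height is positive.

        Completing the square in ``cut_height >= surface_height`` shifts the
        base ellipse to ``(A² tx, B² ty)/(2 H0)`` and scales both semiaxes by
        ``sqrt(C/H0)`` with ``C = H0 + (A² tx² + B² ty²)/(4 H0)``.
        """
        tx, ty = self.tilt_vector
        center = np.array([self.A**2 * tx, self.B**2 * ty]) / (2.0 * self.H0)
        C = self.H0 + (self.A**2 * tx**2 + self.B**2 * ty**2) / (4.0 * self.H0)
        k = np.sqrt(C / self.H0)
        return center, k * self.A, k * self.B


# ---------------------------------------------------------------------------
# ground truth


def truth_volume(spec: ParaboloidSpec, rtol: float = 1e-6) -> float:
    """Exact cavity volume (mL) of the slanted-cut paraboloid.

    For an unslanted cut the closed form ``π A B H0 / 2`` applies (the
    cross-sectional area is linear in z).  A slanted cut is integrated as a
    2-D quadrature of column heights ``cut − surface`` over the elliptical
    footprint, to relative tolerance ``rtol``.
    """
    A, B, H0 = spec.A, spec.B, spec.H0
    tx, ty = spec.tilt_vector
    if tx == 0.0 and ty == 0.0:
        return np.pi * A * B * H0 / 2.0 / MM3_PER_ML

    center, sx, sy = spec.footprint()
    cx, cy = center

    def height(y, x):
        return float(spec.cut_height(x, y) - spec.surface_height(x, y))

    def y_lo(x):
        r2 = 1.0 - ((x - cx) / sx) ** 2
        return cy - sy * np.sqrt(max(r2, 0.0))

    def y_hi(x):
        r2 = 1.0 - ((x - cx) / sx) ** 2
        return cy + sy * np.sqrt(max(r2, 0.0))

    val, _ = integrate.dblquad(height, cx - sx, cx + sx, y_lo, y_hi,
                               epsabs=0.0, epsrel=rtol)
    return val / MM3_PER_ML


# ---------------------------------------------------------------------------
# meshing


def make_paraboloid(spec: ParaboloidSpec) -> trimesh.Trimesh:
    """Closed triangulated surface of the cropped paraboloid (mm).

    The lateral surface is sampled on radial rays from the apex to the rim
    (the curve where the cutting plane meets the paraboloid); the basal cap
    is a triangle fan in the cutting plane.  Raises if the cutting plane
    dips to (or below) the apex level anywhere over the footprint.
    """
    center, sx, sy = spec.footprint()
    tx, ty = spec.tilt_vector
    min_cut = (spec.H0 + tx * center[0] + ty * center[1]
               - np.hypot(tx * sx, ty * sy))
    if min_cut <= 0.0:
        raise ValueError(
            "cutting plane reaches the apex level: slant angle too large for "
            "this footprint"
        )

    nb, nr = spec.n_boundary, spec.n_rings
    phi = np.linspace(0.0, 2.0 * np.pi, nb, endpoint=False)
    rim_xy = np.column_stack([center[0] + sx * np.cos(phi),
                              center[1] + sy * np.sin(phi)])

    verts = [np.zeros((1, 3))]  # apex
    for j in range(1, nr + 1):
        xy = (j / nr) * rim_xy
        z = spec.surface_height(xy[:, 0], xy[:, 1])
        verts.append(np.column_stack([xy, z]))
    cap_center = np.array([[center[0], center[1],
                            float(spec.cut_height(center[0], center[1]))]])
    vertices = np.vstack(verts + [cap_center])
    cap_idx = len(vertices) - 1
    ring0 = 1

    faces = []
    for k in range(nb):  # apex fan
        faces.append([0, ring0 + k, ring0 + (k + 1) % nb])
    for j in range(nr - 1):  # lateral quads
        lo = ring0 + j * nb
        hi = lo + nb
        for k in range(nb):
            k2 = (k + 1) % nb
            faces.append([lo + k, hi + k, hi + k2])
            faces.append([lo + k, hi + k2, lo + k2])
    rim0 = ring0 + (nr - 1) * nb
    for k in range(nb):  # basal cap fan
        faces.append([cap_idx, rim0 + (k + 1) % nb, rim0 + k])

    mesh = trimesh.Trimesh(vertices=vertices, faces=np.asarray(faces),
                           process=False)
    if mesh.volume < 0:
        mesh.invert()
    return mesh


# ---------------------------------------------------------------------------
# analytic view contours


def analytic_view_contour(spec: ParaboloidSpec, azimuth_deg: float,
                          n_points: int = 257) -> Contour2D:
    """Exact in-plane boundary seen by a longitudinal view plane.

    The plane contains the long axis and sits at ``azimuth_deg`` from the
    cross-section major axis.  In-plane coordinates: x lateral (signed
    distance from the long axis along the view direction), y along the long
    axis with the apex at the origin.  The contour runs basal corner 1 →
    apex → basal corner 2; both corners lie exactly on the cutting plane.
    """
    if n_points < 200:
        raise ValueError("contour needs >= 200 points")
    az = np.radians(azimuth_deg)
    c, s = np.cos(az), np.sin(az)
    # parabola z = H0 * u^2 / R^2 along the in-plane lateral coordinate u
    inv_R2 = c**2 / spec.A**2 + s**2 / spec.B**2
    tx, ty = spec.tilt_vector
    g = tx * c + ty * s  # in-plane slope of the cutting plane
    H0 = spec.H0

    # basal corners: H0 * u^2 * inv_R2 = H0 + g * u
    a_ = H0 * inv_R2
    disc = np.sqrt(g**2 + 4.0 * a_ * H0)
    u1 = (g - disc) / (2.0 * a_)
    u2 = (g + disc) / (2.0 * a_)

    u = np.linspace(u1, u2, n_points)
    z = a_ * u**2
    z[0] = H0 + g * u1  # corners exactly on the cutting plane
    z[-1] = H0 + g * u2
    return Contour2D(np.column_stack([u, z]))


def view_pair(spec: ParaboloidSpec, view: ViewConfig,
              n_points: int = 257) -> tuple[Contour2D, Contour2D]:
    """The two biplane contours at the view configuration's azimuths."""
    a1, a2 = view.azimuths
    return (analytic_view_contour(spec, a1, n_points),
            analytic_view_contour(spec, a2, n_points))
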