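"""Biplane LV volume estimators: SBR, TBC and BOD.

All three methods consume a pair of longitudinal view contours (nominally
A4C plus A2C or A3C) and approximate the cavity as a stack of elliptical
elements whose two diameters at each level come from the two views:

* **SBR** — Simpson's biplane rule, the summation-of-disks method:
  n cylindrical disks of equal height perpendicular to the long axis,
  ``V_T = (π L / 4 n) Σ a_i b_i`` with L the larger of the two views' long
  axes (mitigates single-view foreshortening).
* **TBC** — truncated basal cylinder: the disk stack is refined to
  elliptical frustums with an apical elliptical cone, and one extra
  half-cut cylinder is appended over the slanted basal region.
* **BOD** — basal-oriented disks: the frustum/cone stack is kept, but the
  element planes are oriented parallel to each view's basal (mitral) chord
  instead of perpendicular to the long axis, so a slanted base is tiled
  without the staircase of partial disks that biases SBR and without the
  basal add-on that biases TBC.

Diameters are chord lengths of the contour polygon; volumes are reported in
mL (1 mL = 1000 mm³).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import Contour2D, ContourError

__all__ = [
    "DiskStack",
    "StackElement",
    "ChordProfile",
    "chord_diameters",
    "sbr_volume",
    "tbc_volume",
    "bod_volume",
    "frustum_volume",
    "cone_volume",
    "slant_angle",
]

MM3_PER_ML = 1000.0


# ---------------------------------------------------------------------------
# element volumes


def frustum_volume(a1: float, b1: float, a2: float, b2: float, h: float) -> float:
    """Volume (mL) of an elliptical frustum with linearly varying diameters.

    Cross-section at fraction t is an ellipse with diameters
    ``a(t) = a1 + t (a2 - a1)`` and likewise b; integrating the area
    ``π a(t) b(t) / 4`` over the height gives
    ``(π h / 24) (2 a1 b1 + a1 b2 + a2 b1 + 2 a2 b2)``.
    """
    if min(a1, b1, a2, b2) < 0 or h <= 0:
        raise ValueError("frustum needs non-negative diameters and h > 0")
    return (np.pi * h / 24.0) * (2 * a1 * b1 + a1 * b2 + a2 * b1 + 2 * a2 * b2) \
        / MM3_PER_ML


def cone_volume(a: float, b: float, h: float) -> float:
    """Volume (mL) of an elliptical cone: (1/3) (π a b / 4) h."""
    if min(a, b) < 0 or h <= 0:
        raise ValueError("cone needs non-negative diameters and h > 0")
    return (np.pi * a * b / 4.0) * h / 3.0 / MM3_PER_ML


def _cylinder_volume(a: float, b: float, h: float) -> float:
    return (np.pi * a * b / 4.0) * h / MM3_PER_ML


def slant_angle(contour: Contour2D) -> float:
    """Signed in-plane basal slant bθ_view (degrees); positive when the
    second basal corner sits nearer the apex than the first."""
    return contour.slant_angle_deg


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class StackElement:
    kind: str          # cylinder | frustum | cone | half_cylinder
    a_top: float       # diameters, mm (view-1 chord)
    b_top: float       # view-2 chord
    a_bot: float
    b_bot: float
    h: float           # mm
    level: int
    volume_ml: float


@dataclass(frozen=True)
class DiskStack:
    """Result of one biplane volume estimate: the element list and total."""

    method: str
    elements: tuple[StackElement, ...]
    L_used: float      # long-axis (or basal-perpendicular) length employed, mm
    n: int
    total_volume: float  # mL

    def __post_init__(self):
        total = sum(e.volume_ml for e in self.elements)
        if not np.isclose(total, self.total_volume, rtol=1e-12, atol=1e-12):
            raise ValueError("total_volume inconsistent with element volumes")


@dataclass(frozen=True)
class ChordProfile:
    """Chord lengths of one contour at levels along a stacking direction."""

    levels: np.ndarray      # mm from apex, strictly increasing
    diameters: np.ndarray   # mm, >= 0
    stack_direction: str    # long_axis_perpendicular | basal_parallel

    def __post_init__(self):
        if np.any(np.diff(self.levels) <= 0):
            raise ValueError("levels must increase strictly from apex to base")
        if np.any(self.diameters < 0):
            raise ValueError("diameters must be non-negative")


# ---------------------------------------------------------------------------
# chord sampling


def _level_fractions(n_levels: int, placement: str) -> np.ndarray:
    if placement == "midpoint":
        return (np.arange(1, n_levels + 1) - 0.5) / n_levels
    if placement == "boundary":
        return np.arange(1, n_levels + 1) / n_levels
    raise ValueError("placement must be 'midpoint' or 'boundary'")


def chord_diameters(contour: Contour2D, direction: str, n_levels: int,
                    placement: str = "midpoint",
                    span: float | None = None) -> ChordProfile:
    """Sample cavity chords at equally spaced levels from the apex.

    ``direction='long_axis_perpendicular'`` takes chords perpendicular to
    the apex → basal-midpoint line over ``[0, L_view]`` (or an explicit
    ``span``); ``direction='basal_parallel'`` takes chords parallel to the
    basal chord over the perpendicular height ``H_view``.  ``placement``
    puts levels at disk midpoints ``(i-1/2)/n`` or boundaries ``i/n``.
    A level outside the cavity yields diameter 0.
    """
    if direction == "long_axis_perpendicular":
        axis = contour.long_axis_dir
        chord_dir = contour.lateral_dir
        full = contour.long_axis_length if span is None else span
    elif direction == "basal_parallel":
        axis = contour.basal_normal_dir
        c1, c2 = contour.basal_corners
        chord_dir = (c2 - c1) / np.linalg.norm(c2 - c1)
        full = contour.basal_height if span is None else span
        if abs(contour.slant_angle_deg) >= 45.0:
            raise ContourError("basal-parallel stacking needs |b_theta| < 45 deg")
    else:
        raise ValueError("unknown stack direction: " + direction)

    fracs = _level_fractions(n_levels, placement)
    levels = fracs * full
    apex = contour.apex
    eps = 1e-8 * full  # retry just inside: a level exactly on the basal
    diam = []          # chord degenerates in exact arithmetic
    for lv in levels:
        d = contour.chord_length(apex + lv * axis, chord_dir)
        if d == 0.0:
            d = contour.chord_length(apex + (lv - eps) * axis, chord_dir)
        diam.append(d)
    return ChordProfile(levels=levels, diameters=np.asarray(diam),
                        stack_direction=direction)


def _clamped_profile(contour: Contour2D, n: int, L: float, placement: str,
                     short_view_policy: str) -> np.ndarray:
    """Long-axis-perpendicular diameters over a shared span L.

    Levels beyond the contour's own extent give 0 under the ``zero`` policy;
    under ``clamp`` (default) a level within one disk height of the
    contour's basal-most extent reuses the basal-most available chord,
    avoiding an artefactual staircase when the shared L exceeds this view.
    """
    prof = chord_diameters(contour, "long_axis_perpendicular", n,
                           placement=placement, span=L)
    if short_view_policy == "zero":
        return prof.diameters
    if short_view_policy != "clamp":
        raise ValueError("short_view_policy must be 'zero' or 'clamp'")
    diam = prof.diameters.copy()
    apex = contour.apex
    extent = contour.max_extent_along(apex, contour.long_axis_dir)
    disk_h = L / n
    for i, lv in enumerate(prof.levels):
        if diam[i] == 0.0 and lv > extent:
            if lv - extent <= disk_h:
                # basal-most chord still inside the cavity
                diam[i] = contour.chord_length(
                    apex + (extent - 1e-9 * max(extent, 1.0)) * contour.long_axis_dir,
                    contour.lateral_dir)
            else:
                diam[i] = 0.0
    return diam


# ---------------------------------------------------------------------------
# estimators


def _check_pair(cA: Contour2D, cB: Contour2D) -> None:
    for c in (cA, cB):
        if c.long_axis_length <= 0:
            raise ContourError("degenerate contour: non-positive long axis")


def sbr_volume(cA: Contour2D, cB: Contour2D, n: int = 20,
               short_view_policy: str = "clamp") -> DiskStack:
    """Simpson's biplane rule: n cylindrical disks on the shared long axis.

    L is the larger of the two views' apex-to-basal-midpoint lengths; both
    views are sampled with midpoint-placed chords perpendicular to their own
    long axis at the same n levels of the shared L, and
    ``V_T = (π L / 4n) Σ a_i b_i``.
    """
    _check_pair(cA, cB)
    L = max(cA.long_axis_length, cB.long_axis_length)
    a = _clamped_profile(cA, n, L, "midpoint", short_view_policy)
    b = _clamped_profile(cB, n, L, "midpoint", short_view_policy)
    h = L / n
    elements = []
    for i in range(n):
        vol = _cylinder_volume(a[i], b[i], h)
        elements.append(StackElement("cylinder", a[i], b[i], a[i], b[i], h,
                                     level=i, volume_ml=vol))
    total = float(sum(e.volume_ml for e in elements))
    return DiskStack("SBR", tuple(elements), L_used=L, n=n, total_volume=total)


def _corner_projections(c: Contour2D) -> tuple[float, float]:
    """Projections of the two basal corners onto the view's long axis,
    measured from the apex; returns (nearer, farther)."""
    u = c.long_axis_dir
    p = [float(np.dot(corner - c.apex, u)) for corner in c.basal_corners]
    return min(p), max(p)


def _frustum_stack(a: np.ndarray, b: np.ndarray, h: float,
                   level0: int = 0) -> list[StackElement]:
    """Apex cone followed by frustums, from boundary-placed diameters."""
    elements = [StackElement("cone", a[0], b[0], 0.0, 0.0, h, level=level0,
                             volume_ml=cone_volume(a[0], b[0], h))]
    for i in range(1, len(a)):
        vol = frustum_volume(a[i - 1], b[i - 1], a[i], b[i], h)
        elements.append(StackElement("frustum", a[i - 1], b[i - 1], a[i], b[i],
                                     h, level=level0 + i, volume_ml=vol))
    return elements


def tbc_volume(cA: Contour2D, cB: Contour2D, n: int = 20) -> DiskStack:
    """Truncated-basal-cylinder method.

    Each view's disk-stack length is cut at its *nearer* basal corner so
    that a truncated (half-cut) cylinder can tile the slanted basal region;
    the frustum stack (apical cone first) is then built over the
    foreshortening-corrected shared length ``L = max(L_A, L_B)`` with each
    view's boundary diameters sampled over its own cut span — i.e. the
    basal length cut is re-inflated as if it had been foreshortening.  One
    half-cut cylinder per view, spanning that view's basal slant extent
    (farther minus nearer corner projection) with the stack-top diameters,
    is appended.  With differing view slants the inflated L plus the basal
    add-ons overestimate the cavity; at zero slant both add-ons vanish and
    the method reduces to the plain frustum stack.
    """
    _check_pair(cA, cB)
    nearA, farA = _corner_projections(cA)
    nearB, farB = _corner_projections(cB)
    if min(nearA, nearB) <= 0:
        raise ContourError("degenerate basal corners: non-positive stack extent")
    L = max(cA.long_axis_length, cB.long_axis_length)

    a = chord_diameters(cA, "long_axis_perpendicular", n,
                        placement="boundary", span=nearA).diameters
    b = chord_diameters(cB, "long_axis_perpendicular", n,
                        placement="boundary", span=nearB).diameters
    elements = _frustum_stack(a, b, L / n)

    level = n
    for near, far in ((nearA, farA), (nearB, farB)):
        basal_h = far - near
        if basal_h > 1e-12:
            vol = 0.5 * _cylinder_volume(a[-1], b[-1], basal_h)
            elements.append(StackElement("half_cylinder", a[-1], b[-1],
                                         a[-1], b[-1], basal_h, level=level,
                                         volume_ml=vol))
            level += 1
    total = float(sum(e.volume_ml for e in elements))
    return DiskStack("TBC", tuple(elements), L_used=L, n=n, total_volume=total)


def bod_volume(cA: Contour2D, cB: Contour2D, n: int = 20) -> DiskStack:
    """Basal-oriented-disks method.

    Each view is sampled with chords *parallel to its own basal chord* at
    boundary fractions i/n of its perpendicular apex-to-base height H_view;
    diameters are paired across views by fraction index.  The stack is an
    apical elliptical cone plus n−1 frustums of shared element height
    ``max(H_A, H_B)/n``, so the disk planes follow the basal plane and a
    slanted base is tiled without partial disks.
    """
    _check_pair(cA, cB)
    profA = chord_diameters(cA, "basal_parallel", n, placement="boundary")
    profB = chord_diameters(cB, "basal_parallel", n, placement="boundary")
    H = max(cA.basal_height, cB.basal_height)
    elements = _frustum_stack(profA.diameters, profB.diameters, H / n)
    total = float(sum(e.volume_ml for e in elements))
    return DiskStack("BOD", tuple(elements), L_used=H, n=n, total_volume=total)
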