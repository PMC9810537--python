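# Methods

## The estimation problem

Biplane LV volume estimation reconstructs a 3-D cavity volume from two
longitudinal tracings.  All three formulations implemented here share the
same inputs — a pair of open endocardial contours, each running from one
basal (mitral-annulus) corner around the apex to the other corner, with
the basal chord closing the cavity implicitly — and differ only in how the
cavity is tiled with elliptical elements.  Diameters are chord lengths of
the closed cavity polygon (contour plus basal chord); volumes are in mL
with all coordinates in mm.

**SBR.** `n` cylindrical disks of equal height perpendicular to the long
axis (apex → basal midpoint), midpoint-sampled over the shared length
`L = max(L_A, L_B)`; `V_T = (π L / 4n) Σ a_i b_i`.  Sampling both views on
the shared `L` uses each view's own chords at each level; a level beyond a
shorter view's basal extent reuses that view's basal-most chord when it is
within one disk height of the extent, else contributes zero (the
`short_view_policy="clamp"` default; `"zero"` is available).  The clamp
avoids an artefactual staircase when the two views have slightly different
lengths; on the synthetic workbench it almost never triggers because the
slanted contour extends past `L` on its far side.

**TBC.** The disk stack is refined to elliptical frustums with the
apex-most element an elliptical cone (boundary-placed diameters at
fractions `i/n`), which better follow wall curvature.  To make room for a
basal add-on, each view's stack span is cut at its *nearer* basal corner
projection; the stack is then built over the foreshortening-corrected
shared length `L = max(L_A, L_B)`, i.e. the cut length is stretched back
as if it had been foreshortening.  Finally one half-cut cylinder per view
— height equal to that view's basal slant extent (farther minus nearer
corner projection), diameters taken at the stack top — tiles the slanted
basal region.  When the two views carry unequal slants the stretch
inflates the shorter profile and the add-ons double-count part of the
base, which is exactly the overestimation mechanism this formulation is
known for; at zero slant both add-ons vanish and TBC coincides with the
plain frustum stack.

**BOD.** Chords are taken *parallel to each view's basal chord* at
boundary fractions `i/n` of that view's perpendicular apex-to-base height
`H_view`; diameters are paired across views by fraction index, the shared
element height is `max(H_A, H_B)/n`, and the stack is the same cone +
frustum sequence.  Because the element planes follow the basal plane, a
slanted base is tiled without partial disks and without a basal add-on.
Fraction pairing degrades gracefully: at zero slant BOD is bitwise the
TBC/frustum stack.

Element volumes are closed forms: elliptical frustum
`(π h / 24)(2 a₁b₁ + a₁b₂ + a₂b₁ + 2 a₂b₂)` (the exact integral of
`π a(t) b(t) / 4` with linearly interpolated diameters) and cone
`(π a b / 12) h`.

## Synthetic workbench

The phantom is the paraboloid `z = H0 (x²/A² + y²/B²)` (apex at origin,
long axis = z) cropped by a basal plane through `(0, 0, H0)` with gradient
`(tx, ty)`: `z = H0 + tx·x + ty·y`.  Defaults `A = 25 mm`, `H0 = 80 mm`
put the unslanted volume at 71–79 mL depending on μ — a physiological
end-diastolic volume with a realistic length-to-width ratio; percentage
errors of all three estimators depend on this aspect ratio, so the
defaults are fixed here to make results reproducible.

Completing the square shows the cavity footprint is an ellipse shifted to
`(A² tx, B² ty)/(2 H0)` with both semiaxes scaled by `√(C/H0)`,
`C = H0 + (A² tx² + B² ty²)/(4 H0)`.  Ground truth is
`π A B H0 / 2` for an unslanted cut (cross-section area is linear in z)
and otherwise adaptive 2-D quadrature of column heights over the footprint
(relative tolerance 1e-6); the closed form `π A B C² / (2 H0)` and a
0.2 mm column-sum voxelization serve as independent oracles in the tests.
With this pivot the plane provably never reaches the apex for slopes below
45°, and the cavity volume *grows* slightly with bθ (the footprint
expands faster than material is removed) — the implementation asserts this
observed direction rather than assuming monotone loss.

**Slant semantics.** Basal slanting is quantified clinically as the angle
visible in an apical view, so the workbench's default construction
(`ParaboloidSpec.for_view_slant`) solves `(tx, ty)` from the two view
azimuths such that *both* views see an in-plane basal slant of exactly bθ.
Axis-aligned tilts (about the major or minor cross-section axis, slanting
a single azimuth) remain available via `slant_axis=` for studying the
unequal-slant worst case.

**View angles.** `ViewConfig(Am, vθ)` places the primary view at azimuth
`90° + Am` from the major cross-section axis: Am = 0 means the primary
plane contains the *minor* axis, Am = 90 the major axis.  This convention
is chosen so that, with μ > 1 and vθ < 90°, Am = 0 biases volumes low (the
major axis is missed by both views) and Am = 90 biases them high — the
sign structure the error study exhibits.  The secondary view sits at
`vθ` further; vθ = 90° is the ideal orthogonal (A4C–A3C-like) pair and
vθ = 60° approximates the A4C–A2C pair.

Analytic view contours are exact: the in-plane boundary is the parabola
`z = H0 u²/R(α)²` with `R(α)` the ellipse radius at azimuth α, closed by
the cut line `z = H0 + g u`, `g = tx cos α + ty sin α`; the corners solve
the resulting quadratic so they sit on the cutting plane to machine
precision.  Contours default to 257 points — an odd count so symmetric
contours sample the apex exactly, which keeps the zero-slant degeneracy
(TBC ≡ BOD) exact.

## Mesh pipeline

Ground truth for arbitrary anatomies is the divergence-theorem volume of a
watertight triangulated surface (signed tetrahedra to the origin, via
trimesh); non-watertight meshes are refused, and negative orientation is
fixed by flipping faces rather than erroring, since mesh provenance
varies.  PLY/OBJ load through trimesh; legacy ascii VTK polydata has a
small dedicated parser (POINTS/POLYGONS).

Standard view planes follow echocardiographic convention: A4C at 18°
counterclockwise from the projected RV direction about the long axis, A2C
and A3C a further 60° and 90°.  Counterclockwise is defined looking from
base toward apex; the phantoms used for validation are symmetric under the
opposite convention, so results do not depend on this choice.  A slice is
the single plane/mesh intersection loop projected to in-plane coordinates
(y along the long axis, base center at y = 0, apex at positive y) and
opened at the basal chord: within the basal 15% of the y-range, the two
loop vertices with the sharpest turning angle (the cap rim) become the
corners, falling back to the farthest candidate pair for smooth caps.
`foreshorten` deliberately translates or tilts a frame to produce
apex-missing contours for robustness studies.

## Numerical choices and degenerate inputs

* Chord queries intersect an infinite line with the cavity polygon
  (shapely).  Mildly non-convex tracings can intersect more than twice;
  the outermost pair is used with a warning.  A chord exactly on the basal
  boundary is degenerate in exact arithmetic, so a zero result is retried
  a relative 1e-8 inside the span.
* The contour apex is the point farthest from the basal midpoint;
  near-ties (within 1e-6 relative, e.g. semicircular tracings) are broken
  by depth from the basal chord line.
* Contours are validated on construction: ≥ 10 points, finite, simple
  polyline, positive long-axis length, |bθ_view| < 45°.
* All angles cross the public interface in degrees; radians are internal.
* Sweeps and batches are deterministic; per-point failures are captured in
  an `error` column instead of aborting, and the CSV column order is fixed
  for byte-stable regression comparisons.

## What the workbench does and does not show

The phantoms have exact elliptical cross-sections with no slice-to-slice
variation of Am or μ, no trabeculation, no segmentation noise, and
perfectly known landmarks.  Passing the synthetic suite therefore
demonstrates formulation error in isolation — how each method responds to
basal slanting, view orientation, inter-view angle and eccentricity — not
performance on clinical images, where tracing variability and
within-ventricle shape variation add further error.  Real anatomies also
vary in aspect ratio, and absolute percentage errors scale with it; the
fixed default dimensions make the reported numbers reproducible rather
than universal.

## Problem sizes

The test suite and the acceptance script run the estimators at the
clinical n = 20 on 257-point contours, sweep grids of a few dozen
configurations, and validate oracles on 20 random phantoms with meshes of
~33k triangles — all chosen as the smallest sizes at which discretization
error is comfortably below the effects being measured.
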