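# Methods

This note documents the models, conventions and numerical choices behind
`abcline`, in the spirit of a statistics-package methods appendix: what
is computed, under which assumptions, and what the synthetic phantom can
and cannot tell you about real anatomy.

## Coordinate frame

All computation happens in a craniometric frame anchored at the apex of
the dorsum sellae: origin at the dorsum, +x toward the subject's right
(lateral), +y anterior, +z superior, right-handed, midsagittal plane
x = 0. Heights of the basilar apex (A) and ICA bifurcation (B) are then
plain signed z coordinates, and the lateral breadth of B is |x|. Heights
are deliberately *not* floored at zero: low-set vessels genuinely sit
below the dorsum sellae (the published cohort ranges reach −5 mm for A
and −1.4 mm for B), and the sign carries surgical meaning. All lengths
are millimetres, everywhere; the CLI accepts `cm`-suffixed values and
converts on input.

## The trajectory model

The surgical corridor is idealized as the straight ray from A through B.
Point C is the exit of that ray through the cranial surface, computed by
exact ray–triangle intersection (Möller–Trumbore) against the watertight
skull mesh. Choices that matter:

- **Outer-table exit.** The *largest* forward intersection parameter is
  taken. On a single-shell phantom this is the unique exit; on a
  two-shell (inner/outer table) mesh it selects the outer surface, which
  is the surface a craniotomy is marked on. Whether a clinical
  workstation projects to the inner or outer table is not documented in
  the source material; the outer table is assumed.
- **Arc-length parameterization.** The ray direction is normalized, so
  t-values are mm: t_B = ‖B − A‖ and t_C > t_B always (C lies beyond the
  bifurcation on the extension of the corridor).
- **Grazing rays.** If no forward hit is found (possible only for
  origins numerically on the surface), the origin is nudged 1e−6 mm
  along the ray and the cast repeated once — deterministic, and below
  every reported precision.
- **Tolerances.** Collinearity of C with the A–B line is checked to
  1e−6 mm (pure floating-point diagnostic); mesh-vs-analytic agreement
  is held to 0.5 mm (discretization budget, see below). These are
  separated by three orders of magnitude precisely so that an
  algorithmic defect cannot hide inside discretization error.

A closed-form companion, `analytic_ellipsoid_intersection`, solves the
ray–ellipsoid quadratic for origins strictly inside and serves as the
independent oracle for the mesh path. At the default mesh resolution
(icosphere subdivision 5, 20 480 faces) the chordal sag of the
discretized ellipsoid is ≈ 0.014 mm; observed worst-case disagreement
over 1000 random interior trajectories is ≈ 0.05 mm, comfortably inside
the 0.5 mm budget. Oracle trajectories are sampled inside the ellipsoid
scaled to 0.95 so that exit rays stay away from tangency, where the
mesh/analytic difference is amplified by 1/sin(incidence); anatomically
plausible corridors are nowhere near tangent.

## Measurements

C-Z (to the zygomatic arch) and C-L (to the lateral canthus) are
straight-line 3D Euclidean distances. Geodesic distance along the scalp
would be an alternative reading of a caliper-on-workstation measurement,
but chord distance is reproducible, 1-Lipschitz in C, and agrees with
how distances between a point and a landmark are normally read off a 3D
workstation. C-Z uses the full arch polyline (minimum over clamped
segment projections); a single mid-zygomatic-point mode
(`cz_mode="midpoint"`, arc-length midpoint of the arch) is provided
because the published material itself is ambiguous between "arch" and
"mid-zygomatic point". The polyline is the default since a distance to
the whole arch is what zygoma removal physically relieves.

## The decision rule

Both distances < 30 mm → `oza_recommended`; both > 40 mm →
`pterional_sufficient`; everything else — including exact boundary
values — `indeterminate`. The thresholds come from the reported surgical
experience (OZA patients had both distances under 3 cm; patients clipped
without the OZA had both over 4 cm) and are exposed as parameters. The
indeterminate band is deliberate: the one reported patient inside it
(C-Z 36 mm, C-L 31 mm) was approached pterionally and could not be
clipped, so collapsing the band onto either label would misrepresent
what the construct can support. The rule is monotone: increasing both
distances never moves a subject toward needing the OZA.

## Statistics

Pearson correlation between each distance outcome (C-Z, C-L) and each
anatomical predictor (height of A, height of B, width of B), two-sided
p-values from the t-distribution with df = n − 2, Bonferroni-corrected
threshold α/m with m = 3 predictors per outcome family (0.05/3 ≈ 0.0167,
reported as 0.017 at 3 d.p.). Sidedness is not stated in the source
material; two-sided is the conservative default. With n < 3 the t-test
has no residual degrees of freedom: the package warns, reports r where
defined (NaN for zero-variance columns, which at n = 2 arise structurally
because the two sides of one subject share the same apex height) and
sets all p-values to NaN rather than guessing. Cohort summaries use the
sample SD (n − 1).

## Synthetic anatomy

The phantom exists so every downstream stage is testable without any
clinical data. What it models, and how:

- **Skull**: an axis-aligned ellipsoid, default semi-axes 70 (lateral) ×
  90 (AP) × 65 (SI) mm, centred 35 mm above the dorsum sellae, meshed as
  a subdivided icosahedron with vertices exactly on the analytic
  surface (watertight, genus 0, outward normals). Any convex closed
  surface preserves the construct's qualitative behaviour; the ellipsoid
  additionally admits the closed-form oracle.
- **Landmarks**: external auditory canal, lateral canthus and a 5-point
  zygomatic-arch polyline per side, placed analytically on the ellipsoid
  at configurable (y, z) stations; the left side is the exact mirror of
  the right (symmetry < 1e−6 mm). The arch runs posterior→anterior at
  the EAC's axial level, ending at the zygomatic body.
- **Vessels**: per subject, one near-midline apex A (|x| ≤ 2 mm,
  truncated Gaussian lateral jitter) shared by both sides — the basilar
  apex is a midline structure — and one B per side. Heights of A and B
  and the width of B are drawn from truncated normals; A sits at
  y = −8 mm (posterior, interpeduncular region) and B at y = +10 mm
  (anterior, supraclinoid region), each with 2 mm Gaussian AP jitter.
  The AP stations are not published anywhere and are stand-in defaults,
  exposed as parameters. Sides are independent draws by default (the
  published cohort treats two sides of one patient as two samples), with
  a `mirror_sides` flag for sensitivity analyses.
- **Calibration**: each truncated normal is *moment-matched* — the
  parent (μ, σ) are solved numerically so that the truncated
  distribution's mean and SD equal the published values exactly, with
  truncation at the published range so no draw can escape it. Truncating
  a normal parameterized directly by the published numbers would bias
  the sample (for height of A, truncation at [−5, 10.5] shifts the mean
  from 4.9 to ≈ 4.4 mm); moment matching removes that bias by
  construction. A requested SD above the uniform-distribution bound
  (range/√12) is unattainable under truncation and rejected with a
  parameter error. Draws landing outside the skull are redrawn (all
  stochastic components of the point at once) up to a retry budget,
  after which a generation error names the offending parameters.

What the phantom does **not** emulate: real cranial shape (temporal
fossa, orbital walls, skull base relief), vessel curvature and tortuosity
(A and B are points, not vessels), the posterior clinoid process, brain,
nerves and tentorium, inter-subject skull-size variation, and any
correlation between skull geometry and vessel position. Consequently,
passing tests demonstrate that the *construct* behaves as described —
the trajectory geometry, the measurement definitions, the decision rule,
the statistical machinery, and the directional mechanism linking vessel
heights to C-Z — but absolute synthetic values of C-Z/C-L and the
synthetic correlation magnitudes are properties of the phantom, not
estimates of clinical quantities. The published real-cohort correlation
coefficients are therefore not reproduction targets (the raw 80-sample
data are not available); only their signs, which follow from the
geometry, are.

## The directional mechanism

On any convex skull, with B fixed, raising A tilts the A→B ray downward
at its exit, so point C moves inferiorly toward the zygomatic arch and
C-Z shrinks; with A fixed, raising B tilts the exit upward and C-Z
grows. The package verifies this as strict monotonicity by 1 mm finite
differences across the published ranges of both heights, and
end-to-end as sign recovery: in 20 independent synthetic cohorts of
n = 80, r(C-Z, height A) < 0 and r(C-Z, height B) > 0 in at least 19.
C-L behaves less cleanly on the phantom because point C lands near the
canthus station for central parameter values, so its correlations are
weak and not asserted — consistent with the source material itself
reporting conflicting signs for the C-L pairs.

## Voxel phantom path

For workflows that want a CT-like volume, the mesh can be rasterized to
a binary occupancy grid (one ray per voxel column; voxels between
entry/exit crossing pairs are filled; grazing columns re-cast with a
nudged origin) at voxel sizes 0.25–2.0 mm, with a one-voxel shell
(occupancy minus its erosion) for NIfTI export and a marching-cubes
isosurface for round-trip checks. Fidelity is measured as a symmetric
vertex-sampled Hausdorff distance and stays within 2 voxel widths
(observed: ≈ 0.5 voxel), halving when the voxel halves. For large
marching-cubes meshes the point-to-triangle distances prune candidates
to the 64 nearest triangle centroids per query point (exact in practice
for near-uniform meshes whose triangle diameter is far below the pruning
radius).

## Problem sizes and determinism

Default analyses use an 80-subject-side cohort on a subdivision-5 mesh;
sign recovery uses 20 cohorts; oracle agreement uses 1000 trajectories;
generator calibration uses n = 5000 (2 standard-error criterion on each
mean); voxel-path checks run on a subdivision-3 skull at 1.0 and 0.5 mm.
These sizes make every property statistically decidable while keeping
the whole suite and the acceptance script in the minutes range on one
CPU. Every stochastic stage consumes a single integer seed through
`numpy.random.default_rng`; the pipeline manifest records config, seed,
library versions and a SHA-256 per numeric output, and re-running a
manifest reproduces every numeric artifact byte-for-byte. (The scatter
PNG is excluded from hashing: image encoders embed library metadata.)

## Known limitations

- The straight-ray corridor ignores that surgeons work around the ICA,
  not through it; the construct is a planning reference, not a
  simulation of the operative view.
- Chord C-Z/C-L distances can differ from on-scalp (geodesic) distances
  by several mm for far-lateral exit points.
- The ellipsoid's lateral narrowing near the skull base places the EAC
  more medially than in a real skull; EAC-relative coordinates of C are
  phantom-specific.
- The decision thresholds derive from five surgical cases; the package
  treats them as configurable defaults, not validated cutoffs.
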