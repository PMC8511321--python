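# Methods

## Coordinate frame and projection

All analysis happens in an anatomy frame anchored at the centre of the
external auditory canal: z along the canal pointing laterally, x parallel
to the temporal line pointing posteriorly, y = z × x pointing superiorly.
The superior direction of y is a convention choice (the inferior mastoid
tip lives at negative y); it is configurable through the frame axes.
Left-sided anatomies are mirrored about the frame's y–z plane into the
right-side convention before any measurement, so multi-subject maps and
pooled statistics share one lateral-view coordinate system. The frame is
user input (a JSON file); no automatic landmark detection is attempted,
mirroring the manual alignment such data normally receives.

Surface samples are generated by casting rays along −z from above the
mesh at the nodes of a regular x–y grid; the first intersection is the
sample position and the hit face's normal (oriented toward +z, then
negated) is the inward normal. Grid spacing defaults to 0.5 mm — fine
enough to resolve 0.1 mm histogram bins in the summaries while keeping a
100 × 100 mm footprint at ≈ 40k samples. Nodes whose ray misses the mesh
are marked invalid and propagate as missing map cells.

## Cortical layer thickness (CLT)

CLT at a sample p with inward normal n̂ is the minimal Euclidean distance
from p to the nearest *opposite* surface — the interior cortical wall or
an air-cell wall. "Opposite" is made precise as a half-space criterion:
candidate surface points q must satisfy (q − p)·n̂ ≥ δ with δ = 0.05 mm.
The distance is evaluated from the probe point p + δ·n̂ and δ is added
back, so a parallel slab of thickness t reports exactly t. The δ margin
exists solely to exclude the sample's own outer-surface patch; its
side-effect (a candidate at depth d is excluded when d·cos α < δ for
approach angle α) only matters for nearly-tangential geometry and is
bounded by δ itself.

Two query modes are provided. `nearest` (default) is the unrestricted
Euclidean minimum over the constrained surface, computed exactly:
triangles fully inside the half-space use the standard closest-point-on-
triangle classification; triangles straddling the criterion plane are
clipped exactly and the closest point on the clipped polygon is taken.
`ray` instead intersects the inward-normal ray with the mesh. The
wording "minimal distance" motivates `nearest` as the default; the ray
variant is kept because the two differ on oblique interior walls and the
difference is occasionally diagnostic.

CLT values beyond `max_thickness` (default 10 mm) are censored at the cap
and flagged: far-field cortical measures carry no information for screw
seating and unbounded searches dominate runtime. Genuine near-zero CLT
(e.g. at cranial suture lines in real data) is reported as measured, not
treated as missing — such values belong to the reported distributions.

All nearest-point, constrained-nearest and ray queries share one pruning
scheme: a cKDTree over triangle centroids discards triangles whose
bounding sphere provably cannot beat the current best distance, so the
result is identical (≤ 1e-9 mm in the test suite) to a brute-force loop
over every triangle while scaling to 10⁵-face meshes. The brute-force
oracles live in the test suite and use a deliberately different
closest-point formulation (plane projection + edge clamping).

## Distance to dura / venous sinuses (DDVS)

DDVS is the plain minimal Euclidean distance from the sample position to
the dura + sinus mesh — no half-space restriction, since that mesh is a
separate structure. Screw clearance is intentionally asymmetric, matching
surgical reading: a tip short of the dura reports the omnidirectional
minimal distance (positive), while a tip beyond it reports the axial
overshoot along the screw axis (negative), found by casting the head→tip
ray against the mesh. The contact flag is exactly `clearance ≤ 0`. Only
the tip point enters the metric; the 3.2 mm thread diameter is carried in
the screw spec for reporting but no lateral cylinder clearance is
checked.

## Regions

The region of interest (ROI) for screw placement is the sector
θ ∈ [−60°, 30°] with inner radius 15 mm and an outer radius linear in θ
from 15 mm at −60° up to 50 mm at +30°. The lower anchor of that linear
relationship is not well determined anatomically and is configurable
(`r_max_at_theta_min`); widening it grows the inferior ROI considerably.

Within the ROI, labels are assigned by a fixed precedence chain
(mastoid tip > mastoid > petrous pyramid > parietal > the rest), which
makes boundary ties deterministic:

1. **mastoid tip**: y ≤ −8 mm and x ≥ −16 mm;
2. **mastoid**: r ≤ 30 mm and strictly inferior to the −45° separating
   line through the origin shifted 4 mm along −y;
3. **petrous pyramid**: within the 15 mm-thick band centred on that line,
   r ≤ 30 mm;
4. **parietal**: the band beyond 30 mm, plus the posterior area superior
   to the band beyond 30 mm at θ < 0;
5. **middle fossa**: superior to the band, r ≤ 30 mm;
6. **superior temporal surface**: superior to the band, r > 30 mm, θ ≥ 0;
7. **retrosigmoid**: inferior to the band beyond the mastoid annulus.

Only the ROI bounds, the 15/30/50 mm radii, the 45° band with 15 mm
thickness and −4 mm shift, and the mastoid-tip bounds are prescribed by
the mapping convention; the shapes of regions 1, 2 and 7 are an explicit
reconstruction of the published region sketch and every boundary lives in
`RegionConfig`, so users can redraw them without code changes. Note that
under the default tapered ROI the mastoid and retrosigmoid regions are
small (the taper truncates the inferior sector); analyses that need the
full annulus should widen the lower ROI anchor. The mastoid/petrous
separation uses the *line* (not the band edge) so that the band axis
itself belongs to the petrous pyramid; the strict inequality implements
that tie-break.

## Statistics

Percentiles use linear interpolation between order statistics with
inclusive endpoints (numpy's `linear` method); the headline table reports
the 1st, 5th, 50th and 95th percentiles of CLT and DDVS per region plus a
pooled **All** row. "All" pools every ROI sample — including samples in
no named region — rather than averaging region rows; pooled and averaged
percentiles differ and pooling is what "fraction of the area of interest"
means under equal-area grid sampling. Each valid grid sample counts once;
no vertex-density weighting is applied. Regions with fewer than two
samples are flagged insufficient.

The thread-length recommendation reads the DDVS value at the
(100 − coverage)th percentile from each selected region and returns the
minimum: a thread no longer than this leaves the dura/sinus untouched
over at least `coverage` % of the selected area under the table's
distributions. It is non-increasing in coverage and cannot decrease when
a shallow region is removed from the selection.

Cohort aggregation computes cell-wise mean and minimum maps over subjects
on a shared grid (overall and per age group G1: 8–10, G2: 12–14, G3: 24,
G4: 48 months), recording the per-cell contributing count. Rigid
alignment into the common frame is assumed; no non-linear morphing is
performed, so averaged maps blur across residual anatomical variation.

## Synthetic phantom

The generator emulates exactly the geometric features the pipeline
measures: an outer surface that is a gently domed heightfield
(Gaussian dome, default amplitude 2.5 mm, σ = 30 mm, radius of curvature
> 300 mm — curved enough that projection-along-z and surface normals
measurably differ, so direction-convention bugs cannot hide, but flat
enough that offset surfaces are exact distance surfaces); an inner
cortical wall offset along the exact analytic normal by a configurable
thickness field (constant, linear, or sinusoidal, within the 0.3–4.5 mm
range reported for pediatric temporal bones); spherical air cells placed
by seeded rejection sampling strictly inside the shell (the accepted
count is recorded in the truth object, never silently altered); and a
dura sheet offset 1–11 mm below the surface, optionally with a
sphere-capped cylindrical sinus ridge rising toward the bone.

Ground truth is closed-form: CLT(x, y) = min(thickness, distance from the
surface point to the nearest air-cell wall); DDVS(x, y) = min(dura depth,
distance to the sinus axis segment − tube radius). Offset-surface
distances equal the offset exactly when the offset is below the surface's
radius of curvature and the fields vary slowly (error ≈ D·|∇D|²/2; with
default gradients ≤ 0.04 this is below a micrometre), so the dominant
recovery error is the mesh chord (sagitta) error, well under the 0.05 mm
test tolerance at the default 1 mm edge length. The bone mesh is
watertight by construction (outer + inner heightfields, boundary wall,
inverted cavity spheres) and identical configs yield byte-identical STL
output.

What the phantom does **not** model: real cortical-bone segmentation
noise, partial-volume thresholding artefacts, suture lines, nerve/vessel
channels in the interior surface, the facial nerve canal, ossicles, or
anatomically shaped sinus curvature. Passing the recovery suite therefore
demonstrates the measurement machinery is geometrically correct at
0.05 mm, not that segmentation-induced errors on clinical CT are that
small.

## Numerical and sizing choices

* Pruned queries are exact by construction; no tolerance trades accuracy
  for speed. Ray intersections use Möller–Trumbore with t > 1e-9 to
  avoid self-hits at the origin.
* Degenerate (zero-area) faces are dropped at load with a logged count;
  a mesh that becomes empty is an error. Meshes whose bounding-box
  diagonal is < 1 are rejected as probably metre-scaled unless units are
  given explicitly — never silently rescaled.
* The recovery suite runs five phantoms spanning 0.5–4 mm shell thickness
  and 1.2–11 mm dura depth on a 64 × 64 mm footprint at 1 mm mesh edge
  length and 1 mm sampling — sizes chosen so the whole suite stays
  desk-scale while every field family, air cells and the sinus ridge are
  exercised.
* Published-table reproduction (the thread-length recommendations) is
  exact arithmetic on the reference table and independent of the
  percentile convention.

## Known limitations

* CLT/DDVS are surface-mesh metrics; no voxel-intensity thickness is
  computed, so the results inherit whatever bias the upstream
  segmentation threshold introduced.
* The seven-region parameterisation beyond the prescribed boundaries is a
  reconstruction; region-level numbers for regions 1, 2 and 7 should be
  read with that in mind (and the boundaries adjusted via `RegionConfig`
  where better information exists).
* Screw clearance ignores the thread cylinder and any bone deformation;
  efficacy is proxied purely by CLT at the entry point.
* Cohort maps assume rigid alignment; landmark mismatch across subjects
  appears as blur, not as an error estimate.
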