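# Methods

## Geometry and coordinate conventions

All coordinates are millimetres. The isocentre is the origin; the treatment
beam travels along −z, entering from the +z side; the gaze fixation plane
lies at z = +132.5 mm; azimuth 0° is along +x, counterclockwise as seen from
the fixation plane. A fixation point at polar angle θ and azimuth φ sits at
radius r = 132.5·tan θ on that plane, and the clinical polar limit of 25°
bounds a feasible disk of radius ≈ 61.79 mm.

The patient model is a set of per-structure point clouds (globe, retina,
lens, cornea, ciliary body, macula, optic disc, target) in a *gaze-centered*
frame: primary gaze along +z, globe centre at the origin, nasal = +x for a
right eye (a left eye is mirrored in x; laterality has no other meaning
here). The rotation point defaults to the globe centre and is configurable.
Orienting the model toward a fixation point applies the minimal rotation
taking +z onto the gaze vector about the rotation point, then translates the
model rigidly so the target centre of mass sits at the isocentre.
Re-orientation always starts from the stored gaze-centered frame, so
composing orientations is exact and rigid-body invariants hold to machine
precision.

Default anatomy (all configurable, schematic adult eye): globe radius 12 mm;
retina an inner shell of 0.3 mm thickness extending 115° from the posterior
pole; cornea an anterior cap of the wall shell (24° half-angle, 0.6 mm);
lens an oblate ellipsoid (4.5, 4.5, 2.25 mm semi-axes) centred 5.3 mm behind
the anterior pole; ciliary body a 1 mm wall band between 40° and 58° from
the anterior pole; macula a patch 2° temporal of the posterior pole; optic
disc a patch 16.5° nasal (plus 1.5° superior) of it, giving a macula-disc
centre separation of ≈ 3.4 mm.

## Tumor model

The target is a dome following the inner eye wall: the intersection of the
eye ball with a second sphere chosen so that the dome's base is a spherical
patch of the requested area and its apex reaches the requested radial height.
Both the indicator function and the volume have closed forms (ball-ball
intersection, with the complement branch for domes shallower than the base
sagitta); the point cloud is rejection-sampled uniformly inside the dome with
the apex pinned so the realized height is exact at any point count. A base
patch beyond a hemisphere or a height above the globe radius is a geometry
error.

## Synthetic cohort

The cohort generator emulates the anatomical variability of a clinical OPT
population: target height 2.35–11.50 mm, base area 34.20–671.65 mm²,
implied dome volume constrained to 57.67–2795.21 mm³ by rejection; globe
radius uniform in 11–13 mm; two thirds of targets posterior to the eye
equator (base latitude −85° to −15°) and one third spanning the equator
(−15° to +35°), with uniform longitude and laterality. The generator
reproduces the *ranges and mix* of a clinical population, not its joint
distribution: real cohorts correlate tumor size with location, include
non-dome shapes, clip-registration uncertainty and eyelid geometry, none of
which are modelled — so green tests certify the pipeline's behaviour on
plausible geometry, not clinical performance.

## Dose model

A simplified passive-scattering broad beam, factorized per point as

    dose = prescription × depth_factor(WED) × lateral_factor(signed distance)

The eye is homogeneous water; the water-equivalent depth (WED) is measured
from the anterior globe-sphere intersection along the beam axis per (x, y)
column (columns missing the globe receive no dose). `depth_factor` is an SOBP
plateau with logistic fall-offs at the proximal and distal plateau edges;
`lateral_factor` is a logistic profile of the signed distance to the aperture
contour, value 0.5 exactly on the contour. 80–20 fall-off widths default to
1.0 mm (distal and proximal) and 2.0 mm (lateral); the logistic scale is
s = w/(2 ln 4). Per orientation, range = deepest target WED + distal margin
(default 2.5 mm), modulation covers the target depth extent plus both
margins (clamped to the range), and the aperture is the convex hull of the
target's beam-eye projection offset outward by the 2.5 mm lateral margin
(rounded corners via polygon buffering). Orientations needing more than the
35 mm range of 70 MeV protons or an aperture beyond the 35 mm blank are
untreatable and are recorded, not scored. Dose grids default to 60×60×60
voxels at 0.59 mm, centred on the globe so the eye is always covered.

Structure masks are pure voxel occupancy of the structure's points. Dx% and
V_D are exact order statistics of the mask-voxel doses (Dx% = minimum dose of
the hottest x%, an ICRU-style near-max convention; V_D = 100 × count
fraction, computed in that exact arithmetic order so independent sort-based
recomputation matches digit for digit). The optimizer's fast path evaluates
dose only at each OAR's occupied voxel centres — identical voxelization and
dose formula as the full grid, so the metrics agree exactly while skipping
voxels that contribute to no metric.

## Cost, NTCP and fractionation

Cost weights: macula = optic disc = 3, other OARs 1, in both the DVH-area
term (M = 20 levels at 5% steps of the 60 GyRBE prescription, volume-percent
values) and the named dose-volume points; mixed units across terms are
absorbed by the weights. The NTCP curves are two-parameter logistics per
endpoint (Table: maculopathy ← D2% macula, optic neuropathy ← D20% optic
disc, neovascular glaucoma ← D20% cornea, retinal detachment ← V55GyRBE
retina, cataract ← V27GyRBE ciliary body). No published (m50, k) pairs exist
for these endpoints in a form this package could verify, so the defaults are
documented placeholders — m50 at 80% of each metric's scale (48 GyRBE for
dose metrics, 80% for volume metrics), k = 6 GyRBE / 10% for a visibly
sloped curve — and every consumer treats them as configuration. The
maculopathy endpoint is tracked via visual-acuity deterioration, which
optic neuropathy also affects; the two curves are not independent in
reality. A stored 0.96 multiplicative threshold adjustment converts
published retina/ciliary dose-volume points between fractionation schemes;
it is deliberately kept distinct from the BED ratio
BED(4×14.3)/BED(4×15) = 0.9116 computed from first principles, because the
printed constant's derivation is not reconstructable and it is applied as
given.

## Gaze prediction and sampling

One 50-tree random forest per fixation-plane coordinate; the prediction is
the bagged mean, clamped radially to the feasible disk. Features are
geometric only (target COM relative to model centre and rotation point,
bounding extremes, distances to optic disc / macula / ciliary body, tumor
height / base area / volume); laterality, age and diagnosis are excluded as
uninformative. Leave-one-out evaluation retrains without the held-out
patient and reports planar (mm) and polar/azimuth (degree) deviations.

The sampler dart-throws the dense region (50 mm radius around the
prediction, clipped at the feasible-disk edge) with 9 mm minimum spacing and
the remaining disk with 25 mm spacing (9 mm to dense points; the cross-region
spacing is a design choice). The first dense dart is the prediction itself —
the single most likely treatment-viable fixation point, investigated first.
Fixed attempt budgets (200 dense, 150 sparse throws) realize the intended
operating point of ≈ 35 accepted candidates per run; at saturation the same
geometry would accept ~45–50. The queue is strictly FIFO, dense before
sparse, dense ordered nearest-to-prediction. Ties at equal minimum cost break
toward the smaller polar angle (clinically easier gaze), then smaller
azimuth. Early stopping (after a configurable number of consecutive
non-improving treatable evaluations) exists but is off by default.
Continuous maps are piecewise-linear interpolants over a Delaunay
triangulation of the treatable records, with nearest-sample values outside
the convex hull; untreatable orientations are excluded.

## Plan comparison

NTCP differences (automated − reference) in absolute percentage points, with
a 1-point threshold: improved (some endpoint drops ≥ 1 and none rises ≥ 1),
inferior (the mirror), trade-off (both), neutral (all |Δ| < 1). A difference
of exactly ±1.0 counts as a change; the four categories partition all
difference vectors. The physicist preference review is human judgment and is
represented only as a free-text annotation field.

## Numerical choices and problem sizes

Point densities and grid resolutions are configurable; the test suite runs
cohorts at 0.15–0.5 of the default point density and dose grids at 40³/0.885
mm where many thousands of candidate evaluations are needed (the
optimizer-vs-exhaustive check uses 20 patients × ~3000 lattice points), and
at the default 60³/0.59 mm elsewhere. Random draws all flow through seeded
`numpy` generators; identical seeds reproduce cohorts, samplers and forests
exactly. Degenerate inputs fail loudly with categorized errors
(configuration, geometry, feasibility, treatability, attribution, schema).

## Known limitations

- The guided sampler is built to *localize favourable regions* cheaply, not
  to resolve the global cost minimum to fine tolerance: proton penumbrae
  (~2 mm) sweeping across millimetre-scale structures (macula, optic disc)
  create cost ravines whose 2%-sublevel sets are narrower than the 9 mm
  dense sampling net, and cost maps frequently contain symmetric,
  near-equal-cost minima on opposite sides of the disk. Consequently the
  suite's strict oracle bound — every guided best within 2% of an exhaustive
  2 mm-lattice minimum — fails for part of the cohort (for low-cost patients
  especially, where the relative band is fractions of a cost unit). The
  attainable and verified guarantees are: the best record equals the argmin
  over everything evaluated, and dense-region containment of good solutions.
  Planners should read the maps, not a single returned point.
- Homogeneous-water eye, no wedge compensators, no range uncertainty, fixed
  RBE 1.1 folded into GyRBE, rigid optic nerve, no eyelid.
- NTCP parameters are placeholders; absolute probabilities are illustrative.
  Comparisons (differences, classifications) are meaningful only under the
  configured curves.
- EyePlan interoperability and fiducial-clip registration are out of scope;
  the JSON model format is this package's own.
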