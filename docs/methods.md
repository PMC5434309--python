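# Methods

`microgrind` reconstructs 3D anatomy from serial block-surface imaging
("microgrinding"): a resin-embedded specimen is ground down in thin runs,
every freshly exposed surface is stained and photographed, and the specimen
itself is destroyed in the process.  Each photograph shows the cross-sections
of three vertical fiducial sticks, and a micrometer caliper records the
remaining specimen thickness near each stick after every run.  The package
turns such a stack — images plus caliper CSV — into posed slices, tissue
label maps, a 3D label volume, watertight surfaces and morphometric
measurements.  Because no public dataset of this kind exists, the package
ships a phantom simulator that generates the whole input from analytic
ground truth, making every stage testable end to end.

## Coordinate model

Right-handed block coordinates in micrometers.  `z` is depth ground away;
`z = 0` is the first-run surface; the x/y origin sits at fiducial anchor A.
Images are row-major pixel rasters with pixel centers at
`(index + 0.5) * pixel_size`; image x runs along columns, y along rows, and
the block y axis follows image rows (no mirroring anywhere in the pipeline,
which lets the registration reject reflections outright).

Cut surfaces are planes `z(x, y) = g_x x + g_y y + c`.  The grinding machine
does not remove material uniformly: the emulated protocol removes ~35 um per
run near the structures of interest but up to ~94 um at the block periphery.
The simulator exposes a single mechanism for this spread — plane tilt.
`GrindingSchedule.tilt` is the per-run *increment* of the plane gradient:
with a constant gradient all planes would be parallel and removal spatially
uniform, so a linearly growing gradient is the simplest schedule that yields
a constant removal at anchor A together with a proportionally larger removal
far from it, every run.  Whether the physical spread stems from tilt or from
pressure distribution is not distinguishable from caliper data alone; tilt
is the modeled mechanism and the registration recovers it per run, whatever
its physical origin.

## Phantom simulator

A `PhantomSpec` is a block containing analytic solids — spheres, ellipsoids,
capsules, flat-capped tubes — each labeled with one of six classes: resin,
bone, cartilage, vessel, soft tissue, fiducial.  Overlap precedence is
soft tissue < bone < cartilage < vessel < fiducial, so channels are never
occluded by the solid they pierce and the fiducial columns are drilled
through everything.  Presets provide an ossicle-like vocabulary: a bone
sphere with a vessel channel (`two_sphere_test`), a sphere whose axial
channel occupies exactly 1.0 % of the enclosed volume
(`one_percent_channel`, tube radius 125/3 um over 960 um — closed form, no
tuning), incus-like and malleus-like bodies with seeded cartilage islands
and vessel networks (channel radii 7–42 um, matching the few-tens-of-um
regime of real ossicle vasculature), a thin-walled stapes-like arch with
~116 um crura, and a Y-branching vessel.

Grinding defaults mirror the emulated protocol: 35 um nominal abrasion,
up to 151 runs, caliper readings rounded to 1 um (the instrument's
quantization is the dominant plane-estimation noise), abrasion noise 2 um
SD, in-plane jitter 10 um (2 px) translation SD and 0.5 deg rotation SD per
slice, 5 um pixels.  Staining emulates a Mann-Dominici-type surface stain as
per-class Gaussian RGB colors (bone orange-pink, cartilage metachromatic
violet, vessels dark red, mucosa pale violet, resin near-white, wood brown;
noise SD 4 intensity units).  The uncolored resin lets structures up to
150 um below the cut plane shimmer through; the renderer tints resin toward
the deep structure's color with weight `0.5 * exp(-depth / 50 um)`.  What
the simulator does *not* model: optical PSF, specular reflection, grinding
scratches, stain variability between laboratories, deformation.  Passing
tests therefore validate the geometry and algebra of the pipeline, not its
robustness to real-world optics.

`analytic_class_volumes` is the ground-truth oracle: dense voxelization at
2 um with the same precedence rules.  The in-plane sample lattice of each z
row is shifted by golden-ratio offsets because a fixed lattice digitizes
thin cylinders with a systematic few-percent area error; quasi-random phases
decorrelate it (sphere volumes agree with closed form to <0.5 %, 25-um tubes
to <1 %).

## Registration

Three fiducials give 6 constraints for the 4 similarity parameters, so the
in-plane fit is a least-squares Procrustes (Umeyama) with the RMS residual
reported as a drift alarm (stick wobble would show here).  Reflections are
rejected; scale is estimated by default (photography distance may vary) but
clamped to [0.98, 1.02] to prevent degenerate fits.  Fiducials are labeled
geometrically (lowest `x*1e6 + y` is A, then counter-clockwise), not by
color — real wooden sticks are indistinguishable.  The cut plane is solved
exactly from the three caliper readings (3 equations, 3 unknowns), so the
plane reproduces the readings to the 1-um caliper quantization by
construction.  On default phantom noise the recovered poses are within
0.03 deg and 0.15 px of truth; the acceptance bounds are 0.05 deg / 0.5 px.

## Segmentation

Per-pixel maximum-likelihood classification under the per-class Gaussian
color model, then a 3x3 majority filter (radius 1 px; it biases the width of
structures thinner than ~3 px, which is why the default `min_area` of
200 um^2 — about two pixels — also discards anything indistinguishable from
stain debris).  Show-through is handled in color space: mixture components
are placed along each resin-to-class segment at 1/3, 2/3 and all of the
maximum show-through opacity and classify as resin.  Without them, the
resin-to-bone blend of a structure just below the surface passes near the
soft-tissue color and produces phantom "internal soft tissue" at structure
caps (observed to corrupt the not-calcified fraction threefold).  A separate
`deep_vessel_evidence` channel exposes sub-surface vessel courses for
inspection without pretending to do 3D deconvolution.  Contours are
marching-squares iso-lines at 0.5, grouped into exteriors (CCW) and holes
(CW) by containment, with sub-pixel vertices mapped through the slice pose.
Manual contour CSVs are supported so a real study can trace structures by
hand instead of trusting the color model.

## Reconstruction

The primary path rasterizes posed label maps into an isotropic volume:
every voxel takes the class of the nearest cut plane along z at that (x, y),
with each plane's own tilt (or, for comparison, the flat-stacking
approximation using mean plane heights).  Nearest-plane (zero-order) fill is
deliberate: the ground surfaces destroy the material between planes, so no
intermediate shape is invented; the cost is a bias of order gap/2 at
structure caps, and coverage is clipped to the span between the first and
last planes rather than extrapolated.  Default voxel size is
`min(pixel_size, median_gap / 3)` — volume error is dominated by the ~35 um
z-sampling, not by 5-um pixels.

Two numerical details matter.  Labels are sampled by an area-majority vote
over each voxel's in-plane footprint: point sampling aliases by ~1 % in
volume whenever the voxel and pixel grids are commensurate (voxel centers
land exactly on pixel boundaries).  And the frequent two-class ties at
smooth boundaries are broken by one extra sample offset by an irrational
fraction of a pixel — breaking ties by class order instead would erode every
structure by the tie set (~0.6 % volume).

Surfaces are marching-cubes iso-surfaces of the class indicator at 0.5 on
the padded volume, small components dropped, optional Taubin smoothing
(lambda 0.5, nu -0.53; volume drift <1 % over 20 iterations), watertightness
verified and recorded.  The lofting path stitches matched contours across
slices in the CAD tradition: rings are matched by IoU and centroid distance,
chains of 1-1 matches are resampled on one shared arc-length knot set
(union of all ring vertices, or 256 uniform knots if that explodes) so
strips and caps share vertices exactly and the result is edge-manifold by
construction.  Caps use a centroid fan when the ring is star-shaped, ear
clipping otherwise.  Components with branchings or interior holes fall back
to rasterize + iso-surface with a log notice — how a CAD operator would
bridge a bifurcation is genuinely underdetermined, and the voxel route
handles arbitrary topology (a Y-branch yields one watertight genus-0 mesh).
Prism-like lofts are exact: five stacked unit squares give the prism volume
to machine precision.

## Morphometry

Mesh volume is the classic signed-tetrahedron sum over triangles, referenced
to the mesh centroid for conditioning, divided by 6 once at the end so
integer-coordinate meshes are exact; origin independence is asserted on
every call and non-watertight input is rejected with the boundary-edge
count.  The not-calcified fraction is
`100 * (vessel + cartilage + soft tissue) / (bone + those)` over interior
material only: a connected internal-class component counts when it borders
the bone/tissue complex more than it borders the surroundings — this admits
vessel canals that pierce the cortex while excluding the mucosal layer
draped on the outer surface (the outer bone surface, not the mucosa, is the
structure boundary).  Channel diameters are `2 x` the Euclidean distance
transform sampled on the 3D skeleton (Lee thinning; if thinning annihilates
a perfectly symmetric even-width tube, the EDT ridge substitutes), accurate
to one voxel on cylinders across the 14–83 um regime of interest at 5 um
voxels.  Local thickness (largest inscribed sphere) is computed by sphere
painting over integer radius bins, each dilation realized as a distance
transform threshold; one voxel is subtracted for the half-voxel overreach on
each side.  The diffusion screen flags voxels whose distance to the nearest
non-class voxel exceeds the limit (default 150 um, the literature diffusion
range of lamellar bone, exposed as a parameter since it is a cited value,
not a measured one); a structure is "fully diffusion-supplied" when nothing
is flagged — a 120-um wall passes, a solid 500-um sphere flags its analytic
core fraction (350/500)^3 to within 2 points.  Reports print um^3 and mm^3
side by side; published absolute ossicle volumes carry ambiguous units and
are never asserted.

## Verification experiments and problem sizes

All tests run on synthetic phantoms at desk scale: 9–50 slices of
280 x 280 px, volumes up to ~2.6 M voxels, chosen so the full suite and the
acceptance script each finish in minutes on one CPU.  Headline checks:
sphere volume through the full noisy pipeline within 3 % (typically ~0.2 %);
pose recovery on 50 jittered slices within 0.05 deg / 0.5 px; the 1.0 %
not-calcified phantom recovered within 0.1 points; tilt-aware reconstruction
strictly beats flat stacking voxel-wise in every replicate, and on the mean
of three replicates its net volume error is under half the flat one (the
mean is used because flat stacking shuffles material between columns, so its
much larger voxel error can cancel in the net volume of a single
realization).  Convergence is demonstrated on the symmetric-difference
volume error (total volume of voxels classified differently from ground
truth): it halves when the slice gap halves (140/70/35 um) and when the
voxel size halves (40/20/10 um against a 5-um reference).  The *net signed*
volume error is not monotone in the gap — nearest-plane stacking is a
midpoint rule whose signed error oscillates with plane phase — which is why
the stricter symmetric-difference metric is the convergence measure, while
the net error is separately bounded by the 3 % recovery check.

## Known limitations

Single-specimen workflows only (no cross-specimen registration or stain
normalization); the Gaussian color model assumes stain colors cluster, which
real bone/cartilage boundaries may not honor; lofting does not stitch
branchings directly; the simulator's noise model is far simpler than real
photography; `import_external_label_volume` expects an already segmented
uCT-style label volume and does not reconstruct from projections.
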