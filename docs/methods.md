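# Methods

This note documents the models, numerical choices and limitations behind
`cortexstack`.  Everything quantitative stated here is computed by the
test suite or the acceptance script.

## Coordinate conventions

All world coordinates are micrometers, axis order (x, y, z) =
left→right, posterior→anterior, inferior→superior.  Voxel indices are
0-based and refer to voxel centers; the world position of voxel
`(i, j, k)` is `origin + index·spacing`.  Only axis-aligned grids are
supported (NIfTI affines with off-diagonal terms are rejected): the
pipeline's own products are axis-aligned, and supporting oblique frames
would complicate every resampling contract for no benefit here.  The
mirror plane for left-right symmetrization defaults to the grid's world
center, where mirroring is an exact array flip and hence an exact
involution; any other plane goes through resampling.

## Tile shading and stitching

Vignetting is modeled as a single multiplicative field per channel,
estimated as the per-pixel mean (or median) over a tile sample and
normalized to mean 1; correction divides each tile by the field.  With 60+
tiles of flat scenes and 1 % noise the field is recovered to < 1 % RMS.
Channel 3 (the injection-site channel) is typically excluded from
correction by callers because too few of its tiles carry signal.

Stitching trusts the microscope's world-coordinate offsets verbatim.
Each tile is cropped `crop` pixels (default 50) on every border that
faces another tile; borders on the section hull are kept so the canvas
stays covered.  Blending weights are separable linear ramps rising from 0
at a cropped border over `max(overlap − 2·crop, 1)` pixels, normalized to
a partition of unity; output pixels covered only with zero ramp weight
fall back to the plain average of covering tiles.  Ties at exact borders
therefore resolve to the neighboring tile's interior value,
deterministically.  Uncovered *interior* pixels are a hard error listing
gap bounding boxes.  Note the protocol defaults (80 px overlap, 50 px
crop) leave no overlap after cropping; geometrically consistent use needs
`overlap > 2·crop`, and the stitcher warns when cropping exceeds the
implied overlap.

## Injection site, cells, tracer maps

The injection site is the largest 26-connected component after Gaussian
smoothing (default σ = 100 μm, i.e. 2 voxels at the 50 μm working
resolution — the smoothing scale is not dictated by the acquisition, so a
2-voxel kernel is used as the weakest smoothing that regularizes the
threshold) and thresholding at half the smoothed maximum.  The result is
invariant to uniform intensity rescaling by construction.

Cell detection treats a probability map (from any producer — the
threshold-based stand-in here, or a trained network) as input: strict
local maxima over the full 8/26-neighborhood with probability ≥ 0.5;
equal-probability plateaus collapse to their centroid; non-maximum
suppression within a caller-set separation runs in descending probability
order with lexicographic tie-breaks, so output is deterministic.

The tracer *density* conserves counts exactly: each output voxel counts
the tracer-positive pixels whose centers fall in its 50×50 μm in-plane
bin of one section.  The *normalized intensity* is
`max(ch2 − ch1, 0) / max outside the injection site`, where "outside"
excludes the mask dilated by 2 voxels (the site saturates, and a margin
keeps partial-volume bleed of the blob out of the normalization maximum;
the margin width is configurable).  Values inside the site may exceed 1
and are not clamped.  Multi-injection composites take the voxelwise
maximum of normalized maps.

Laminar labels use relative cortical depth with the supra-/infragranular
boundary at depth 0.5 by default — a configurable surrogate for cortical
layer IV, which a synthetic pipeline cannot locate histologically.

## The flatmap stack

A flatmap stack is a (U, V, D) grid — default 500×500×50, dividing the
cortex into 50 equidistant depth layers — whose in-plane axes come from
the 2D flatmap coordinates of a triangulated mid-surface and whose depth
axis runs from the inner (white matter, depth 0) to the outer (pial,
depth 1) boundary.

**Direction field.**  The default construction solves the harmonic depth
potential: Laplace's equation with Dirichlet values 0 on the inner
boundary shell and 1 on the outer shell and reflecting lateral sides,
discretized as count-normalized 6-neighbor averaging and solved exactly
by conjugate gradients (initialized with the normalized distance-transform
ratio); the field is the normalized gradient of the lightly smoothed
(σ = 1 voxel) potential.  The classical alternative — seeding boundary
voxels with surface normals and diffusing the *vectors* by renormalized
Jacobi sweeps — is available as `method="vector"`; its fixed point
acquires a few degrees of tangential tilt near rasterized patch edges
(the staircase boundary biases the equilibrium), which the scalar
potential avoids because its continuum solution is exactly
boundary-orthogonal.  On the shell phantom the potential field is radial
to a median 0.3°, the vector field to ~2°; both satisfy the < 5° check.
Boundary seed normals (needed for the vector method and for seeding
trajectories) are the gradient of the smoothed distance to the *opposite*
boundary, which stays clean at lateral mask cuts where a mask-gradient
normal tilts sideways.

**Trajectories.**  Fixed-step midpoint (RK2) integration of the
trilinearly interpolated field, step = half a voxel, starting on the
interface between the inner shell and the interior (inner-shell voxel
centers advanced half a voxel along the field).  A trajectory terminates
successfully within 3/4 voxel of the outer shell, or when it exits the
domain within 2.5 voxels of the outer shell (rasterized patch edges leave
small gaps in the one-voxel shell); any other exit, or exceeding 5× the
estimated cortical thickness, marks it failed.  Failed trajectories are
excluded and counted, never silently filled; more than 20 % failures
aborts the build.  On the 1–2 mm shell ~3 % fail, all at the patch rim.

**Flat coordinates.**  Each trajectory takes the (u, v) of its
mid-surface crossing: the flatmap coordinate of a mesh vertex when one
lies within a voxel of the trajectory, otherwise barycentric
interpolation at the closest point of the crossed triangle (searched in
the nearest vertex's one-ring, so no spatial index over triangles is
needed).  Depth along a trajectory is relative arc length.  Because
vertex inheritance quantizes (u, v) to the vertex grid, the phantom's
mid-surface mesh is generated ~4× finer than the voxel size; with that
density the inherited coordinate is accurate to a fraction of a voxel.

**Dense maps.**  Scattered (world ↔ (u, v, depth)) trajectory samples
(4 seeds per inner-boundary voxel by default, tangentially offset) are
densified into the forward map `to_world` (per stack voxel) and the
inverse map `from_world` (per cortex voxel) by inverse-distance-squared
interpolation over the k = 8 nearest samples, with exact pass-through at
coincident points.  One scheme serves both directions; samples that
overshoot past the outer shell are dropped so the forward map never
points outside the data support.  On the shell phantom at default size,
recovered depth agrees with the analytic depth to a mean |Δ| ≈ 0.015 and
recovered (u, v) to a mean ≈ 1.6 stack voxels (the acceptance thresholds
are 0.05 and 2).

**Isotropy validation.**  Seeds placed equidistantly in stack layers
(defaults 5, 25, 45) are mapped to world space, surrounded by spheres
sampled uniformly on the surface (seeded RNG), and mapped back; the
3×3 covariance of the back-projected stack coordinates gives eigenvalues
λ1 ≥ λ2 ≥ λ3 and the isotropy score `sqrt(λ3/λ1)` — the ratio of the
shortest to longest ellipsoid semi-axis, 1 for a perfect sphere.  Only
the score's range is fixed by convention; this definition is documented
and configurable.  Under an exact affine map the score is independent of
the sphere radius (the test asserts equality), and a 2× uniaxial stretch
scores exactly 0.5 up to finite-sample covariance noise.  Spheres that
leave the cortex are skipped and counted — validating layer 45 of a 1 mm
thick cortex needs a sphere radius below ~80 μm.

## Symmetric gradient directions

A left-right-symmetrized HARDI template must satisfy
`S(x, n) = S(x, −n)` (antipodal) and
`S(x, y, z, nx, ny, nz) = S(−x, y, z, −nx, ny, nz)` (mirror).  Directions
are therefore lines (one representative per antipodal pair) whose set
must map to itself under `M = diag(−1, 1, 1)`.

The optimizer places mutually repelling charges on the sphere: total
energy `Σ 1/d` over distinct line pairs with the antipodally symmetrized
chordal distance `min(‖u−v‖, ‖u+v‖)`.  Mirror closure is enforced *by
construction*: `n = 2k` lines are parametrized as k free representatives
plus their exact mirror images (for odd n, one extra line is confined to
the mirror plane, where a line is its own mirror image up to antipode).
Energies are evaluated on the deduplicated line set: a literal
multiplicity-4 orbit expansion would assign infinite self-energy to any
configuration with a line on the mirror plane or axis — which includes
the optimal mirror-closed orthogonal triple for n = 3 — so orbit
coincidences are treated as single charges, which is also what the
physical charge picture prescribes.  Projected gradient descent with
backtracking makes the accepted energy sequence non-increasing; the
optimum for n = 3 is the orthogonal triple (verified against a
brute-force grid search), and n = 64 (seed 0) yields 64 representatives
with exact closure and a 14.8° minimum pairwise angle, versus ~1.4° for
the median random symmetric scheme.

Spherical interpolation operates per b-value shell on the antipodally
symmetrized angle; b = 0 volumes pass through.  Two kernels: the default
inverse-angular-distance over the k = 8 nearest source directions
(a robust zeroth-order smoother, ~3 % relative RMSE on a single-tensor
128→64 resampling), and a Gaussian RBF in angle (bandwidth two mean
inter-direction spacings, ridge 1e−8, weights normalized to a partition
of unity so constants are exact) that reaches ≪ 1 % on the same task and
is used where accuracy matters.  Whether interpolation should run on raw
signals or a spherical-harmonic fit is an open modeling question; raw
signals are used here.

Population averaging is the voxelwise weighted mean `Σ wᵢIᵢ / Σ wᵢ` —
weights like `1/(1 + tracer)` suppress tracer-dominated voxels, zero
weight excludes missing tissue, and all-zero-weight voxels fall back to
the unweighted mean (logged).  With mirroring on, every input is pooled
with its x-flipped copy (HARDI channels permuted by the direction
mirror-permutation), so the output is exactly mirror-invariant and the
operation is a projection.

## Streamlines

"Touching" and "visiting" are decided on the polyline densified to at
most half-voxel steps; segments subdivide into power-of-two pieces, so
the sample set equals the vertices plus recursively inserted midpoints
(the criterion a vertex+midpoint oracle checks exactly).  Density images
count *distinct* streamlines per voxel — the track-density-imaging
convention — not visitation multiplicity.  Selection returns original
geometry, never the densified copy.

## Statistics

NCC is the Pearson correlation over an explicit mask (default: union of
the nonzero supports — comparisons are cortex-restricted, not
full-grid).  Degenerate inputs raise; similarity matrices record
degenerate entries as missing (NaN), never as silent zeros.  Permutation
tests are two-sided with the add-one correction
`p = (1 + #{|r_perm| ≥ |r_obs|})/(1 + n_reps)`, never exactly zero, and
super-uniform under the null; the suite calibrates the type-I error rate
at α = 0.05 over 1,000 null simulations with 999 permutations each
(tolerance ±0.02).  Dice of two empty masks is 1 by convention (logged).
In landmark reports, ties between the automation/manual and
manual/manual medians count for the manual group (the conservative
choice).

## The phantoms: what they do and do not emulate

The generators are pure functions of parameters and seed, and every
phantom ships its ground truth.  The shell cortex has closed-form depth
`(‖p‖ − r_in)/(r_out − r_in)` and an equirectangular patch flatmap that
is injective and distortion-bounded; its defaults (1–2 mm radii, 50 μm
voxels, 120° patch) give a 20-voxel cortical thickness comparable to the
working resolution of the real pipeline.  The 3-channel volume plants a
saturated injection sphere, meandering 2-voxel-thick fiber tubes at 3,000
intensity over a ~1,000 ± 50 background (≫ 5 background SDs), and
well-separated Gaussian cell spots; multiplicative Gaussian noise
(default 2 %, clipped at 0) mimics the scale dependence of fluorescence
noise without committing to a Poisson model.

What passing tests on these phantoms show: the geometric and statistical
machinery is correct at realistic scales and noise levels.  What they do
not show: performance on real tissue — no gyrification (the shell is
convex; the real validation reports anisotropy precisely at gyri), no
optics/PSF or section-alignment artifacts, no realistic axon morphology,
no histological layer IV.  Real-data headline figures (cortical Dice
against external atlases, human-expert cell-detection rates, published
injection-overlap percentages) require the original datasets, trained
networks and atlases, and are out of scope.

## Problem sizes

Default test and acceptance runs use the 1–2 mm shell (85³ grid, ~68k
cortex voxels, ~10k trajectories, 500×500×50 stack; ~1 minute end to
end), a 600 μm slab, 200-streamline tractograms, and 1,000-repetition
permutation calibrations — sizes chosen so the full suite exercises the
default, full-resolution stack geometry while remaining a desk-scale
computation.
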