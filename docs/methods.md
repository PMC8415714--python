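# Methods

## Scope and data model

The package analyzes reconstructed 3D grayscale volumes of fruit
(`VoxelVolume`): unsigned 8/16-bit intensities on an isotropic grid with
voxel size in μm. Slice index 0 is the calyx end and the last slice the
stem end; the loader records this convention but cannot verify it, so
axial profiles are reported in slice order and the user is responsible
for scan orientation. Coordinates are 0-based voxel indices; the physical
position of voxel *i* is (i + 0.5)·voxel_size (voxel-center convention).
Tomographic reconstruction is out of scope — the pipeline consumes
reconstructed volumes only.

16→8-bit conversion maps v → round(255·(v−w₀)/(w₁−w₀)) with
half-away-from-zero rounding; the default window is the observed min/max,
which is parameter-free and preserves the histogram shape the valley
detector needs. A threshold chosen on one scale can be mapped through the
same window, so phase classification commutes with conversion up to
quantization.

## Segmentation

Air surrounding the fruit is as dark as the pores, so segmentation is
two-stage:

1. **Fruit mask.** Otsu threshold on the full volume, largest 26-connected
   bright component, 3D hole filling. A largest component below 1 % of
   the volume raises "no object found".
2. **Pore/tissue threshold.** The gray-level histogram of masked voxels
   (256 bins at 8 bit, 1024 at 16 bit) is smoothed with a centered moving
   average (default window 9 bins — wide enough to suppress sampling
   noise in the valley, narrow enough not to merge modes). The two
   highest distinct local maxima are taken as the pore and tissue modes
   and the threshold is the center of the lowest bin strictly between
   them (ties resolve to the lowest intensity). Unimodal histograms fall
   back to Otsu, flagged in the output. Thresholds are per-volume, never
   shared across samples.

Pore labeling is strict (`intensity < T`), which lets fractional
thresholds on integer scales behave exactly as printed values like 69.7
suggest.

## Pore morphometry

Pores are 26-connected components ("face, edge, or corner" adjacency;
6-connectivity is available for sensitivity checks). Equivalent diameter
is the diameter of the sphere with the pore's volume,
d_eq = (6V/π)^(1/3). Porosity is the pore-voxel fraction of a region, in
percent; per-slice porosity uses each slice's fruit-mask cross-section,
and slices with an empty cross-section are flagged rather than
zero-filled. Size-class histograms use 100-μm classes centered at 100,
200, …, 3000 μm with nearest-center assignment (diameters at or beyond
the top edge go to the top class). "Mean pore diameter" is the unweighted
mean of d_eq over pores; a volume-weighted variant is exposed as a flag.
No minimum-size filter is applied by default (single-voxel pores count);
`min_voxels` exists because scanner-noise handling is a per-study choice.

At ≥ 10 voxels per diameter, digitized-sphere d_eq is within 5 % of the
analytic value; tests enforce this bound and the exactness of the
formula on closed-form volumes.

## Pore-network skeleton

The pore phase is thinned to a one-voxel centerline by parallel
topology-preserving simple-point deletion (Lee-style thinning via
scikit-image, 26-connected object / 6-connected background). Thinning
can annihilate very small components outright, so a representative voxel
(nearest the component centroid) is restored for any pore component left
without a skeleton voxel; component counts are then preserved by
construction and verified on random fields.

Graph decomposition classifies skeleton voxels by 26-neighbor count
(1 endpoint, 2 path, ≥ 3 junction), merges 26-adjacent junction voxels
into one node at their centroid, and traces degree-2 paths into edges.
Conventions, fixed and documented rather than inferred:

- **Body radius** of a node = maximum distance-map value over its voxels
  (largest inscribed sphere). **Pore length** = body diameter (2r),
  averaged over all nodes.
- **Throat** = graph edge. Path length sums center-to-center Euclidean
  steps (1, √2, √3 voxels). Throat diameter = 2·min distance-map value
  over the path interior, capped at 2·min(body radii) — a throat is
  never wider than the bodies it connects. Throat length = path length
  minus the two incident body radii, floored at 0.
- **Coordination** = incident edge count, averaged over *all* nodes
  including isolated ones, so a pore space of disconnected voids reports
  average and maximum coordination 0.
- **Spur pruning**: endpoint-terminated edges into a junction shorter
  than 2 voxel sizes are removed iteratively to a fixpoint (junctions
  reduced to degree 2 are absorbed on re-extraction).
- **Isolated voids**: the skeleton of a compact void is a short segment
  lying inside the void's inscribed sphere; a two-endpoint component
  whose single edge has throat length 0 is therefore collapsed to one
  isolated node. Pure skeleton cycles with no endpoints or junctions
  likewise become single isolated nodes (their loop length is not
  reported).

On capsule phantoms the skeleton's end-to-end length is within a few
voxels of the true axis length (thinning erodes free tips by roughly one
radius), total path length tracks the true centerline length within 5 %
on the tube fixtures used in tests, and throat diameters recover true
radii within 10 %.

## Risk zones and core

The mesocarp is partitioned by normalized depth
u = d_core/(d_core + d_skin), with d_core the Euclidean distance to the
core surface and d_skin the distance to the fruit exterior: u < 1/3 is
the inner low-risk shell (LRA), u < 2/3 the middle shell (MRA), the rest
the outer high-risk shell (HRA). The fruit-anatomical zone boundaries
are not numerically defined in general, so equal thirds of normalized
depth are the default and the fractions are exposed as parameters. For
concentric spheres u is linear in radius, which the tests use as the
geometric oracle. Per-zone porosities recompose exactly to the
whole-mesocarp porosity as a voxel-count-weighted mean.

Core extraction assumes the core images brighter than the flesh: within
the central third of the fruit's bounding box, the smoothed histogram
must show a mode brighter than the dominant (flesh) mode; the threshold
is the deepest valley between the two, and the candidate component
containing the fruit centroid is kept and morphologically closed. Absent
such a mode — the no-contrast situation typical of disordered fruit —
extraction fails as a *reported outcome* and the pipeline proceeds with
a geometric fallback core (central ellipsoid at 0.25 of the fruit's
half-extents), flagged in the report.

Core shape: solidity = voxel volume / convex-hull volume of voxel
centers, clamped at 1.0 because digitization can push the raw ratio
marginally above 1 for convex bodies; sphericity =
π^(1/3)·(6V)^(2/3)/A with A from a marching-cubes surface mesh (naive
voxel-face counting overestimates smooth surface area by ~1.5× and would
break sphericity ≤ 1; the mesh estimator keeps digitized balls in
[0.9, 1.0]).

## Synthetic phantoms

Phantoms emulate the measurement situation, not the physics: a
fruit-shaped (ellipsoidal) or slab-shaped tissue matrix with dark
spherical pores, optional brighter core, and independent Gaussian
intensity noise (defaults: tissue 160, pore 30, air 10, core +40,
sd 8 — a deeply bimodal 8-bit histogram). Voxelization uses the
center-inside rule. Pore centers are drawn from the fruit interior with
a per-slice axial weight (constant, U-shaped with ends ≈ 4× the middle,
or linear), with a 2-voxel placement margin so objects never touch the
fruit surface (one voxel for the sub-voxel center jitter, one so pores
stay interior and hole-fillable). Placement stops when the pore-voxel
fraction reaches the target within half of one object's expected
contribution, or at the object count implied by a count-density target;
exhaustion (10× the expected placements) raises a generation error
naming the constraint. With overlap disabled, placed spheres keep a
>1-voxel moat so 26-connected labeling recovers them one-to-one.
Identical spec + seed give bit-identical volumes and truth.

Named presets fix the study conditions once:

| preset | grid | voxel | target | pores |
|---|---|---|---|---|
| healthy_whole | 128³ | 79.4 μm | 3.52 % porosity | lognormal, median 240 μm |
| corkspot_whole | 128³ | 79.4 μm | 9.37 % porosity | lognormal 260 μm, U-shaped axial profile |
| healthy_mesocarp | 96³ slab | 79.4 μm | 1.0 % porosity | lognormal 240 μm |
| mra_corkspot | 96³ slab | 79.4 μm | 5.0 % porosity | lognormal 260 μm |
| hra_corkspot | 96³ slab | 79.4 μm | 20.0 % porosity | lognormal 300 μm |
| healthy_flesh | 192³ slab | 2 μm | 5 % porosity | fixed 22 μm, non-overlapping |
| corkspot_flesh | 224³ slab | 2 μm | 8 % porosity | fixed 87 μm, non-overlapping |

The whole-fruit targets are the healthy/cork-spotted porosities the
package is designed to measure; the zone presets sit inside the reported
risk-zone brackets (HRA 15–30 %, MRA ≈ 5 %, healthy < 1.5 %), with the
healthy-mesocarp value fixed at 1.0 % mid-bracket; the flesh presets use
the healthy/cork-spotted pore diameters (22/87 μm). Grid extents are
package sizing choices: 128³ whole-fruit grids and 192³/224³ flesh
slabs recover porosity and diameter targets at desk scale, and the
flesh voxel size is 2 μm rather than the 0.5 μm of the original
high-resolution scans (at fixed sphere diameters the digitization error
at 11+ voxels per diameter is already below the 5 % test band).
Whole-fruit presets carry no denser core by default — a third histogram
mode can outrank the pore mode in the two-highest-maxima valley rule —
and core-bearing phantoms are constructed explicitly where core
extraction is under test.

What the phantoms do **not** emulate: partial-volume blur at phase
boundaries, beam hardening, ring artifacts, spatially correlated noise,
anisotropic pore shapes, and real pore-space connectivity beyond what
overlapping spheres produce. Passing the recovery suites therefore
demonstrates correctness of the measurement chain on well-posed binary
phantoms, not robustness to every scanner artifact.

## Statistics

Percent-valued morphometrics are variance-stabilized with
asin(√p) before comparison. Group comparisons use the Welch
(unequal-variance) two-sample t-test with Welch–Satterthwaite degrees of
freedom — a robust default where the original analysis software is not
further specified. Reported dispersions are standard deviations, and the
output says so. A Monte-Carlo check (1000 null replicates of n = 10
Beta-distributed percentage samples) keeps the empirical type-I error
within [0.03, 0.07] at α = 0.05.

## Numerical and degenerate-input choices

- Histograms bin integers exactly (unit-width bins centered on integer
  gray levels), so valley centers land on integer values; thresholds
  remain real-valued.
- Empty pore phase: skeletonization returns an empty skeleton; network
  statistics on an empty graph are all zero with n = 0.
- Empty regions/masks raise errors rather than returning 0 (an empty
  denominator is a caller bug, not a measurement).
- `ConvexHull` degeneracies (coplanar or < 4 points) report solidity 1.
- Determinism: every stochastic step draws from one seeded generator;
  pipeline reports are byte-identical across reruns apart from the
  timestamp.

## Known limitations

- The valley rule assumes a bimodal masked histogram; heavy noise
  (component sd approaching half the mode separation) degrades both the
  threshold and the porosity estimate, and the Otsu fallback changes the
  estimator class silently except for the `source` flag.
- Skeleton-based throat metrics depend on thinning artifacts near
  junction clusters; maximal-ball or watershed pore-network extraction
  is out of scope.
- Tip erosion biases path lengths short by about one body radius per
  free end; on short stubby channels this can exceed the 5 % band the
  tube fixtures meet.
- The axis convention (calyx first) cannot be checked from data; axial
  profiles of misoriented stacks are silently reversed.
- Risk-zone shells are geometric (normalized depth), not anatomical;
  real mesocarp zonation does not follow exact equal thirds.
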