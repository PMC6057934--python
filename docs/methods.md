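# Methods

`plastoquant` quantifies filamentous protein networks (the FtsZ-based
"plastoskeleton" of chloroplasts) in single-channel confocal z-stacks.  The
pipeline has four stages — segmentation, gross morphology, spatial-graph
extraction, element descriptors — followed by a two-group statistical
comparison, and ships a synthetic phantom generator with exact analytic
ground truth so every stage can be validated without microscopy data.

## Geometry conventions

Arrays are indexed `(z, y, x)`; physical coordinates are micrometres with the
origin at the corner of voxel `(0, 0, 0)` and voxel centres at
`(k + 0.5) * spacing`.  Spacing resolution order is CLI flag > config file >
TIFF (ImageJ-style) metadata.  Thicknesses are reported in nanometres.
Confocal voxels are strongly anisotropic (the motivating acquisitions used
0.021 x 0.021 x 0.240 um); every distance, volume and filter window in the
pipeline is computed in physical units.

## Segmentation

A voxel is foreground iff its intensity exceeds the local mean in an
anisotropy-aware box window times `(1 + offset_fraction)` (defaults: window
radius 0.5 um, offset 0.10; reflective boundary).  The threshold is purely
relative, so segmentation is invariant to uniform intensity scaling, and it
requires a non-zero detector baseline to be well defined — fluorescence
stacks have one; the phantom renderer adds one explicitly.  A light Gaussian
denoising filter (default sigmas 0.12/0.05/0.05 um, i.e. below the PSF) runs
before thresholding; without it, threshold-crossing noise forms a fuzzy halo
attached to the structures.  Cleanup removes 26-connected components below
`min_component_voxels` (default 50) and fills single-voxel cavities.  The
original workflow's interactive correction step is represented by replayable
add/remove edit masks, so runs are reproducible from their inputs.

## Wrapped hull and shape descriptors

The wrapped hull is the union over z-slices of each slice's filled 2D convex
hull of the foreground (degenerate slices with < 3 non-collinear pixels
contribute themselves).  From it: enclosed volume `V_EN` (hull voxels x voxel
volume), network volume `V_PN` (mask voxels), volume density
`rho_PN = V_PN / V_EN`.  The shape matrix is the covariance of the hull's
surface voxel centres; with eigenvalues `l1 >= l2 >= l3`,

- stretch `St = 1 - sqrt(l3 / l1)` (0 isotropic, -> 1 elongated),
- oblateness `Ob = 2 (sqrt(l2) - sqrt(l3)) / (sqrt(l1) - sqrt(l3)) - 1`
  (+1 plate-like, -1 rod-like, defined as 0 when `l1 - l3` underflows),
- `d_max`, `d_min`: surface-point extents along the first and third
  eigenvectors.

These are the standard triaxial shape-tensor forms; they satisfy the stated
ranges and the prolate/oblate limits exactly (a prolate surface has
`l2 = l3`, hence `Ob = -1`, regardless of the surface measure).  Note the
sign convention: here positive oblateness means plate-like; a study that
reports negative values as "more plate-like" is using the opposite sign.

## Spatial graph

1. **Distance map** — Euclidean distance (um) of each foreground voxel to the
   nearest background voxel, with the stack border counting as background.
   Twice the distance map is the local filament diameter.
2. **Centerline** — the mask is nearest-neighbour resampled onto a thinning
   grid at the finest axis spacing, except that the z step is
   `thinning_z_compression` (default 4) times coarser.  Thinning treats the
   grid as isotropic; sampling z at the axial/lateral PSF ratio makes the
   axially smeared tube cross-section round in grid units, which keeps the
   medial axis a single clean curve instead of a zig-zag through a tall
   ribbon.  Thinning is Lee's 3D topology-preserving algorithm
   (scikit-image); terminal spurs shorter than `prune_length_um` (0.3) that
   end on a junction are removed.
3. **Graph tracing** — skeleton voxels of degree >= 3 are junction voxels;
   26-connected clusters of them merge into one node at their
   thickness-weighted centroid (node thickness = cluster maximum of twice the
   distance map).  Degree-1 voxels are open nodes; maximal degree-2 chains
   between nodes are segments; junction-free cycles become one segment closed
   on a virtual node flagged `cycle` (excluded from node censuses and angle
   statistics).  Terminal branches whose physical length (path plus one tip
   radius) is below `min_terminal_um` (0.55) are dropped: they are skeleton
   artefacts of the thick merged-tube zone around junctions.  Nodes left with
   two incident segments are dissolved and their segments merged.
4. **Polyline geometry** — segment polylines are refined onto the local
   intensity ridge (in-plane squared-intensity centroid over +/-3 pixels;
   axial plain-intensity centroid over +/-2 slices of the denoised,
   baseline-subtracted stack — the binary medial axis wanders with the noisy
   mask boundary, the blurred intensity ridge does not), smoothed with a
   0.25 um moving window, and resampled at `resampling_step_um` (50 nm, the
   point-to-point scale of the published graphs).  Open segment ends are
   extended along the end tangent by half the local radius: thinning retreats
   about one radius from the mask tip while the thresholded mask overshoots
   the physical tip by a comparable amount.
5. **Change points** — resampled points are flagged where the local direction
   changes by more than `orientation_threshold_deg` (20 deg) or the relative
   thickness changes by more than `thickness_change_fraction` (0.20); all
   resampled points are kept (the published point-to-point spacing, ~60 nm,
   is only consistent with keeping them), and segment inhomogeneity `I_s`
   counts the flagged interior points.  No reference formula exists for
   `I_s`, so its absolute scale is this package's own.

## Element descriptors

Per node: thickness, nearest-neighbour distance `d_nn`, distance to the
nearest hull-surface voxel `d_ns`, distance to the network centre of gravity
(mean foreground voxel position) `d_nc`, and the ratio `d_ns / d_nc` (nodes
exactly at the centre of gravity are excluded with a flag).  Network level:
node count `N_n`, node density `rho_n = N_n / V_EN`, and compactness
`C_PN = (mean d_nc - mean d_ns) / mean d_nc` — a ratio of means, which is
what reproduces the published value from the published mean distances
(2.07 um and 0.57 um give 0.72).  `C_PN <= 1` always, and it can be negative
when nodes sit nearer the centre than the surface.

Per segment: arc length `L_s`; Menger curvature `kappa_s`
(`4 * area / (abc)` for a point triplet, the reciprocal circumradius),
averaged over triplets taken at a physical stride (`curvature_stride_um`,
0.4) rather than at neighbouring 50-nm points, whose local circumradius is
dominated by sub-voxel error; mean thickness `th_s`; inhomogeneity `I_s`;
mean point spacing `d_pp`.

Per connection: mean connections per junction `n_c`; open-node percentage
`n_oe` (open nodes / all census nodes x 100); inter-segment angles at 3- and
4-way junctions between tangent chords to the first polyline point >= 100 nm
from the node (damping voxel jitter), averaged per node and then over the
network (`theta_c3`, `theta_c4`).

## Statistics

All 25 descriptors are compared by the classic equal-variance unpaired
Student's t-test (two-sided, `df = n_a + n_b - 2`); Welch's variant is
available behind a flag.  Significance is `p < alpha` (default 0.05) with no
multiple-testing correction — replicating the source methodology — and every
report carries an advisory note saying so.  p-values are printed to three
significant digits, never truncated to zero.  Element-level distributions
are summarised as mean +/- SD over networks of each network's normalised (or
cumulative) histogram on fixed bins; thickness bins are 40 nm wide over
0-600 nm so that 480-520 nm (the meganode range) is exactly one bin.

## Synthetic phantoms

Ground-truth networks emulate a transfected chloroplast's plastoskeleton:
junctions (degree 3:4 drawn 0.85:0.15, matching a mean of ~3.1 connections
per node) are placed on an oblate ellipsoid shell — in vivo the networks hug
the organelle envelope and nodes concentrate near the surface — with a
minimum spacing (default 0.7 um, about five filament diameters); a spanning
tree plus nearest-pair extra edges realises the drawn degrees exactly, and
the requested number of open filaments leaves the shell outward (lengths
0.7-0.9 x the shell margin).  Segments are circular arcs (chord + bow
height, default bow 7% of the chord), so their Menger curvature `1/R` and
arc length are exact oracles; filament radii are Gaussian (60 +/- 8 nm,
i.e. 100-140 nm thickness); an optional fraction of junctions become
meganodes, spheres of 480-520 nm diameter.  Degree/endpoint bookkeeping is
exact: the number of extra (cycle) edges is
`(sum(d) - 2(J-1) - E) / 2`, adjusted by single 3<->4 flips for parity, and
an infeasible request raises rather than silently truncating.

Rendering mirrors the microscope: the structure is rasterized on a
z-supersampled grid (~15 nm axial step — the filament diameter is below the
native 240 nm slice spacing), convolved with an anisotropic Gaussian PSF
(default sigmas 300/70/70 nm), and only then sampled at the native slice
centres.  Ordering matters: box-averaging into disjoint slabs before
blurring destroys the sub-slice position of thin filaments and reads out as
fake curvature downstream.  Exposure is set so the median centerline
intensity equals the nominal amplitude (junctions and meganodes may exceed
it); a detector baseline of `baseline_fraction x amplitude` (default 2) is
added — the purely relative local threshold needs a baseline to be
meaningful — followed by Gaussian noise of SD `amplitude / snr` (default
SNR 10) and optional Poisson resampling.  The noiseless render consumes no
random numbers, so it is seed-independent.

What the phantoms do **not** emulate: real PSF side lobes and depth
dependence, deconvolution artefacts, chlorophyll autofluorescence bleed,
intensity variation along filaments, and chloroplast-to-chloroplast shape
diversity.  Passing recovery tests therefore demonstrates the correctness of
the computational chain under controlled optics, not performance on any
particular instrument's data.

## Problem sizes and accuracy at realistic degradation

Default phantom grids are ~4 x 6 x 6 um at 0.24/0.042/0.042 um spacing
(2x-binned laterally relative to the motivating acquisitions, still near
Nyquist for the ~140 nm lateral resolution), with ~30 junctions per network —
compact enough that a full phantom-to-descriptors run takes seconds, and the
bundled recovery studies use 6-10 phantoms per condition and 100-200 null
replicates.

Under the realistic degradation (70/300 nm PSF, SNR 10), node count and mean
segment length are recovered within ~10%.  Two quantities are
resolution-limited and must be interpreted as *measured* rather than *true*
values, exactly as one should for the corresponding published numbers:

- **Thickness** is read from the distance map of the thresholded mask, which
  the PSF fattens; sub-resolution filaments read ~2x too thick, and a 40 nm
  thickness bin (the meganode signature) is not resolvable through the
  imaging chain.  Meganode discrimination is therefore validated on the
  analytic descriptor route, and thickness comparisons between groups
  processed identically remain valid.
- **Curvature** is inflated by smooth 30-60 nm centerline deviations (axial
  PSF crosstalk between nearby filaments; junction-zone migration of the
  medial axis).  Because |curvature| is a rectifying statistic these
  deviations cannot average out, and the measured network mean sits ~2-3x
  above the true arc curvature of ~0.5 um^-1.  Stronger smoothing, robust
  triplet statistics and signed circle fits were all evaluated and do not
  remove the floor; only deconvolution would.

## Degenerate inputs and tie-breaks

Empty masks, all-removed components, overlapping manual edits, single-node
graphs (`d_nn` reported missing, never 0), junction-free cycles, networks
without 4-way junctions (`theta_c4` missing), zero pooled variance in the
t-test (p = 1 for equal means, p = 0 flagged degenerate otherwise) and
(near-)coplanar hulls (descriptors from the bounding box, `St`/`Ob` as 0)
are all handled explicitly; missing values propagate as NaN and are dropped
per-descriptor in group comparisons, never silently zeroed.
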