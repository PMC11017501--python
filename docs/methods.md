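# Methods

## Coordinate and intensity conventions

All arrays are ordered (z, y, x); all sizes, coordinates and voxel sizes
are given in the same order, in µm. Voxel centers sit at
`(index + 0.5) × voxel_size`. The default grid is 256 × 256 × 64 voxels at
0.58 × 0.58 × 1 µm — the acquisition geometry (1024 × 1024 pixels at
0.58 µm/pixel, 1 µm z-steps) scaled down 4× in xy so desk-scale runs stay
fast; the full field of view is available by configuration. Intensities
are arbitrary units ≥ 0 and are stored as float32 in rendered stacks.

## The phantom forward model

**Geometry.** `generate_tree` places tubular vessels of the five AV
classes. Arteries and veins are roots spanning the volume roughly
horizontally (pial trunks); arterioles branch off artery walls and head
outward, venules likewise off veins, and capillaries run from an arteriole
wall to the nearest of a few candidate venule wall points (falling back to
free-ended branches when no collision-free connector exists). Branches
start on the *wall* of their trunk, not its centerline, so a venule is
never engulfed by its parent vein. Tubes are straight lines with a pinned
low-amplitude sinusoidal perturbation (tortuosity). Candidates colliding
with already-placed vessels are rejected; non-connected vessels keep an
8 µm wall-to-wall neuropil clearance, with an exclusion zone of
`sqrt(2 R dr)`-scale arclength around junctions where overlap with the
trunk's clearance band is legitimate. Repeated failure raises
`PlacementError`.

**Diameters.** Per-class normal distributions (A 74.1 ± 14.5 µm,
Ae 26.8 ± 8.0, C 6.1 ± 1.2, Ve 21.3 ± 8.9, V 76.7 ± 25.0), truncated to the
classification bands inside `generate_tree` so labels stay consistent with
the rules. The recovery *cohorts* (below) instead truncate only at a
physical minimum of 1.5 µm: band truncation would shift e.g. the venule
cohort mean by +1.7 µm and defeat the mean-recovery comparison, and a
single-tube cohort needs no class-consistent label.

**Rendering.** Each voxel's distance to the nearest centerline sample and
that sample's radius come from one Euclidean distance transform per scene
(anisotropy-aware). Lumen occupancy is partial-volume: 1 inside, 0
outside, a linear ramp one xy-voxel wide across the wall with half
occupancy exactly at the wall — so the full width at half maximum of a
tube profile equals the true diameter by construction. Perfused lumina
carry `tracer_intensity`; occluded ones are dark in the tracer channel but
full in the optional endothelial-reporter channel.

**Leak halos.** A planted leak on vessel `v` at arclength fraction `u`
with planned spreading distance `D` adds, over a stretch of
`site_length_um` (default 20 µm), the intensity
`amp · exp(−d_wall² / (2 s²))` outside the wall, with `s = D/2` and
`amp = 0.5 × tracer_intensity`. The calibration constant is
`exp(−2) ≈ 0.135`: a detector thresholding at `amp·e⁻²`
(`halo_detection_threshold`) finds the most distant continuous signal at
exactly the planned distance. Spreading-distance draws use the per-class
distributions A 14.1 ± 5.4 µm, V 13.9 ± 5.8, C 6.0 ± 3.0 (truncated > 0);
arteriole/venule spreading is not reported for the acute phase, so their
generator default is an interpolated 10.0 ± 4.0 µm.

**PSF and noise.** The Gaussian PSF default is derived from the stated
optics (two-photon excitation at ~920 nm, NA 1.0 water immersion): lateral
FWHM ≈ 0.35 µm and axial FWHM ≈ 1.2 µm, i.e. sigmas (z, y, x) =
(0.5, 0.15, 0.15) µm. A wider ad-hoc PSF systematically erodes the
half-maximum edge of ~6 µm capillaries (≈ −0.35 µm at σ_lat = 0.5 µm);
with the physical PSF the residual bias is ≈ −0.03 µm. Noise is Poisson
shot noise (default 0.1 photons per intensity unit) plus Gaussian read
noise (default 5% of tracer intensity); phantoms used for calibration
checks render noise-free. Rendering is bit-deterministic given the spec
seed and timepoint tag.

**Timepoints.** `apply_timepoint` advances a scene: exactly
`round(fraction × n)` leak sites grow (spreading × U(1.2, 1.8)), the rest
shrink (× U(0.5, 0.85)); per-class constriction factors (post/pre diameter
fractions 0.735 Ae, 0.782 A, 0.794 V, 0.869 Ve, 0.887 C — the published
mean percent decreases) are drawn with sd 0.03 and applied to all radii.
The sd is the package's choice (no spread is published); 0.03 reflects a
fairly uniform within-class constriction response and was fixed from a
pre-run power analysis of the smallest cohort (arteries, n = 7, tolerance
±3 percentage points ⇒ 2·se ≈ 2.3 at sd 0.03). Tracer concentration is
held constant across timepoints (its decay over a 2 h session is not
characterised).

## Tracing and filling

`trace` joins consecutive seeds by minimum-cost paths on the 26-connected
voxel graph. A move from voxel *u* to *v* costs the physical step length
(µm) times the trapezoidal mean of the vertex costs
`1 + κ / max(I/I_max, floor)` (κ = 10, floor = 10⁻³): bright voxels cost
≈ 1 + κ per µm, dark ones up to three orders of magnitude more, so the
path follows the lumen and — inside a flat bright core — the shortest
(central) chord. The search uses geometric minimum-cost-path machinery
(`skimage.graph.MCP_Geometric`); tests certify it against an independent
hand-rolled Dijkstra on random small stacks. Paths are resampled to ≤ 2 µm
spacing (default 1 µm) and per-point radii are initialised as half the
FWHM of the perpendicular in-plane profile. A seed in a zero-intensity
region warns but traces (occluded vessels are traced on the reporter
channel in practice).

`fill_lumen` accepts voxels with (pre-smoothed) intensity ≥
`threshold_fraction` (default 0.3) × the median intensity along the path,
connected to a path voxel through accepted 26-neighbours, with geodesic
reach from the path bounded at 3 × the radius of the nearest path point.
The threshold default recovers noise-free cylinders within 10% volume
error; the reach bound stops bleed-through where extraluminal signal is
high after occlusion. Supervised correction enters as force-include /
force-exclude voxel lists (forced voxels still obey connectivity). Filling
operates on smoothed intensities (the alternative — raw — is a config
choice). At branch overlaps a voxel belongs to the vessel with the nearest
centerline in µm; exact ties go to the lower vessel id.

## Leakage accounting

`split_signal` is an exact partition (luminal + extraluminal = input,
voxel-wise). `leakage_ratio` background-subtracts (clipping negatives),
then sums intensities per compartment — sums, i.e. volume-weighted, with a
config switch to means, since the normalisation statistic is not further
specified — and reports extraluminal/luminal overall and per compartment.
A one-voxel dilation ring around the lumen is excluded from the
extraluminal sum by default to suppress PSF bleed at the wall (this is why
a pre-occlusion timepoint is not exactly zero on noisy data). A zero
luminal sum flags the result undefined instead of raising. Compartments
come from per-plane closed ROI polygons (point-in-polygon rasterisation);
lumen voxels override ROI labels. The phantom's curved brain surface is a
spherical cap: depth 0 at the field center, `curvature_depth_um` at the
corners; voxels above it are subarachnoid.

Perfused density is centerline length per volume (µm/µm³). Length per
volume (not per projected area) was chosen as the 3D-native reading; a
path counts as perfused when its median luminal intensity exceeds the
background by a configured factor (strictly positive when the background
is zero).

## AV-axis operations

**Classification** applies the printed bands exactly (strict "> 45",
"< 10"; 10–45 and 10–50 inclusive). Overlaps (exactly 10 µm; 45–50 µm) and
boundary values return the candidate set unless morphology
(elongated → {A, Ae}, irregular → {V, Ve}, single-cell → {C}) or topology
(branches_off_artery → Ae, converges_to_vein → Ve) resolves them. Flags
are inputs (from truth or the analyst); extracting them from the reporter
channel is out of scope.

**Diameter** is the FWHM of the intensity profile along the in-plane
perpendicular to the local tangent, averaged over 3 adjacent stations 1 µm
apart. The station center is first refined along z to the local intensity
maximum (parabolic, sub-voxel, clipped to ±1 µm) so the coarse axial
sampling does not cut the tube off-equator. Profiles are sampled at ¼ xy
voxel with trilinear interpolation; half-max crossings are linearly
interpolated; a profile that never falls to half maximum (vessel exits the
field) returns NaN.

**Attribution** compares the site's intensity-weighted centroid against
every vessel's wall (centerline distance − local radius, clamped ≥ 0);
nearest wins, and the runner-up is included when the two wall distances
differ by ≤ 0.58 µm (one xy pixel — the "equally close" tolerance, which
is not otherwise quantified). Sites farther than 50 µm from every wall
stay unattributed and are logged.

**Spreading distance**: above-threshold extraluminal voxels count only
when 26-connected to the wall (within 1.5 µm ≈ one voxel diagonal), so a
detached bright blob never extends the measurement. The site's length axis
is the projection onto the attributed vessel's centerline; stations every
1 µm (1–2 µm supported) take the maximal wall distance of continuous
signal and are averaged. Distances are 3D µm by default with a 2D
(in-plane) mode available. The default detection threshold in the pipeline
is background + 3 × background sd estimated from a corner block; the
recovery experiments use the generator's matched threshold `amp·e⁻²`.

**Progression** classifies matched sites by the strict sign of the
spreading change (ties reported separately) and reports the fraction
increased plus a paired t-test p-value as supporting output.

## Recovery experiments and problem sizes

`avleak.validation` treats published per-class statistics as generating
parameters and measures how well the pipeline recovers them. Cohort sizes
follow the published group sizes: diameters 29/28/236/190/29 (A/Ae/C/Ve/V),
constriction 7/14/113/128/16, 200 attribution sites (class shares
48% Ve, 25% C, 12.5% Ae, 8% V, 6.5% A), 50 halos per spreading class, 100
two-timepoint progression sites with exactly 67 growing. Single-tube
scenes are sized per draw (tube plus 10–12 µm profile margin plus
1.4 × spreading halo margin) and carry sub-voxel center dither and a ≤ 3°
in-plane tilt so grid alignment cannot flatter the measurement. The
attribution scene is a 591 × 591 × 300 µm tree (the acquisition field at
up to 300 µm depth) analysed geometrically; its site points stand in for
halo centroids, with wall offsets drawn from the halo's radial mass
profile, capped at 10 µm, placed outside every other vessel's lumen and
away from junction zones where "nearest vessel" is ill-defined.

## What the phantoms do and do not show

Passing recovery at these tolerances shows the *operations* are faithful:
unbiased FWHM at 0.58 µm pixels, calibrated spreading measurement,
consistent attribution and exact bookkeeping. The phantoms do not emulate
red-blood-cell shadows, photobleaching, motion, depth-dependent scattering
or pulsation; real-data performance additionally depends on those
nuisances and on analyst seed/ROI quality. Hemodynamics are not simulated;
occlusion is a binary perfusion flag.

## Numerical choices and degenerate inputs

Distances are physical µm everywhere (anisotropy-aware); connectivity is
26-neighbour throughout. Gaussian smoothing interprets sigma in xy pixels
and scales the z sigma by the anisotropy. Stacks are float32; ratio
invariance under global intensity scaling holds to single precision.
Degenerate inputs fail loudly: identical consecutive seeds, seeds outside
the volume, empty paths, non-closed ROI polygons, zero hemisphere area,
constriction factors outside (0, 1], diameter means outside their class
band. Zero luminal signal and unmeasurable diameters are flagged (NaN /
`undefined`), not raised, because they occur in legitimate analyses.
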