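# Methods

`plaquestruct` reconstructs the structural-assessment chain used in
image-based carotid plaque studies — multi-contrast segmentation, plaque
morphometry, material mapping, and hemodynamic / wall-stress descriptors —
and drives it with a synthetic carotid-bifurcation phantom so that every
stage is testable against known ground truth. This note records the models,
the defaults and why they are what they are, the numerical choices, and
what the synthetic validation does and does not establish.

## The phantom

The phantom is a Y-shaped vessel: a common carotid artery (CCA) along +z
that splits at an apex into an internal (ICA) and external (ECA) branch
tilted ±20° in the x–z plane. Cross-sections are circles swept along
straight axes. Defaults follow typical adult carotid calibre: CCA lumen
radius 3.1 mm, distal ICA 2.5 mm, ECA 2.0 mm, wall thickness 1 mm.

The ICA carries a cosine-tapered stenosis centred 7 mm downstream of the
apex (half-width 6 mm): lumen radius `r(s) = r_ICA (1 − f·b(s))` with bump
`b` peaking at 1, so the throat radius is exactly `r_ICA (1 − f)` for
stenosis fraction `f`. The wall thickens to 3 mm over the same bump (the
plaque), and the lumen centre is offset away from the plaque side by
0.4 × the local radius loss (eccentric stenosis). Study conditions use
`f ∈ {0.81, 0.83, 0.82}`, the stenosis spread of the three-patient
reference cohort this package emulates.

Two ellipsoidal inclusions sit in the thickened wall: a lipid core under
the throat whose inner pole lies a configurable fibrous-cap distance
(default 0.73 mm) outside the lumen surface, with a short axial semi-axis
so the throat station remains the closest approach and the configured cap
is the true minimum; and a smaller calcification 3.5 mm proximal at a
different azimuth. Analytic ellipsoid volumes (4/3·π·abc) are the ground
truth for volume recovery.

Rasterisation is nearest-axis-sample lookup on an axis-aligned grid
(0.25 mm isotropic default, configurable 0.25–0.5 mm; the source imaging
protocol does not state a resolution). Inclusions must lie strictly inside
the wall band; an escaping inclusion is an error, not a warning.

Contrast rendering assigns each tissue a per-channel normalized mean
(T1W/T2W/PDW/TOF) following standard multi-contrast plaque-MRI behaviour:
lumen brightest on TOF (flow-related enhancement), lipid hyperintense on
T1W/PDW and hypointense on T2W, calcification hypointense everywhere.
Noise is additive Gaussian, default SD 0.05 per channel (Rician noise is a
non-goal). At zero noise the rendering is exactly invertible by
nearest-signature classification, which the tests assert.

The phantom's TOF lumen is additionally shaded with a cone profile
`1 − 0.4·(d/r)` (brightest on the axis), emulating the velocity-weighted
enhancement of laminar flow. This is physical, and it is also load-bearing:
a least-cost path through a *flat* bright lumen has no reason to run along
the axis, so centerline extraction would degenerate to chord-cutting.
`render_contrasts` keeps piecewise-constant output unless the radial
coordinate map is passed explicitly.

Waveforms: one cardiac cycle (period 1 s) sampled at 40 equidistant frames
(41 samples closing the period, matching ~40-frame gated PC-MRI). The
shape is a two-Gaussian template (systolic peak at 0.16 T, dicrotic bump
at 0.45 T) mapped affinely so the discrete trapezoidal mean and the
sampled maximum match the requested mean/peak flow exactly (defaults
6 and 18 mL/s, ordinary CCA values). The pressure waveform is the flow
waveform rescaled affinely onto [diastolic, systolic] (default
80–120 mmHg), the standard scaling when only cuff pressures are measured.

## Centerlines

Cost volume: `1/(ε + I_norm)` on the min–max-normalised TOF channel,
ε = 0.05 (bounded by 1/ε). The pipeline smooths the channel by one voxel
first; otherwise per-voxel noise on the cost is comparable to the medial
intensity gradient and paths wander.

Paths are exact shortest paths on the 26-connected voxel graph, edge
weight = mean endpoint cost × metric step length, ties broken
lexicographically on linear voxel index (bit-reproducible). A single
target uses an admissible A* heuristic (global minimum cost × Euclidean
distance), which cannot change the optimum. The two bifurcation paths are
reconstructed from one single-source tree rooted at the CCA seed — their
common prefix is then exactly the shared trunk, and the apex is the last
common point walking from the CCA seed. The apex definition is a choice;
the recovered apex is discretisation-limited to about the voxel scale
because near the apex the two daughter axes differ by less than half a
voxel over several slices at a 20° branch angle.

## Segmentation

Slices are planes orthogonal to the image z-axis. Both the lumen snake and
the outer-wall trace run on 2×-spline-upsampled slices: the stenotic
throat spans ~2 voxels at 0.25 mm and sub-pixel localisation improves
markedly on the interpolated grid.

**Lumen.** A closed snake (64 vertices) initialised as a 1.2 mm circle on
the centerline point. Internal energy (tension α = 0.05, rigidity
β = 0.10) is handled with the classical semi-implicit pentadiagonal solve;
external forces are (a) ascent on the gradient-magnitude ridge and (b) a
signed region pressure — inflate where the normalised slice intensity
exceeds 0.40, deflate where below. The pressure term is what makes one
initial radius work everywhere: 1.2 mm is inside a normal lumen (inflate
to the edge) and outside the throat lumen (deflate onto it). On a flat
image only the internal terms act and the contour performs
curve-shortening, which a test verifies. Iteration stops when the largest
vertex move drops under 0.01 mm; collapse below one voxel of area is an
error suggesting a larger initial radius. A final pass snaps each vertex
to the parabolic sub-pixel peak of the gradient magnitude along its radial
ray (sharper smoothing, σ = 0.8 upsampled px), then 3-median-filters the
vertex radii — minimum-distance morphology statistics are maximally
sensitive to single-vertex noise spikes.

**Outer wall.** A polar map around the lumen centroid: 72 rays, 32 radial
samples from the lumen boundary to 4 mm outward. Node cost is the negative
outward falling-edge strength (polarity configurable); transitions pay
λ·|Δr| (λ = 0.35 per mm) and may jump at most 2 radial samples per ray.
The minimum-cost *cyclic* path is solved exactly by dynamic programming
with closure enforced by solving once per admissible first-ray radius —
exhaustive enumeration and an independent layered-graph shortest path
confirm exactness in the tests. As λ → ∞ the solution degenerates to the
best single circle (the "circle model" limit). By construction radii start
at the lumen boundary, so the outer contour encloses the lumen.

Both lumens above the apex are segmented, each assigned to its nearest
centerline; centerline points closer than 1 mm (the common trunk) are
segmented once.

## Tissue clustering

Features are the four channel intensities of wall-band voxels, z-scored
per channel over the band. k-means is Lloyd's algorithm with k-means++
seeding, best of 10 restarts, fixed seed 17; empty clusters re-seed at the
farthest point; inertia is asserted non-increasing at every iteration
(scikit-learn's KMeans is the cross-check oracle in tests, never the
implementation — the contract here specifies internals sklearn does not
expose). Centroids map to tissues by nearest z-scored signature among
{arterial wall, lipid, calcification}; surplus clusters land on the wall
signature; a tissue claimed by no centroid is reported, not an error.

The full pipeline clusters with k = 6 over a *conservative* band (lumen
contours dilated and outer contours eroded by 0.15 mm): segmentation is
accurate to ~half a voxel, so the raw band contains partial-volume voxels
at both edges whose mixed intensities otherwise absorb clusters. The
module default stays k = 4 for a clean (ground-truth) band.

## Morphology

Component volume = voxel count × voxel volume. Thinnest fibrous cap = 3D
minimum Euclidean distance from the lumen surface to the lipid surface via
a distance transform (voxel centres; exhaustive all-pairs oracle in
tests). 3D is the stricter bound compared with per-slice 2D minima. A cap
not exceeding one voxel spacing is flagged as a breach; absent lipid is an
absent result, not an error.

NASCET stenosis = `100·(1 − d_min/d_distal)` with the distal reference
averaged over the final 5 mm of the ICA profile (the original reference
length is unstated; 5 mm of the unstenosed distal segment is used). The
measured radius profile uses the **area-equivalent radius** `√(A/π)` of
each sub-pixel lumen contour rather than the maximal inscribed circle:
zero-mean contour ripple cancels to first order in the area (an inscribed
circle is a min-statistic, biased low by ~5% even on noise-free synthetic
disks), and the obliquity inflation of z-orthogonal cuts through a tilted
branch is a constant factor that cancels exactly in the diameter ratio.
The inscribed-circle convention remains available as an option. Profiles
are smoothed with a quadratic Savitzky–Golay filter (window 9), which
averages per-slice noise without inflating the parabolic throat minimum
the way a moving average does. Finally the scale-space edge-displacement
correction `R = (r + √(r² + 4σ_b²))/2` undoes the inward bias of
gradient-peak localisation at blur-limited radii; σ_b combines the
refinement smoothing with the half-voxel acquisition width (≈0.16 mm at
0.25 mm voxels) and is a property of the measurement chain, not a fitted
constant. It moves a 2.5 mm radius by 0.01 mm and the 0.47 mm throat by
~0.05 mm.

## Material mapping

Per-element properties on a tetrahedral wall mesh: arterial tissue
0.6 MPa, calcification 10 MPa, lipid 0.02 MPa, Poisson ratio 0.48
throughout; lookup is by the tissue label at the element centroid
(deterministic and idempotent, unlike nodal averaging). Elements whose
centroid falls in lumen/background at the rasterised boundary get arterial
properties, counted in the log. The transitional region between components
is inverse-distance-weighted averaging of **log**-modulus within a radius
(default 0.6 mm ≈ 2 voxels; the original interpolation method and width
are unstated): log-space keeps the 500× calcification/lipid stiffness
ratio from dominating, and a convex combination in log-space is bounded by
the extreme modul and monotone across a flat interface. ν is untouched.
Constants are stored, not solved — no finite-element analysis here.

Phantom wall meshing: Delaunay over a jittered cubic lattice restricted to
the wall band, tetrahedra kept if their centroid stays in the band,
orientation fixed positive. Lattice pitch = target edge / 1.22 (the median
Delaunay edge over a jittered lattice mixes axis and diagonal edges),
which lands the median edge within a few percent of the 0.3 mm target
convention.

## Hemodynamic descriptors

The coupled-CFD participant is replaced by a transparent quasi-steady
surrogate, flagged `surrogate` in every output: Poiseuille wall shear
`τ(s,t) = 4μQ(t)/(π r(s)³)` along the local tangent, μ = 0.00345 Pa·s,
branch flow split ∝ distal radius⁴ (parallel resistance). Externally
computed WSS time series can be substituted; the descriptor operations do
not care where the field came from.

TAWSS is the trapezoidal cycle mean of |τ|; OSI is the standard vector
form ½(1 − ‖∫τ dt‖/∫‖τ‖ dt) ∈ [0, ½] (the typeset source formula loses
the magnitude bars; the vector form is universal), masked — not zeroed —
where total shear exposure vanishes. Peak-systole WSS is |τ| at the
instant of maximum inlet flow, earliest sample on ties. ROI statistics are
unweighted point statistics (area weighting available) over an arc-length
window anchored at the bifurcation apex; the default TAWSS ROI is the
apex-anchored 17 mm of the ICA. Under the unidirectional quasi-steady
surrogate OSI is identically 0; OSI's analytic limits (0 unidirectional,
0.5 zero-mean oscillation) are validated on synthetic vector fields.
Trapezoidal quadrature of a 40-frame rectified sine is within 0.25% of
the closed form 2A/π.

The surrogate's throat WSS at an 81% stenosis reaches ~10² Pa — the r⁻³
law at a 0.47 mm throat — so ROI means are far above patient-level CFD
values by design; only the descriptor *machinery* is validated, never
patient magnitudes.

## Wall stress

Thin-wall Laplace hoop stress σ(s,t) = p(t)·r(s)/h(s) (mmHg → Pa
internally, reported in kPa) stands in for the maximum-principal-stress
field of a structural solve, again flagged as a surrogate that does not
reproduce patient kPa values. The stress ROI selects the cross-section
with maximal peak-systole stress (ties → smallest arc-length), centres a
13 mm window on it, truncating with a warning at vessel ends, and reports
mean ± SD and maximum.

Cross-case comparison arithmetic: volumes and mean TAWSS compare as fold
ratios (larger/smaller), maximum stress as a percent difference relative
to the smaller value. Printed-precision renderings use truncation (the
published volume folds 22.4/7.4 and stress differences 13.8%/8.9% are
truncations of 22.49/7.42/13.86/8.98; the published TAWSS fold 2.7 is a
rounding of 2.68) — full-precision values are always reported alongside.

## Pipeline, determinism, problem sizes

`report.run_pipeline` chains the stages, caches intermediates under a
content hash of the configuration, and emits a units-annotated JSON report
with seed, config hash and surrogate flags; identical configuration and
seed reproduce the report byte for byte. All randomness flows from
explicit seeds (phantom noise, k-means, mesh jitter).

Validation problem sizes: phantoms at 0.25 mm (≈ 0.8 M voxels,
~100 × 50 × 160), three cases at stenoses 81/83/82%, full pipeline
~2 minutes per case on one core; exhaustive optimizer oracles at 6×6×3
(Dijkstra) and 6 rays × 4 radii / 12 × 8 (cyclic DP); wall meshes at
0.3–0.5 mm target edge.

## What the synthetic validation shows — and does not

Passing tests establish that the algorithms are implemented correctly
(exact optimizers verified against enumeration), that the measurement
chain recovers the generator's parameters under the stated imaging model
(NASCET within ±2 points, component volumes within ~2%, cap within one
voxel diagonal at 0.25 mm), and that the comparison arithmetic reproduces
the published three-patient figures from their printed inputs. They do
not establish performance on clinical MRI: the phantom has circular
cross-sections, piecewise-constant signatures with Gaussian noise, no
bias fields, motion, flow artefacts or intra-plaque haemorrhage, and its
contrast separations are favourable. The hemodynamic and stress values are
surrogates with the scaling behaviour, not the magnitudes, of the coupled
simulations they replace. Known limitations additionally include: snake
threshold sensitivity at sub-millimetre throats (region threshold 0.40 is
calibrated to the phantom's contrast conventions), laminar/Newtonian
assumptions inherited by the surrogate, and linear-elastic material
constants taken from the literature.
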