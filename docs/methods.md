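# Methods

This note documents the models, conventions and numerical choices behind
`rvk`, in the order the pipeline runs. Where the underlying experimental
practice leaves a definition open, the choice made here is stated explicitly
as a package convention, with the alternative noted.

## Recordings and units

A recording is a synchronized set of channels at a fixed sampling rate
(default 128 Hz): per-crystal 3-D trajectories (mm), LV/RV/central-venous
pressures (mmHg), and ECG (arbitrary units). Bundles are stored as a JSON
header plus a CSV channel table — human-readable, diffable, and free of
binary dependencies; vendor acquisition formats are out of scope. Headers may
declare cm/m, kPa, or ms, converted on read. Floats are written with 12
significant digits, so a write/read round trip is identity to ~1e-12
relative.

The crystal layout fixes roles and circumferential order: 6 annular labels,
three free-wall parallels totalling 13 (default split 5/4/4 — the total is
anatomically fixed, the split is a configurable convention), and 1 apex
label.

## Cycle landmarks

* **ED** = R-wave peak. Detector: moving-median detrend (600 ms window),
  threshold at 60 % of the 98th-percentile detrended amplitude, 200 ms
  refractory period, parabolic sub-sample refinement rounded to the nearest
  sample. All constants are keyword-configurable; the defaults are tuned for
  clean epicardial ECG with distinct R spikes, not for arrhythmia screening.
* **ES** = argmin of LV dP/dt strictly inside (ED, next ED). dP/dt is the
  central difference of the moving-average-smoothed pressure (default window
  5 samples ≈ 39 ms at 128 Hz; interior error on band-limited signals is
  O(h²)). A beat whose ES candidate sits at the interval boundary is flagged
  unusable rather than silently kept.
* **EIVC / EIVR** are *package conventions* (the phase names are standard but
  operational definitions are not): EIVC = argmax of LV dP/dt within the
  beat; EIVR = first sample after ES where LV pressure falls below its ED
  value.

## Beat averaging

Each of the first 4 usable consecutive beats (count configurable; 4 is the
standard acquisition practice this package mirrors) is linearly resampled
from its ED to the next ED onto a 101-point 0–100 % grid; channels are
averaged pointwise and landmark phases averaged in normalized time. Time
normalization is plain linear ED→ED — no piecewise landmark warping — as the
simplest defensible reading of "averaged over beats". The alternative
(averaging derived scalars per beat rather than channels on the grid) would
commute with all linear steps and differ only through the nonlinear geometry
operators; it is not implemented.

Averaging n beats attenuates iid coordinate noise by 1/√n at grid points
aligned with samples. Off-sample grid points are linear interpolations with
weights (1−w, w), which multiplies the noise SD by √((1−w)² + w²) — on
average √(2/3) ≈ 0.82 for uniform w. Validation of the √n law therefore uses
sample-aligned grids; on real (unaligned) grids the measured residual noise
is correspondingly smaller.

## Geometry

* **Annular area**: the 6 annular crystals are projected orthogonally onto
  their total-least-squares plane (SVD) and the shoelace area of the
  projected polygon is taken. The annulus is non-planar, so this is a
  definition, not an approximation of a unique truth; a 3-D centroid-fan
  triangulated area is available (`method="fan"`) for sensitivity analysis
  and agrees within ~2 % on the phantom.
* **Percent annular reduction** = 100·(1 − A_TRA/A_Baseline). Cohort reports
  summarize the *per-animal* reductions (mean ± SD), which differs from the
  ratio of cohort means; both are recoverable from the report.
* **RV volume**: convex hull (Qhull) of all 20 crystals, in ml. This is a
  shape index of the epicardial point cloud, not a chamber volume. For points
  sampled on a half-ellipsoid the hull is bounded above by (2/3)πabc; with
  only 20 surface points the inscribed hull necessarily loses a substantial
  fraction (≈30 % even at full circumferential coverage — compare the
  dodecahedron, the best 20-vertex inscription of a ball, at 66 %), and with
  the default 180° free-wall span it captures ≈43 % of the bound.
* **Cross-sectional area** of a parallel: chord-closed polygon of the row's
  crystals (they cover only the free wall, not the septum) on its best-fit
  plane. The chord closure is a convention; 5 points on a semicircle give
  exactly the inscribed polygon area, a 10 % deficit versus πr²/2.
* **Radius of curvature**: Kåsa algebraic circle fit in the row's best-fit
  plane, refined by one geometric Gauss–Newton pass. Exact on noise-free
  circular data for any n ≥ 3 (n = 3 gives the circumcircle). A 2-D in-plane
  fit was chosen over a 3-D sphere fit because per-parallel "radius of
  curvature" naturally means in-plane curvature of that hoop.

All geometry outputs are rigid-motion invariant to ≤1e-9 relative and scale
as s² (areas), s³ (volumes), s (radii) under isotropic scaling; these are
regression-tested.

## Strain mesh

**Triangulation.** Rows (annulus → basal → mid → lower) are stitched as
triangle strips by a greedy shorter-diagonal rule; an apex fan closes the
bottom. Vertex order equals layout order, so meshes built for different
states or times share connectivity by construction. Diagonal comparisons use
a 1e-9 relative tolerance before the index-order tie-break: without it,
exactly symmetric geometries flip ties under the float jitter of a rigid
motion and change connectivity. The base mesh is an oriented
manifold-with-boundary disk (V − E + F = 1, 25 faces for the 5/4/4 layout);
orientation and manifoldness are checked on construction. Faces between
annulus and basal row are labelled *basal*, basal→mid *mid*, and both
mid→lower and the apex fan *lower*.

**Modified Loop subdivision.** Interior even vertices use Loop's
valence-dependent mask with β = (1/n)(5/8 − (3/8 + ¼cos(2π/n))²); boundary
even vertices the cubic-spline mask (1/8, 3/4, 1/8); interior edge midpoints
the (3/8, 3/8, 1/8, 1/8) mask; boundary edge midpoints the plain average.
These are the standard boundary modifications for open meshes; no crease
tagging is implemented. The operator is assembled as a sparse matrix whose
rows sum to 1 (affine invariance), is linear in vertex positions, and
depends only on connectivity — which is exactly what licenses applying the
*same* operator to reference and deformed crystal positions and comparing
the resulting fine meshes face by face. Default refinement level is 2 (400
faces); levels 0–4 are supported, and on smooth non-affine test deformations
regional strain means move by < 0.005 between levels 2 and 3.

## Strain computation

Per face, an orthonormal tangent frame (first axis along the first edge,
second the in-plane perpendicular) is erected on the reference and deformed
triangles; **F** is the exact 2×2 linear map between the in-frame edge
matrices, E = ½(FᵀF − I), areal strain = det F − 1. Strain is a per-face
(element-native) quantity; regional aggregation is reference-area-weighted by
default, with unweighted means available (the two differ negligibly on
near-uniform meshes).

Circumferential/longitudinal directions: the long axis L runs from the
annular-crystal centroid to the apex crystal at the reference time; per face
with normal n, longitudinal = normalized in-plane projection of L,
circumferential = n × longitudinal. Faces with n ∥ L (never the case on the
default geometry) fall back to neighbor-averaged directions. An alternative
per-row tangent construction was considered and rejected: the axis-based
field is smooth across subdivision levels and orientation-complete near the
apex fan.

Properties guaranteed and tested: objectivity (independent rigid motions of
either state change nothing to ≤1e-9), exactness for globally affine
deformations at any subdivision level (< 1e-6), 1 + areal = det F = exact
triangle-area ratio to 1e-9, and the inverse identity
(1 + a₁₂)(1 + a₂₁) = 1 when reference and deformed states are swapped.

*Cardiac* strain references each state's own ED and is evaluated at each
grid time of the averaged beat; *interventional* strain references Baseline
at the matched time point (ED or ES), with connectivity built once from the
Baseline frame.

## Synthetic phantom

The phantom stands in for unavailable animal recordings; its defaults are
the study conditions the pipeline targets.

* **Anatomy**: half-ellipsoid free wall (a = b = 50 mm, c = 70 mm), annular
  hexagon of circumradius 19.58 mm (area ≈ 996 mm²), rows at latitudes
  75°/50°/25° spanning 180° of azimuth, apex at the pole.
* **Deformation**: global affine A(t) = diag(α, α, γ) with α: 1 → λ_c = 0.92
  and γ: 1 → λ_l = 0.95 over a raised-cosine activation peaking at the ES
  phase (0.35 of the cycle). Affinity is the point: every directional and
  areal strain has a closed form (`analytic_truth`), exact for the mesh
  pipeline at any subdivision level. A non-affine long-axis twist option
  exists for robustness testing only.
* **TRA**: annular ring rescaled by s = √0.53 (53 % area ratio, 47 %
  reduction); free-wall mechanics unchanged.
* **Signals**: heart rate 106 b/min; ECG = Gaussian R-spikes (σ = 10 ms) at
  cycle starts; LV pressure = 10 + 80·pulse mmHg with a raised-cosine fall
  centred exactly at the ES phase (so max −dP/dt is at ES by construction)
  and a 2 %-of-pulse end-diastolic bump that makes the EIVR crossing well
  defined; RVP/CVP are scaled/offset companions.
* **Noise**: iid Gaussian per coordinate per sample (default σ = 0.1 mm,
  sub-millimetre transit-time localization error); optional dropout mask
  holding stale samples. Baseline and TRA carry independent noise streams.
* **Cohorts**: per-animal anatomy/heart-rate variation (HR SD 20 b/min, ring
  radius SD 1.5 mm, 5 % size CV) shared within a pair — each animal its own
  control. `null=True` removes the ring effect for calibration studies.

What the phantom does **not** emulate: non-affine regional heterogeneity,
through-wall strain gradients, valve–wall mechanical coupling, pressure–
volume physiology, respiratory motion, or crystal-specific dropout patterns.
Passing the phantom-based checks therefore demonstrates correctness of the
*measurement pipeline* (landmarking, geometry, mesh strain, statistics), not
fidelity of any physiological claim about real ventricles.

## Statistics

Paired Student's t (two-sided, α = 0.05) on TRA − Baseline differences;
Shapiro–Wilk (Royston, via scipy) on the differences as a normality screen;
Wilcoxon signed-rank as a distribution-free companion, with zeros dropped
(Wilcoxon's original convention), mid-ranks for ties, the exact sign-flip
distribution (dynamic program over doubled ranks) for ≤ 25 informative
pairs, and the tie-corrected continuity-corrected normal approximation
beyond. Exact and approximate p agree within 0.01 at n = 20. No multiplicity
correction is applied. Report conventions: HR from mean RR of the analyzed
beats, LVP/RVP as means of per-cycle peaks, CVP as mean of per-cycle means.

On 500 null phantom cohorts (n = 8 pairs, no ring effect) the measured
type-I error is ≈ 0.06 for the paired t and ≈ 0.05 for the exact Wilcoxon
(whose achievable level at n = 8 is 0.039), both within [0.03, 0.08].

## Problem sizes and runtime

Validation runs use phantoms of 6 cycles (~500 samples, 20 crystals),
subdivision level 2 (400 faces), 100 phantoms for landmark recovery, 200
draws for the noise law, 8-pair cohorts for recovery studies and 500 cohorts
for test calibration — sizes chosen so the full suite and the acceptance
script complete in a few minutes on one CPU while keeping Monte-Carlo
standard errors well inside the asserted bands.

## Known limitations

* The R-peak detector assumes clean sinus rhythm; no ectopy rejection beyond
  the per-beat usability flag.
* Hull volume is systematically below any enclosed-surface volume (sparse
  inscription); comparisons are only meaningful within a fixed layout.
* Strains are epicardial membrane strains; no bending, through-wall, or
  fibre-direction components.
* EIVC/EIVR are conventions of this package and should not be compared
  across software without checking definitions.
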