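# Methods

`sbrt4d` reimplements, at desk scale, a treatment-planning comparison of two
respiratory-motion-management strategies for pancreatic SBRT: the internal
target volume (ITV) concept, which irradiates the whole envelope of tumor
motion, and adaptive tumor tracking, which follows the tumor with the beam.
Patient 4DCT data are not available, so synthetic 4D phantoms with known
ground-truth motion replace the scans, and a declared surrogate replaces the
commercial planning system. The cohort-level motion/PTV statistics are
computed from a packaged 12-patient table and reproduce the published
numbers exactly at their printed precision.

## The 4D phantom

Each virtual patient is a ~2 mm isotropic voxel grid (axes x=LR, y=AP,
z=SI, mm, voxel-center sampling) carrying analytic organ primitives: an
ellipsoidal GTV; a duodenum built from a vertical limb lateral to the tumor
plus a horizontal limb capping it inferiorly, at a configurable
surface-to-surface gap; ellipsoidal stomach, bowel, liver and kidneys; a
spinal-cord cylinder; and an elliptic-cylinder body. Non-duodenal serial
organs (stomach, bowel) are pushed clear of the tracking PTV
(support-function separation plus 8 mm) so the duodenum gap is the only
adjacency dial; parallel organs are shrunk as needed for motion headroom on
compact grids.

Breathing is a single-frequency cosine, s(t) = (1 − cos 2πt/T)/2, sampled
at the midpoints of n equal-duration phase bins (default n = 10, T = 4 s).
Organ displacement per phase is amplitude × (s_k − s_ref) per axis, with
peak-to-peak amplitudes given in (AP, SI, LR) order; the largest amplitudes
are SI, in the 1–11 mm range of the cohort. Because the midpoint samples
span ~95% of the cosine range, the measured center-of-volume peak-to-peak
recovers the configured amplitude to within ~0.5 mm at 11 mm amplitude —
inside the half-voxel recovery tolerance asserted in the tests. The
reference ("contouring") phase is the bin whose displacement is nearest the
time average (s = 1/2), i.e. mid-ventilation; for n = 10 this is bin 2.

Ground-truth displacement fields (reference → phase, pull-back convention)
replace deformable registration. In `rigid` mode the field is spatially
constant; `rigid_plus_local` adds a Gaussian-windowed SI perturbation near
the diaphragm to exercise the warping code. Phase masks are rasterized
analytically at the displaced positions, so they are exact up to voxel
quantization. The body outline is held static: chest-wall excursion is
small compared to internal motion, and a static body means one attenuation
volume per beam angle serves every phase, both arms and all sub-doses. The
density is water (1.0) inside the body, 0 outside; an optional tumor
density contrast exists for average-CT demonstrations only and is ignored
by the dose engine, whose radiological depth is defined through the body
mask.

Structure propagation: the generic `propagate_mask` warps the signed
Euclidean distance map of a binary mask and re-thresholds at zero (sub-voxel
for smooth surfaces; Dice ≈ 0.95–0.97 against independently rasterized
phase masks at 2 mm). `propagate_gtv` warps the phantom's smooth GTV level
function instead and reaches Dice ≥ 0.99 — the idealized stand-in for
deformable structure propagation with ground-truth fields.

## Structure sets

ITV arm: the GTV motion envelope (voxel-wise OR over phases) is the ITV;
OARs are likewise envelopes; PTV_itv = ITV + 5 mm. Tracking arm: the
contouring-phase structures, with PTV_track = GTV + 5 mm. Margins are
isotropic Euclidean expansions on voxel centers (distance transform, ties
included). No planning margins are applied to OARs. Expansion measures
distance to occupied voxel centers, which biases envelopes ~half a voxel
inward; volume oracles in the tests carry a 5% tolerance for this.

## The surrogate dose engine

The inverse-optimized VMAT dose is replaced by a two-parameter analytic
surrogate; the claims under test are geometric and motion-driven, not
optimizer-driven. Per sampled gantry angle θ (two full arcs, 5° control
points, parallel beam rotating about the SI axis):

    D_θ(x) = w_θ · exp(−μ · depth(x)) · T_θ(u(x), z(x))

* depth — water-equivalent radiological depth from the body surface along
  the beam (geometric depth through the static body mask); μ = 0.004/mm.
* T_θ — beam's-eye-view fluence: the conformal aperture (orthographic
  target silhouette) smoothed by a Gaussian penumbra, implemented as an
  error function of the signed distance to the aperture edge (σ = 3 mm),
  plus a boost of +40% through the silhouette of the pre-margin target
  (ITV or tracked GTV). The boost reproduces the hot-core heterogeneity of
  a prescription to a covering isodose (maximum ≈ 150–170% of the
  prescription) without which the simultaneous-integrated-protection logic
  would never be exercised.
* w_θ — uniform monitor units per control point, summing to 1.

Opposed beams (θ, θ+180°) share one canonical lateral frame, so their
apertures are identical arrays. The engine caches one attenuation volume
per angle per patient; transmission evaluation is a separable bilinear
gather (the lateral index depends only on the in-plane position, the
longitudinal index only on the slice). Out-of-map samples blend to a zero
border ("grid-constant" semantics).

Prescription: 5 × 5 Gy with the dose scaled so D95 of the PTV equals 25 Gy
exactly; the 41.5 Gy ceiling (166%) is reported, not clipped. Coverage is
evaluated with the generalized inverse of the linear-interpolation
quantile, so D95 = Rx corresponds to exactly 95% coverage. OAR constraints:
cord Dmax < 25 Gy; bowel, duodenum, stomach Dmax < 27.5 Gy; kidney
Dmean < 10 Gy (strict inequalities).

SIP overlap handling: the protection window (25–27.5 Gy) applies to the
overlap of the PTV with the serial organs (duodenum, stomach, bowel, cord);
parallel organs are governed by their mean-dose constraints. While the
scaled D0.1cc of that overlap exceeds 27.5 Gy, the beam's-eye-view
projection of the overlap (expanded 2 mm) is subtracted from the apertures
of the angles contributing most to the excess (top eighth per iteration,
each angle blocked once, 20-iteration cap, deterministic ordering), with a
coverage guard that abandons the window once the raw PTV D95 halves — the
"compromised plan" outcome. The raw overlap D0.1cc recorded per round is
non-increasing by construction. Objectives: OAR constraints, ≥95% PTV
coverage at 25 Gy, overlap D0.1cc ≤ 27.5 Gy, overlap D98 ≥ 25 Gy, and
non-overlap PTV D95 ≥ 25 Gy; `objectives_met` is their conjunction.

## 4D dose accumulation

Delivery assumes constant gantry speed (default 3°/s, i.e. 120 s per arc)
and uniform MU per degree; arcs are delivered sequentially against a
continuing breathing trace. Each arc is segmented at every phase-bin
transition; each segment's MU share is distributed over the control-point
time windows it overlaps (windows wrap on a closed 360° arc), which makes
the per-angle MU bookkeeping exact — with zero motion the accumulated 4D
dose equals the 3D dose to floating-point noise. Five fractions start at
phases (0, 2, 4, 6, 8) to average interplay; the per-(angle, phase) shares
of all fractions are aggregated before any dose is computed, so cost does
not grow with breathing cycles or fractions.

Tracking shifts the apertures (and isocenter) rigidly by the phase's GTV
center-of-volume displacement — perfect tracking, zero latency. The
attenuation is not recomputed for the shifted beam; with a static body this
is exact for the translation component along the lateral and longitudinal
axes and a ≤2% approximation along the beam axis, which cancels to first
order over opposed beams. Phase doses are warped to the contouring phase by
pull-back trilinear interpolation of dose (no mass/energy rescaling — the
deformable dose-summation approximation) and summed.

## Dose metrics

Dx% is the (1 − x/100) linear-interpolation quantile of the structure's
voxel doses (descending-sort convention); D0.1cc reads the piecewise-linear
dose-versus-cumulative-volume curve at 0.1 cm³ (partial-voxel
interpolation; one 2 mm voxel is 0.008 cm³, so the discretization is
sub-voxel); Dmin/Dmax are true voxel extrema. DVH curves use 0.05 Gy bins.
3D parameters are evaluated on the planning structures (target = ITV or
tracked GTV); 4D parameters on the reference-phase structures with the GTV
as target for both arms.

## Cohort statistics

All tests are implemented from first principles. Wilcoxon signed-rank:
zero differences dropped, midranks for ties, exact two-sided p by
dynamic-programming enumeration of the full 2^n sign distribution for
n ≤ 20 (12 all-positive pairs give p = 2/4096 ≈ 0.000488), normal
approximation with continuity correction and midrank variance beyond.
Spearman: midranks, Pearson correlation of ranks, two-sided p from
t = ρ√((n−2)/(1−ρ²)) on n−2 degrees of freedom; exact/Monte-Carlo
permutation p behind a flag. Regression: ordinary least squares.
Summary rows use the averaged-inverted-CDF percentile rule — the midpoint
of the two central order statistics when the rank lands on an integer —
which is the rule the published quartiles follow (type-7 interpolation does
not reproduce them). Motion-derived regression and correlation use the
published 3D-motion column (the values the original analysis used); the
recomputed column agrees with it to 0.1 mm and is asserted at load time.

PTV reduction is signed (negative for smaller tracking PTVs) in regression
and correlation, absolute in prose summaries.

## The virtual cohort

`run_virtual_cohort` drives the full pipeline per patient — phantom, both
structure sets, both plans, 3D metrics, both 4D accumulations, 4D metrics —
and emits a per-patient table plus a comparison table (median per
parameter, median paired difference, quartiles, Wilcoxon p, Spearman ρ
versus 3D motion). The default cohort takes its per-axis amplitudes from
the packaged 12-patient table and sizes each (spherical) GTV so the
tracking PTV approximates the recorded volume, clipped to fit the grid.
On a 64³ grid with 10 phases and two arcs the 12-patient run takes a few
minutes on one CPU.

## What a green test does and does not establish

The phantoms emulate rigid-dominant periodic motion of water-equivalent
anatomy on a static body; they do not model CT noise, Hounsfield realism,
irregular breathing, amplitude- versus phase-sorted reconstruction
differences, inter-fraction variation, or tissue-density heterogeneity.
The dose surrogate has no MLC sequencing, no fluence optimization beyond
conformal apertures with a fixed boost, and no heterogeneity corrections
beyond body-path scaling. Consequently the dosimetric comparison tables
produced here share the published tables' *structure* and qualitative
directions (PTV reduction growing with motion, duodenum/stomach sparing
with tracking, ITV-arm objective failures in high-overlap anatomies) but
not their absolute dose values, which depend on the unavailable patient
scans. The quantities reproduced exactly are those derivable from the
packaged cohort table.

## Numerical choices

* Dose grids accumulate in float64; cached attenuation/transmission are
  float32. The zero-motion 4D = 3D identity holds to < 1e−6 Gy.
* Margin ties (distance exactly equal to the margin) are included.
* Aperture thresholds: a beam's-eye-view ray is open when the interpolated
  target occupancy along it reaches 0.5.
* Wilcoxon two-sided p = min(1, 2·min(P(W⁺ ≤ w), P(W⁺ ≥ w))).
* The fixture loader verifies a SHA-256 checksum and the 3D-motion
  consistency before any statistic is computed.
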