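# Methods

## Overview

`strokeatlas` implements an atlas-assisted pipeline for stroke neuroimaging:
midsagittal-plane (MSP) extraction, piecewise-linear (Talairach-style)
atlas-to-scan mapping with statistically localized landmarks, hemispheric
asymmetry detection, lesion quantification against anatomy and blood-supply
territory atlases, thrombolysis eligibility conditions, and a probabilistic
stroke atlas (PSA) for outcome prediction. Every component is exercised on
procedurally generated head phantoms and synthetic cohorts; no clinical data
is required or included.

## The normalized space and the procedural atlases

The reference space is an axis-aligned box with the anterior commissure (AC)
at the origin and RAS axes (mm). The canonical brain is an ellipsoid whose
cortical extremes follow the classical Talairach proportions: L/R = ∓66, A =
68, P = −102, S = 72, I = −42 mm, with the posterior commissure (PC) 24 mm
behind the AC, the top of the corpus callosum at z = 28 and the most ventral
orbito-frontal point at z = −14. The atlas grid is chosen so that no voxel
center lies on the midplane x = 0; mirroring is then an exact index
permutation, which detection depends on.

Two co-registered label volumes share this grid:

* **anatomy** — 14 parcels per hemisphere (ventricle, deep gray, four white
  matter quadrants, a brainstem–cerebellum block, occipital, and split
  frontal/temporal/parietal blocks). The parcel granularity matters for
  detection sensitivity: a lesion must occupy an appreciable fraction of some
  parcel before its statistics shift.
* **territories** — ACA, MCA-terminal, MCA-penetrating and PCA per
  hemisphere, defined by planar cuts and a deep ellipsoid. Boundaries are
  deliberately simple; exact left-right mirror symmetry is the property the
  methods rely on, not vascular fidelity.

## The head phantom

The phantom is built from the same geometric constants as the atlas: a
left-right symmetric brain ellipsoid (gray shell 110, white core 90 on a
CT-like 8-bit scale), a 2 mm subarachnoid CSF gap (30), a 5 mm skull shell
(255), a 2 mm interhemispheric CSF fissure on the midplane, and two mirrored
lateral ventricles. Optional spherical lesions are hypodense (72) or
hyperdense (190). Degradations are applied in a fixed order: lesions, a
first-order polynomial multiplicative bias field with stated peak-to-peak
percentage, rigid rotation (yaw about S-I, pitch about L-R, roll about A-P,
composed Rz·Rx·Ry, resampled linearly about the grid center while ground
truth is transformed analytically), additive Gaussian noise (default SD 2),
and axial slice-thickness pooling (mean for intensities, majority for
masks). Everything is reproducible from one integer seed.

What the phantom does **not** emulate: cortical folding, tissue texture,
partial-volume anatomy at sulci, scanner artifacts beyond noise/bias, and
perfusion physics. Passing tests therefore demonstrate the internal
consistency and geometric correctness of the algorithms under controlled
degradations, not clinical performance.

## MSP extraction by the KL measure

The interhemispheric fissure gives the true MSP an intensity distribution
(CSF-dominated) maximally different from parenchymal slices. Candidate
planes are scored by a **symmetrized KL divergence** (J-divergence) between
the plane's intensity histogram and that of a lateral reference slice; both
histograms are smoothed by ε = 1e−6 per bin and renormalized, making the
measure finite, symmetric, and zero only for identical histograms. The
directed-vs-symmetrized choice was open; symmetry removes the dependence on
which distribution is called the reference.

Numerical choices that proved load-bearing:

* **Histogram support**: 64 bins over the 1st–99th percentile of soft-tissue
  intensities, widened by 8% so low-percentile CSF stays inside the support.
  Air is excluded by a threshold just above the background mode; on CT,
  bone is excluded too (when ≥2% of non-air voxels exceed the skull
  threshold), because a skull-tangent oblique plane is otherwise as
  "different" from parenchyma as the fissure plane is.
* **Coarse stage**: grid-aligned sagittal slices in a VOI around the central
  slice are scored against the first VOI slice. Scores within 10% of the
  maximum are treated as ties broken toward the volume center — under tilt
  no grid slice is special and the raw argmax is noise.
* **Fine stage**: the plane is parameterized by the sagittal offsets of
  three corners of the coarse slice. A coarse grid over the two
  center-pivot tilt directions (±12 steps of 4 slice spacings) and a
  3-step translation bridges local dips in the KL landscape; hill climbing
  over translation, the two pivots and the single-corner moves then refines
  at scales 4, 2, 1, 0.5, 0.25 slice spacings. Plain coordinate descent on
  the raw corner offsets stalls, because a pure tilt about the plane center
  is not expressible as a single-corner move.

Residual behavior: angular accuracy on the phantom is ~0.1–1.5° for
single-axis rotations up to ±25° and combined roll/second-axis rotations to
±15°; the lateral plane position can sit up to one voxel off the fissure
center, because partial-volume planes flanking a thin fissure are
legitimate KL maxima. The mapping stage corrects this bias (below).

The **tilt-extended** variant estimates head orientation first: an ellipse
is fitted to the skull cross-section on each axial slice (yaw from the
in-plane major-axis direction, pitch/roll from the slicewise drift of the
skull center), the volume is counter-rotated, the base extractor runs, and
the pre-rotation is composed back into the returned plane. On 5 mm slices it
is accurate to ≤2° for yaws up to at least 50°.

## Ellipse-based landmarks and the piecewise-linear transform

A maximum-intensity projection over a 10 mm sagittal slab absorbs the
fissure and exposes the cortex outline, which is traced as the sub-pixel
level set of the CSF/gray midpoint intensity (70 by default); bright bone
and its 2-pixel partial-volume halo are excised first so the outline cannot
bridge to the skull. A least-squares conic fit (constrained to an ellipse)
gives center, semi-axes (a, b) and orientation.

Landmarks are fractions of the ellipse axes, **calibrated so that the
normalized-space cortex ellipse reproduces the space's stored landmarks
exactly** (the calibration is itself a test): AC at (0.2·a, −0.263·b) from
the center along the major/minor axes, PC at (0.082·a, −0.263·b), A/P at
±a, S/I at ±b, extended landmarks at 0.228·b and −0.509·b. Lateral extents
L/R are measured from the 3D brain mask in a ±4 mm slab at the AC level
when a CT skull permits brain extraction, else defaulted to ±0.776·a. The
midplane is then re-centered on (L+R)/2, which cancels the one-voxel KL
plane bias and makes the left/right split symmetric.

The transform partitions the source box at the landmark breakpoints —
x: (L, 0, R); y: (P, PC, AC, A); z: (I, AC_z, S), extended z: (I, OF,
AC_z, CC, S) — giving 12 regions with 7 scales + 3 translations + 3
orientations = 13 degrees of freedom, or 24 regions / 15 DOF extended. Each
axis is an independent monotone piecewise-linear map, so continuity across
shared faces is structural and the inverse is exact region-by-region.
Points outside the landmark box are clamped with a warning; labels resample
nearest-neighbor, intensities linearly; region membership uses half-open
intervals.

## Lesion segmentation

* **Brain extraction (CT)**: threshold the skull shell, fill its interior,
  keep the largest interior component, erode one voxel in-plane to trim the
  subarachnoid rim.
* **CSF removal**: confined to a ±4 mm dilation of the individualized
  ventricle template, with an Otsu split of the ROI histogram; nothing is
  removed unless the ROI shows a ≥20-intensity-unit CSF/tissue mode
  separation, so a template sitting in pure tissue is a no-op and distant
  hypodense lesions are untouched.
* **WMH**: a voxel is hyperintensity iff it falls inside the configured
  range in all of T1, T2 and PD. Quantification uses 26-connected
  components, volumes in ml, and Euclidean distance transforms to the
  ventricular surface; the periventricular flag uses a 10 mm default (the
  periventricular/deep dichotomy of the Fazekas scale is operationalized
  differently across sites, hence configurable).
* **DWI infarct**: hemispheric intensity PDFs on shared percentile-derived
  bins (hence invariance to affine intensity rescaling); bins where one
  side's density exceeds the mirror side's by a factor ≥3 are flagged, the
  over-represented side's voxels in those bins are marked, and the mask is
  cleaned by a morphological opening and a 1 ml minimum component. The
  ratio threshold, bin count and cleanup are engineering defaults — the
  divergence concept fixes none of them.
* **Contours**: traced along voxel-edge cracks with vertices at
  half-integer pixel coordinates (outer boundaries counter-clockwise, holes
  clockwise), rasterized back with even-odd XOR filling. This makes the
  mask → contour → mask round trip voxel-exact, which the PSA contract
  depends on; a sub-pixel tracer would not survive the round trip at
  convex corners.

## Detection (type-I ROIs)

Every lateralized ROI of both atlases is compared with its mirror partner
in 3D after CSF removal plus an explicit 8-bit CSF floor (50) that drops
residual fissure CSF. A pair is mismatched when |Δmean| > 6, |ΔSD| > 6 or
|Δpeak height| > 0.05 (8-bit scale, 64-bin normalized histograms,
population-SD convention); thresholds are user-settable, and the defaults
leave the symmetric phantom's false-positive rate at zero over the seeds
tested while detecting hypodense lesions from roughly 8 ml upward. Within
mismatched pairs, evidence voxels are those in intensity bins
over-represented at least 3× relative to the mirror ROI's density curve,
split into hypodense/hyperdense by their position against the mirror mean;
26-connected components ≥0.5 ml become findings carrying slice indices,
overlapped anatomy structures, territories and paired means. Diagnosis:
infarct evidence only → infarct; hyperdense only → hemorrhage; both with a
shared territory → infarct with hemorrhagic transformation (the category is
classical, the overlap rule is this package's choice); both without overlap
→ hemorrhage, as the clinically dominant finding. Pairs smaller than 100
voxels are skipped — after CSF removal the ventricle ROIs reduce to noisy
boundary scraps.

## Thrombolysis conditions (type-II ROIs)

All volumes and ratios are computed in 3D. The territory side is the one
holding the majority of infarct voxels; ratios are reported for MCA (and
its terminal/penetrating branches), ACA and PCA, with strict-inequality
flags against the classical 1/3 and 1/2 eligibility thresholds. The
diffusion-perfusion mismatch is the penumbra/infarct volume ratio, absent
when no penumbra mask is supplied.

## Probabilistic stroke atlas (type-III ROIs)

Lesion contours are rasterized on the scan grid and pulled back through the
case's individualization transform into a 2 mm PSA grid (speed; the space
is configurable). The aggregation pseudocode's "divide by the number of
cases" is ambiguous; both readings are registered (`mean_global_n`,
`mean_coverage`) plus median, 20% trimmed mean, min, max and two
size-weighted means — eight schemes total, all verified against a
per-voxel brute-force oracle. `mean_coverage` is the prediction default
because global-N division shrinks sparsely covered voxels toward zero.
Mean schemes support exact incremental extension by one case; order
statistics require a rebuild.

Constrained instances keep only cases whose selection variables fall in the
quantile range (computed on the cohort minus the target, half-open, top
range closed) containing the target's value; the target is always excluded
(leave-one-out rule). Prediction reads mean, SD and quartiles of the PSA
over covered ROI voxels.

The synthetic cohort couples outcomes to lesion geometry with clinically
shaped models: mRS-like (0–6) and NIHSS-like scores worsen with lesion
volume (0.05 and 0.25 points/ml) and vary along the antero-posterior
centroid; a Barthel-like index mirrors them on its 0–100 scale; Gaussian
noise uses scale-appropriate SDs (0.3 mRS points, 1 NIHSS point, 4 BI
points). Cohort scans default to 64³ at 3 mm so leave-one-out loops stay
fast. Under these conditions leave-one-out error decreases with cohort size
and an infarct-volume constraint does not worsen it — the directions the
method claims — while exact error values are properties of the synthetic
coupling, not clinical estimates.

## Problem sizes and determinism

Robustness sweeps run on 128³ phantoms at 1.5 mm (noise SD 2): single-axis
1°-steps to 25°, combined-roll to 15°, tilt-extended yaw 2°-steps to 50°;
one sweep takes a few minutes on one CPU. Unit and property tests use 96³
or toy grids where the property permits. Every stochastic path takes an
explicit seed; regenerating any phantom or cohort with the same
configuration is bit-identical.

## Known limitations

* The phantom's uniform tissues make intensity-based steps easier than on
  real scans; thresholds validated here (detection defaults, DWI ratio,
  WMH ranges) would need re-tuning on clinical data.
* The KL plane's lateral position is only accurate to about one voxel on a
  thin-fissure phantom; downstream symmetry is restored by the
  lateral-extent re-centering, which assumes an intact skull or a clean
  brain mask.
* The anatomy-driven AC/PC detector, full ventricular-extraction
  algorithms, nonlinear ventricular warping, vessel analysis and
  hemorrhagic-stroke normalization are out of scope; the ellipse path and
  the template-confined CSF removal stand in for them.
* Orientation estimation for the tilt-extended path assumes an
  approximately elliptical skull cross-section; pathological skull
  geometry would defeat it.
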