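# Methods

This note documents the models, defaults and design choices behind
`mrsynthct`, in the order the pipeline runs.

## Volumes and grids

All volumes are scalar 3D arrays indexed `(slice, row, column)` with
per-axis spacing in mm and a voxel-centre world convention
(`world = origin + index·spacing`). NIfTI-1 is the interchange format;
orientation metadata beyond spacing and origin is deliberately ignored —
the pipeline assumes co-registered inputs and refuses mismatched grids
(shape exact, spacing within 1e-6 mm, origin within 1e-3 mm) rather than
resampling. Label maps use fixed class codes 0–7: air, body, eyeball,
lens, cavity, ventricle, brainstem, bone.

## Digital head phantom

The phantom stands in for a clinical cohort: 40 slices of 128×128 voxels
at (2.5, 2.34, 2.34) mm — 2.5 mm slices, 30 cm in-plane field of view.
Geometry is analytic and rasterised at voxel centres:

* head: ellipsoid, semi-axes (45, 85, 65) mm;
* skull: ellipsoidal shell between normalised radii 0.80 and 0.92;
* paired eyeballs (r = 9.5 mm, anterior) each containing a lens
  (r = 3.4 mm) that rides rigidly with its eyeball;
* midline sinus cavity (r = 13 mm), paired lateral ventricles
  (semi-axes 10×24×9 mm), inferior brainstem (18×13×12 mm).

Per-case variation: structure semi-axes jitter ±5 % and centres ±2.5 mm;
the head itself jitters ±2 % (adult head size varies less than individual
internal structures). Containment (every structure inside the head, lens
inside eyeball) is validated on the rasterised masks and violations raise
immediately. All randomness derives from `(spec.seed, case_id, stream)`
so any single volume is reproducible in isolation.

MR intensities are class means (arbitrary units) times a smooth
multiplicative bias field (RMS 3 %) plus white Gaussian noise (SD 3).
The means encode the sequence contrast the segmentation relies on: CSF
(ventricle) dark on T1 / bright on T2, bone visible only on PETRA, lens
T1-bright / T2-dark against the vitreous. They are free parameters of
the simulation, not claims about real tissue — the configured tables are
the single source of truth.

The reference CT is deliberately *not* the ideal bulk CT. Its class
means are offset from the bulk HU table (body +25, bone 990 vs 1000,
eyeball 295 vs 300, cavity −995 vs −1000, …), and it carries white noise
(SD 8 HU) plus a smooth heterogeneity field (RMS 22 HU). Without these
offsets every similarity metric would saturate and the comparison
between the two synthetic CTs would be vacuous. Two numerical choices
matter here:

* the smooth fields are normalised to unit RMS, so the amplitude
  parameter has the same meaning in every case;
* the field's control grid (8×16×16 nodes, ≈19 mm correlation length) is
  fine enough to self-average over each tissue class. A coarser field
  would make each case's reference histogram an essentially random draw,
  which inflates between-case variance without modelling anything real.
* CT values are clipped to [−1000, 3071] HU, so the air floor is exactly
  −1000 as on a real scanner.

What the phantom does **not** model: partial-volume averaging at tissue
interfaces (class boundaries are crisp), MR physics (relaxometry,
k-space artefacts), geometric distortion, lesions, and the
immobilisation hardware present in treatment-position CT. Consequently
the segmentation scores on the phantom sit near the ceiling (mean DSC
≥ 97 per class at default noise) and should be read as a validation of
the pipeline mechanics, not as expected clinical performance; real-data
DSC for MR-based bone segmentation is far lower.

## Automatic segmentation

Body/air separation thresholds the PETRA volume at 15 % of its 99th
percentile, keeps the largest connected component and fills holes
slice-wise (so internal air ends up inside the body). The eight-class
step normalises each sequence by its median inside the body mask —
thresholds are therefore expressed relative to bulk soft tissue ≈ 1.0
and tolerate global scaling and mild bias fields.

Classes are assigned by a fixed first-match-wins cascade:
bone → cavity → ventricle → eyeball → lens → brainstem → residual body.
The order puts the classes with the most specific signatures first and
makes tie-breaking explicit (a voxel matching both the bone and cavity
rules is bone). Localised classes are additionally gated by atlas-style
priors: ellipsoidal supports in the body-bounding-box-normalised frame,
inflated well beyond the nominal structure extents so anatomical
variation stays inside them. No inter-subject registration is needed.

Cleanup removes connected components smaller than 3 voxels
(26-connectivity, so diagonally-touching rasterised shells stay whole);
the lens is exempt because it is legitimately tiny. Morphological
closing/opening radii are available but default to 0: the rules'
intensity margins already absorb realistic noise, and closing with a
1-voxel anisotropic ball measurably distorts the thin skull shell
(and lets the eyeball's closure swallow the lens). When closing is
enabled, a guard prevents one class's closure from absorbing voxels that
another class's raw rule claimed.

With noise disabled the segmentation reproduces the phantom truth
exactly — the class means are separable by construction — which the
tests use as an end-to-end oracle.

## Synthetic CT synthesis

`synthesize_bct` is a per-voxel lookup of the class CT number from a
configurable table (defaults above; two class pairs share a value, so
the output takes six distinct values). `synthesize_wct` maps the body
mask to {0, −1000} HU. Both are pure functions of their inputs.

## Similarity evaluation

*Overlap.* DSC/FND/FPD as defined in the README, computed from exact
voxel counts. FND and FPD are not clamped: an empty segmentation of a
nonempty truth scores FND = 200 by the definition. Cohort tables report
mean and sample SD (n−1); a single-case cohort reports SD 0 with an
explicit degenerate flag instead of NaN.

*Histograms.* Default binning is 256 bins over [−1000, 1000] HU applied
identically to both images, with out-of-range values clipped into the
end bins (mass is conserved). Histograms are unit-normalised — required
for the intersection's "perfect match = 1" anchor. Correlation uses
mean-centred bin vectors (the usual computer-vision convention); it is
undefined for a zero-variance histogram, in which case the combined
comparison reports NaN with a flag while the other three scores are
still computed. Chi-square uses the symmetric denominator H₁+H₂ with
both-zero bins contributing 0. The Bhattacharyya distance uses the
Hellinger form, which meets the 0/1 anchors for unit-sum inputs.

*Gamma.* Evaluated per axial slice by default (3D optional), within the
minimum rectangle covering the body on each slice. The value criterion
is a percentage of a normalization value taken from the reference inside
the ROI; the default is the dynamic range (max − min), which handles
negative HU without an arbitrary shift, with fixed-2000-HU-span and
shifted-maximum modes as alternatives. The search over evaluated voxel
centres is exhaustive within `search_radius_factor × Δd_M` (default 2):
any match beyond that distance has γ > factor from the distance term
alone, so the cap is exact for all γ below the factor and always exact
for the γ ≤ 1 pass/fail decision. Offsets are visited in order of
increasing distance and the scan stops once the distance term alone can
no longer lower any voxel's minimum — an exact early termination. γ ≤ 1
counts as a pass (inclusive). No interpolation is used by default;
integer upsampling of the evaluated image (linear interpolation) is
available for sub-voxel distance-to-agreement. Tightening the criteria
can only raise every voxel's γ, so pass rates are guaranteed monotone
across 3 mm/3 % → 2 mm/2 % → 1 mm/1 %.

## Statistics

W_CT vs B_CT metric sets are compared with Welch's unequal-variance
two-sample t-test (two-sided, α = 0.05), implemented directly from the
Welch–Satterthwaite formulas; the test suite cross-checks it against an
independent library implementation. "Improvement" is defined as the
signed mean difference in the direction favouring B_CT (higher
correlation/intersection/pass rate; lower chi-square/Bhattacharyya) —
positive means the bulk CT is better. The power analysis uses the
two-group normal approximation
n = ⌈2(z_{1−α/2} + z_{power})²/d²⌉ per group at power 0.9, α = 0.05,
evaluated at each metric's observed standardised effect, and the report
flags whether the cohort size is sufficient.

## Problem sizes

The default study is 20 phantom cases on the full 40×128×128 grid; it
runs in roughly half a minute on one CPU, and the test suite (including
a complete study and the brute-force gamma cross-check on fifty 24×24
image pairs) in about a minute. The phantom's default noise levels and
the cohort size are fixed study conditions, not tuning knobs; the
acceptance script re-runs everything from scratch for any seed.

## Known limitations

* Intensity rules and priors are calibrated to the phantom's contrast
  model; applying them to real MR data would at minimum require
  re-deriving the normalised thresholds, and no claim is made that the
  defaults reproduce clinical segmentation accuracy.
* The gamma search is discrete (voxel centres) unless upsampling is
  requested; published gamma tools interpolate, so absolute pass rates
  are not directly comparable across implementations.
* Histogram scores depend on the (unknown in general) binning
  convention; the 256-bin default is a documented package choice.
* External air and internal cavities both map to −1000 HU, so their
  distinction affects segmentation scoring only, never the synthetic CT.
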