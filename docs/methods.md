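# Methods

## Problem and scope

White matter hyperintensities on FLAIR MRI are graded visually on the Fazekas
(0–3) and Brain Dock (0–4) scales, separately for periventricular (PVH) and
deep/subcortical (DWMH) lesions. `wmhgrade` automates everything *after*
segmentation: given binary brain, lateral-ventricle and WMH masks on one
voxel grid, it partitions the WMH into PVH/DWMH, converts volumes to
brain-normalized ratios, and predicts grades by thresholding those ratios.
Segmentation itself (of lesions, ventricles or brain) is out of scope; the
package consumes masks from any source.

All computation happens in stored voxel space. No resampling or
reorientation is performed — clinical FLAIR in this regime has 5–6 mm slices
and sub-millimetre pixels, and both the partition and the volumes are
invariant to orientation once the axial axis is known. The axial axis
defaults to the axis of maximum spacing (correct whenever slices are thicker
than pixels) and can be overridden.

## PVH/DWMH partition

**PV shell.** The periventricular region is every voxel whose centre lies
within `pv_distance_mm` (default 10 mm, the widely adopted criterion for the
PVH/DWMH distinction) of some ventricle voxel centre, minus the ventricles
themselves. It is built by one binary dilation with the anisotropic
ellipsoidal structuring element of all integer offsets `(i,j,k)` with
`(i·sx)² + (j·sy)² + (k·sz)² ≤ r²`. The central plane of this element is the
in-plane 10 mm disk, so the single 3D pass reproduces the union of a 2D and
a 3D mm-radius expansion in one operation. Distances are centre-to-centre;
there is no sub-voxel surface model. The test suite holds the dilation
output voxel-identical to an exhaustive pairwise anisotropic distance
computation on random grids.

**Components.** WMH voxels are grouped into 2D connected components per
axial slice (8-connectivity by default, 4 available); components are never
merged across slices. Classification: a component entirely inside the shell
is PVH; entirely outside, DWMH; boundary-spanning components are kept whole
as PVH when strictly more than `pv_fraction` (default 0.60) of their voxels
lie inside, otherwise split voxelwise along the shell boundary. The
inequality is strict — a component with exactly 60% inside is split — and
the fraction is computed in voxel counts, which equals an area fraction
since in-plane spacing is uniform within a slice. Split components are
recorded once with `assigned="split"`; the voxelwise labels carry the
partition. Candidate fractions 0.5–0.9 are all meaningful settings;
`pv_fraction` is exposed as a parameter rather than hard-coded.

**Volumes.** `pvh_ml = #voxels × sx·sy·sz / 1000`, likewise DWMH and brain;
ratios divide by brain volume. By construction PVH ∪ DWMH = WMH and
PVH ∩ DWMH = ∅, so volumes are conserved to floating-point precision.

## Threshold learning and grade prediction

Grades are predicted from a ratio *r* as the number of boundary thresholds
at or below it; a tie at a threshold takes the *higher* grade, matching the
ROC convention of calling a subject positive at `r ≥ t`. (The equality side
is a genuine convention choice; it only matters for exact ties.)

* **density** — per grade, a Gaussian KDE on raw ratios with Silverman's
  rule bandwidth, floored at 1e-6 so constant samples degenerate gracefully;
  the peak is the argmax on a 2048-point uniform grid over
  `[0, 1.05·max(r)]`; each boundary is the arithmetic midpoint of the two
  adjacent peaks. Kernel, bandwidth rule, raw-vs-log scale and grid are
  implementation choices documented here, since only "KDE with peak
  midpoints" is pinned down by the procedure itself.
* **youden_all / youden_neighbor** — boundary `g|g+1` becomes a binary
  problem: negatives are grades ≤ g (all) or = g (neighbor); positives
  ≥ g+1 or = g+1. Candidates are the midpoints between consecutive distinct
  sorted pooled ratios plus one sentinel below the minimum, so the scan is
  finite and exhaustive; J = sensitivity + specificity − 1 is maximized,
  with ties broken by higher sensitivity and then the smaller threshold.
  With only two grades the strategies coincide.

Fitted boundaries can come out non-monotone on pathological data; they are
then sorted with a warning rather than rejected, because prediction needs
monotone thresholds and rejecting would make the fit unusable exactly when
the data are most ambiguous.

Reference Fazekas thresholds fitted with Youden-neighbor on a clinical
training cohort ship as `DEFAULT_FAZEKAS_THRESHOLDS`, so grading works with
no training data. Brain Dock grades map to Fazekas by merging 4 into 3;
predicting on Brain Dock and merging equals predicting with the Fazekas set
obtained by dropping the top boundary.

## Evaluation

Boundary metrics binarize grades at each cut (positive = upper group) and
report accuracy and F1 of the positive class, with F1 defined as 0 when
precision + recall is 0. Multi-class metrics are exact-match accuracy,
*macro* F1 averaged over the grades present in ground truth or prediction
(absent grades cannot zero out the mean), and MAE on integer grades, on the
scale actually used for prediction. Agreement uses unweighted Cohen's kappa
per rater pair (returning 1 in the degenerate all-identical-single-category
case where the usual ratio is 0/0) and Fleiss' kappa over a complete panel
(NaN with a warning when a single category is used by everyone, where
expected agreement is 1). Accuracy/F1 and Cohen's kappa are computed via
scikit-learn and Fleiss' kappa via statsmodels; the tests pin all of them to
naive textbook implementations at 1e-12.

## Synthetic data

`make_phantom` rasterizes an ellipsoidal brain (default semiaxes
55×70×52 mm on a 160×192×24 grid at 1×1×6 mm — a realistic thick-slice
clinical geometry), two ellipsoidal ventricle bodies (±14 mm laterally,
7×28×10 mm), and spherical lesions placed so the anisotropic distance from
the lesion centre to the ventricle surface matches a requested offset.
Placement is deterministic: among candidate centres at the right distance
(preferring those with enough brain margin to contain the radius), the one
farthest along a caller-given direction is chosen. Generation fails loudly
if a lesion leaves the brain, touches another structure (touching lesions
would merge into one component and break the lesion↔component truth
mapping), or cannot realize its intended class (fully inside the 10 mm
shell for PVH, fully outside for DWMH, crossing it for "straddling").
Per-lesion truth records class, voxel count, volume, and in-shell voxel
count; for non-straddling lesions the separation must recover class and
volume exactly, and the tests assert it does.

`sample_cohort` draws grade-conditional volume ratios from log-normal
distributions — lesion volumes are positive and strongly right-skewed, with
SDs comparable to means, which a normal model cannot represent. The default
calibration takes bundled per-grade mean/SD lesion volumes (mL) observed in
a clinical training cohort (e.g. Fazekas-3 PVH 13.503 ± 5.642 mL) and
divides by a nominal 1400 mL adult brain, since the reference statistics
are absolute volumes while grading operates on ratios. The log-normal
(μ, σ) are moment-matched to each mean/SD pair; `sd = 0` degenerates to a
point mass.

What the phantoms do **not** emulate: real lesion shapes (confluent caps
and bands rather than spheres), segmentation errors, partial-volume
effects, inter-subject registration imperfections, or any intensity
information. Passing tests therefore demonstrate correctness of the
*partition and grading rules*, not segmentation robustness on clinical
images.

## Numerical and design choices

* Binarization on read is strict (`value > threshold`, default 0.5).
* Mask spacing equality is enforced to 1e-4 mm within a subject; ventricles
  outside the brain warn rather than fail (tight brain masks are common).
* Combined output label maps use PVH=1, DWMH=2 — a package convention.
* Youden candidate midpoints (not observed values) keep the chosen cut off
  the data points, making the `r ≥ t` tie rule irrelevant on training data.
* The plug-in Bayes oracle used in testing classifies held-out draws by the
  true generating log-normal densities with equal priors; on the default
  overlapping cohort, Youden-neighbor and density thresholds reach held-out
  accuracy within 3 points of that rate. Youden-all does not: pooling
  non-adjacent grades shifts its cuts away from the adjacent-grade
  crossings, a structural handicap of the strategy under heavy overlap
  (and the reason the neighbor variant is the recommended default).

## Problem sizes

Default test and acceptance runs use grids up to 48×48×12 for oracle
comparisons, 96×112×20 phantoms at 1.5×1.5×6 mm, and cohorts of 100
subjects per grade — small enough for laptop-speed runs while exercising
every code path at clinically representative spacings.

## Limitations

The 10 mm rule and the 60% fraction are conventions, not anatomy; the
package applies them exactly but cannot validate them. Threshold quality
depends entirely on the training cohort's grade composition; with fewer
than ~20 subjects per grade the Youden cuts are noisy. The bundled
reference thresholds were fitted on one cohort's scanner mix and rater
pool and should be refitted for materially different populations.
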