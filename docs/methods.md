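# Methods

`pmmorph` implements a morphometry pipeline for postmortem brain MRI of
formalin-immersed hemispheres, together with the synthetic phantoms and
cohort simulators needed to test every stage without access to donor data.
This note records the models, the parameters that matter, the numerical
choices, and what the phantom experiments do and do not establish.

## Dual-modality brain extraction

Formalin defeats single-modality skull-stripping: it is brighter than
tissue in T2 and darker than white matter in T1, and its texture is smooth
at the voxel scale while tissue is not. The extraction model therefore
consumes both modalities at once. Three small convolutional autoencoders
segment 16x16 patches taken orthogonal to each anatomical axis (sagittal,
coronal, axial), with the T1 and T2 patches stacked as two input channels.

Each model is: three convolutional layers of twelve 5x5 kernels, each
followed by batch normalization and a leaky ReLU with slope 0.1; a flatten
to 192 features; a dense 192→192 bottleneck with dropout 0.25; two
mirrored transposed-convolution layers (same structure); and a final
single-kernel transposed convolution emitting a 16x16 patch of logits with
no normalization or activation. This comes to 52,657 parameters per model
— 52,537 trainable and 120 non-trainable batch-norm running statistics —
small enough to train on one CPU.

Two details are underdetermined by the parameter count alone and were fixed
as follows:

- **Spatial plan.** Parameter counts are stride-independent, but the
  192-feature flatten forces the encoder output to 4x4x12. With "same"
  padding the encoder strides are (2, 2, 1), i.e. 16→8→4→4, and the decoder
  mirrors them as (1, 2, 2). 
- **Input normalization.** Raw scanner units are arbitrary and the formalin
  T2 tail makes min/max scaling unstable, so each volume is rescaled so its
  1st/99th intensity percentiles map to [0, 1]; the identical rule applies
  at training and inference and is recorded with the trained triplet.

Training uses Adam (β₁ = 0.9, β₂ = 0.999, AMSGrad), batch 250, binary
cross-entropy computed from logits, and a staged schedule of 25 epochs at
each learning rate in (0.02, 0.01, 0.005, 0.002, 0.001) — 125 epochs — at
25,000 patches per scan per axis. Phantom experiments in this repository
use a shorter schedule (two stages, 8 epochs each, ≤ 3,000 patches per
scan per axis), which saturates performance on the high-contrast phantoms;
the full schedule remains the default of `TrainConfig`.

Patches are anchored by their minimal corner and sampled uniformly over
valid corners. At inference, patches are tiled at every through-plane
position and on a stride-5 grid in-plane, with the last valid position
appended per axis so borders are always covered (a bare stride grid leaves
up to 4 voxels uncovered). Logits from all overlapping patches of all
three models are summed per voxel; a voxel enters the raw mask iff the sum
is strictly positive. Cleanup fills interior holes (6-connected
background) and removes 26-connected components smaller than 5% of the
largest one. Removing *all* but the largest component would be wrong here:
the cerebellum of a postmortem sample floats detached from the forebrain
and is itself ~10% of the hemisphere, so only speck-sized clusters may be
discarded. This threshold was chosen from the geometry (specks ≪ 5%,
cerebellum ≈ 10%) rather than tuned.

Segmentation quality is measured by Dice, TPR and TNR from voxel confusion
counts; "pulled" metrics recompute the ratios from counts summed across
test cases.

## Intensity correction

Residual low-frequency gain inside the brain mask is removed by normalized
convolution: smooth the masked image and the mask with the same Gaussian
kernel (σ = 2 mm, truncated at 4σ, σ in voxels derived per-axis from the
spacing), take their ratio as the gain-field estimate — the division by
the smoothed mask prevents the dark exterior from biasing the field near
the brain border — divide the original image by the field inside the mask,
and rescale by one scalar so the mean over the mask is exactly preserved.
A constant image is a fixed point; the output is zero outside the mask.
The five-step description this implements ends, read literally, at the
smoothed field itself; since a blurred image cannot preserve grey/white
border contrast, the ratio-to-field interpretation is used.

## Intensity matching and session averaging

To combine differently calibrated scans of one clinical session, a
monotone source→target intensity mapping is estimated from 100,000
co-located voxel samples: source samples are sorted and cut into
consecutive batches of 29 (the trailing partial batch of 8 is dropped);
each batch contributes one control point whose ordinate is the median of
the batch's target samples and whose abscissa is the source value of the
sample pair whose target value is closest to that median. Control points
are deduplicated, made non-decreasing by cumulative maximum (the source
text does not address monotonicity; a non-monotone intensity map is not
meaningful), and interpolated piecewise-linearly with clamped ends.
Session averaging maps every scan onto the first and takes the voxelwise
mean; the result is deliberately order-sensitive, the first scan being the
reference.

## Restricted atlases

Whole-brain atlases are edited for postmortem left hemispheres: ventricle
labels removed everywhere; right-hemisphere labels removed; bilateral
regions cut at the midline plane of the template's first voxel axis
(0-based index, default 90, side configurable — the published plane fixes
only the world-space location, not the index convention); and cerebellar
labels erased within Chebyshev distance 2 of any cortical label (two
dilations with a 3x3x3 element). The erosion opens a gap that deformable
registration can stretch to follow a cerebellum that floats several
millimeters from the forebrain. Both operations only remove labels, never
add or rename, and their postconditions are machine-checked after each
call.

## Tissue-constrained fusion

Each warped atlas parcellation is first cleaned against the subject's
tissue map: wrong-tissue labels are removed (GM labels off grey matter, WM
labels off white matter, anything on CSF/background), cerebellar
grey/white label values are swapped to match the tissue, each
non-cerebellar label keeps its largest 26-connected component, cerebellar
WM grows synchronously into unlabeled WM voxels with a cerebellar-WM
neighbor in their 3x3x3 box, and unlabeled GM voxels with strictly more
than five cerebellar-WM voxels in their 7x7x7 box become cerebellar GM
(the 7x7x7 box intentionally counteracts the atlas erosion above).

Fusion then proceeds white matter first: per-voxel plurality over the
cleaned parcellations' WM labels, per-label component pruning, synchronous
region growing that assigns the most frequent already-selected WM label in
a 7x7x7 box, and reassignment of unreachable WM islands to grey matter
(they are tissue-segmentation failures; the count is reported). Grey
matter voxels are labeled by Gaussian-weighted neighborhood voting: all GM
labels of all parcellations within a 5x5x5 box vote with weight
exp(−d²/2σ²), σ = √2 voxels (up to 20 x 125 = 2500 votes per voxel); the
weights are unnormalized since only the argmax matters. Finally, any
GM-tissue voxel marked cerebellar GM by strictly more than a quarter of
the cleaned parcellations is set to cerebellar GM directly. All ties break
to the smallest label id, and growing is synchronous, so the output is
independent of scan order. GM voxels that receive zero votes stay
unlabeled and are counted in the result.

## Voronoi tessellation of cerebrum WM

Each cerebrum-WM voxel is relabeled by its L1-nearest grey-matter region
(`offset + g`, offset 10,000, keeping the pairing invertible for the WMH
swap). Distances come from per-region city-block chamfer distance
transforms, which are exact for the L1 metric on a voxel grid; ties break
to the smallest region id. A brute-force per-voxel scan over GM voxels
serves as the test oracle.

## WMH accounting

WMH volume is measured per region as overlap voxel count times voxel
volume. Because hyperintense WM mimics grey matter on T2, intensity-driven
tissue maps push WMH volume into GM regions; the corrective swap moves
each GM region's WMH volume (volume and WMH bookkeeping together) into its
Voronoi WM partner. The swap is table-level bookkeeping, not voxel
relabeling — donors without WMH masks receive the same-sex mean of the
reference donors' swap amounts, which has no voxel-level counterpart — and
conserves total volume and total WMH volume exactly; imputed amounts are
clipped at the available region volume with a warning. Fractions are
reported both before and after swapping. The same per-region deltas can be
replicated onto in vivo volume tables.

## Morphometry models

Regional volumes are modeled with robust linear regression under Huber's
norm — tuning constant 1.345 (the standard 95%-efficiency choice; the
source names the estimator but no constant) with asymptotic normal
p-values — as

    volume ~ intercept + sexF + age + invivo + AD + FTD + OD + VD + M

with sex(F) = 1 for women, `invivo` marking antemortem observations (which
inherit the donor's postmortem diagnosis), diagnosis indicators not
mutually exclusive, and M flagging missing diagnosis (all four indicators
zero then). Aggregates: deep grey matter is the sum over labels 10, 11,
12, 13, 17, 18, 26; cerebellum over labels 7 and 8; hippocampus is label
17; a donor with two scan sessions contributes the mean. A missing
required label yields a missing aggregate, never a silent zero.

The age/neuropathology relation is fitted the other way around: age as a
robust quadratic in s = Thal + Braak + CERAD (s ∈ [0, 14] under the 0–5 /
0–6 / 0–3 encodings), then a second robust quadratic of |age − predicted|
giving a ± error band. Negative error predictions are floored at zero and
counted, so the band always contains the point prediction. Where a related
published model prints the same coefficient symbol for s and s², that is
treated as a typo and two free coefficients are fitted. Bonferroni
corrections use the family size declared by the caller (e.g., the number
of Voronoi regions) rather than one inferred from the data.

## Phantom generator

The phantom reproduces the *properties the algorithms exploit*, not
anatomy: an air shell; a formalin ellipsoid bright in T2 (mean 1.0 vs 0.6
grey / 0.38 white) and darker than WM in T1 (0.2 vs 0.72); voxel-scale
Gaussian texture in tissue (sd 0.05) against centimeter-scale smooth
artifacts in formalin (Gaussian-filtered noise, σ = 12 voxels, amplitude
0.08); a hemisphere-like forebrain (GM shell over a WM core with seven
deep nuclei, cut by a half-space); a cerebellum detached by ≥ 3 voxels of
formalin; cortical parcels as quadrants of the GM shell; and spherical WMH
blobs inside cerebrum WM whose T2 intensity matches grey matter. A
`degraded_tissue` map marks WMH voxels as grey matter, mimicking what an
intensity-driven tissue classifier produces and enabling the swap
experiment. Pseudo-atlases warp the true parcellation through smooth
random displacement fields (Gaussian-filtered, RMS magnitude =
the requested amplitude in mm, nearest-neighbor pull-back); amplitude 0
reproduces the truth exactly, and a deformation that erases a label
entirely is an error, not a silent degradation.

What passing phantom tests shows: the models can exploit dual-modality
intensity/texture contrast; fusion corrects independent registration
errors; the bookkeeping is exact. What they do not show: performance under
real formalin chemistry, scanner noise spectra, anatomical shape
variation, or true registration failure modes — phantom compartments are
ellipsoids with stationary Gaussian texture, far more homogeneous than
tissue.

The cohort simulator draws neuropathology scores from clipped rounded
normals matched to the published cohort means (Thal 3.8, Braak 4.6, CERAD
1.9), generates age from the quadratic score model (intercept 60 y, slope
3.2 y per score point, curvature −0.13 — chosen to place the cohort mean
age near 77 y with an inverted-U trend; residual sd 8 y), and generates
regional volumes from the linear model with coefficient magnitudes taken
from the study-scale fits (e.g. whole brain: intercept 5.85x10^5 mm³, sex
−7.52x10^4, in vivo +6.96x10^4, residual sd 3x10^4 mm³). Sex balance
47:45, missing-diagnosis rate 15/92, in vivo availability 31/92, in vivo
scans 3.83 ± 1 years before death.

## Problem sizes and runtime choices

Phantoms are 64^3 at 0.5 mm. The segmentation cross-validation used in the
acceptance suite runs 6 phantoms with leave-three-out (two folds), 3,000
patches per scan per axis and the two-stage schedule; this keeps a full
run around ten minutes on one CPU while saturating phantom segmentation
quality. Fusion experiments use 20 pseudo-atlases at 1 mm RMS deformation.
Cohort experiments use n = 200 donors and 50 replicates.

## Numerical choices and degenerate inputs

- Grids must match exactly in dims and within 1e-6 mm in spacing; every
  cross-volume operation enforces this.
- Scalars are stored as float32, labels as int32 (lossless for all ids).
- Neighborhood counts use exact integer arithmetic via separable
  correlation; thresholds like "strictly more than five" are exact.
- The network engine computes in float32; its backward passes are verified
  against float64 central differences in the suite.
- Constant-intensity sources yield a degenerate single-point intensity
  mapping with a warning; empty masks are rejected (correction) or
  returned empty with a warning (cleanup).
- All randomness flows through seeded NumPy generators; identical inputs
  and seeds give identical outputs on a given platform.

## Known limitations

- The NumPy training loop is single-threaded BLAS matmuls; it is sized for
  16x16 patches and desk-scale schedules, not for GPU-scale experiments.
- No MRI physics: no Rician noise, no k-space artifacts, no partial
  volume beyond voxelization.
- Registration, bias-field correction (N4), denoising, tissue
  segmentation and super-resolution synthesis are upstream tools; the
  pipeline consumes their outputs and cannot compensate for their failure
  modes beyond the documented cleaning rules.
- The imputed WMH swap assumes same-sex donors share regional WMH
  topography; it transfers mean amounts, not distributions.
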