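# Methods

This note documents the models, conventions and numerical choices behind
`hepavol`, and what its synthetic experiments do and do not demonstrate.

## Vessel-to-volume ratios

All ratios are percentages of total liver volume. The liver mask is the
union of parenchyma and both vessel systems, so the denominator includes
vessel voxels; nothing is excluded. `TVVR = HVVR + PVVR` therefore holds
exactly for every label map, and it is asserted as an identity in the
tests. Organ volumes are voxel count × voxel volume, reported in cc.

Published group medians of these ratios (3.9 / 2.8 / 2.3 TVVR,
2.1 / 1.7 / 1.0 HVVR, 1.7 / 1.2 / 1.2 PVVR for control / non-ACLD / ACLD)
are plausible only as percentages; the package treats them as such
throughout.

## EDT calibre convention

Per-voxel vessel calibre is the Euclidean distance transform value: the
distance in mm from the voxel centre to the nearest background voxel
centre, computed in physical units on anisotropic grids
(`scipy.ndimage.distance_transform_edt` with `sampling=spacing`). This
quantity is geometrically a *radius*, but the field's reporting convention
calls it the vessel *diameter*; we follow that convention verbatim and bin
the raw EDT value into [0, 5), [5, 10), [10, ∞) mm. Bins are half-open and
left-closed (a value of exactly 5 mm falls in the middle bin) for
determinism.

Calibre-stratified Dice partitions the *ground-truth* foreground by its
EDT bins; each bin's region is the bin mask dilated by one voxel so
boundary predictions are absorbed rather than dropped, and the bin Dice
compares `pred ∩ region` with `gt ∩ region`. A bin empty in the ground
truth is reported as undefined (NaN) and excluded from averages. One
consequence of the raw-EDT convention worth knowing: the outer shell of a
large trunk has small EDT values, so the 0–5 mm bin always contains shell
voxels of large vessels in addition to genuinely thin branches.

## Image phantoms

A phantom is an ellipsoidal liver and a disjoint ellipsoidal spleen on a
configurable grid (default test scale 48³ voxels at 3.0–3.5 mm spacing).
Two vascular trees grow inside the liver by recursive bifurcation: a
portal tree entering at a hilum surrogate (low end of axis 1) and a
hepatic-vein tree draining at an IVC surrogate (high end of axis 2) whose
root trunk is included in the hepatic label, mirroring the "hepatic veins
including intrahepatic IVC" labelling convention. Child segments start at
the parent's end, taper by a random factor in [0.68, 0.8], deflect by
25–50°, and stop below a minimum radius or depth 6. Segment midpoints and
endpoints are constrained to the liver mask.

Rasterisation marks a voxel foreground iff its centre lies within the
segment radius of any segment axis (distances in mm). Radii are floored at
half the smallest voxel spacing so sub-voxel branches are not silently
dropped; tree growth therefore also stops below that floor, since thinner
branches could only add un-shrinkable volume. Radii are calibrated in two
stages — analytically (cylinder volume ∝ r²), then iteratively against the
rasterised, liver-clipped, overlap-resolved voxel volume (up to 10
iterations, 3 % tolerance, pruning the thinnest leaves when radius scaling
saturates against the rasterisation floor). The construction contract is
±10 % relative on each system's volume fraction; grids of 32³ at ~4.5 mm
or finer meet it comfortably, coarser grids may not (quantisation).

Ground-truth VVRs are computed *from the emitted label map* by the same
voxel-counting code used for predictions, never from the analytic tree, so
ground truth and metrics share one convention.

Intensities are three plateaus (vessels 0.95 > parenchyma 0.55 > spleen
0.40 > background 0.05), emulating the portal-venous-phase ordering in
which venous vessels are most conspicuous, optionally modulated by a
low-order cosine bias field (default amplitude 10 %) and additive Gaussian
noise. No MRI physics (relaxation, k-space, motion, contrast
pharmacokinetics) is simulated, and no arterial or biliary trees exist:
segmentation results on these phantoms demonstrate that the network and
pipeline machinery work, not that the specific published Dice levels on
patient MRI are reproduced.

## Tabular cohort simulator

Groups: control / non-ACLD / ACLD with default sizes 35 / 44 / 118.
Laboratory marginals are log-normals matched to per-group median and IQR
(median exact in distribution; quartiles to the symmetric-in-log
approximation); age is Gaussian; sex Bernoulli. Marginal levels for
albumin, bilirubin, platelets, LSM, HVPG, spleen and liver volume follow
the published per-group medians/IQRs. Three deliberate choices where no
published value exists:

- **Controls' labs** are healthy reference ranges (controls have no CLD
  work-up in the source cohort); they never enter the CLD-only
  correlation analyses.
- **AST/ALT/INR/creatinine/sodium** are not published directly; their
  levels were calibrated once so that the *computed* score medians land
  near the published score medians (FIB-4 ≈ 3.6 vs 3.5 ACLD and 0.79 vs
  0.8 non-ACLD; MELD-Na ≈ 8.8 vs 8.3 ACLD, 7.5 vs 6.6 non-ACLD at
  n = 20 000). The residual gaps reflect that the median of a nonlinear
  score is not the score of the medians.
- **Decompensated fraction** in ACLD defaults to 0.40, typical of a
  tertiary-centre cohort.

Albumin is stored in g/L (values ≈ 33–47); the ALBI formula consumes it
directly. Bilirubin is stored in mg/dL and converted to µmol/L (× 17.1)
inside the ALBI computation. Score formulas: FIB-4 = age·AST /
(PLT·√ALT); ALBI = 0.66·log₁₀(bilirubin µmol/L) − 0.085·albumin g/L;
MELD-Na per the UNOS variant with the standard clamps (creatinine to
[1, 4], bilirubin and INR floored at 1, sodium to [125, 137], final score
to [6, 40]).

Dependence is a one-factor Gaussian copula: each variable loads on a
latent disease-severity factor with a configured loading; the implied
latent correlation of any pair is the product of their loadings, so the
sign structure is configured directly (HVVR and platelets load
negatively; bilirubin, AST, INR, LSM, HVPG and spleen volume positively;
albumin and sodium negatively). Within-group loadings plus between-group
mean shifts jointly reproduce the published cohort-level Spearman signs
(HVVR negative against FIB-4/ALBI/MELD-Na/LSM/spleen volume, positive
against platelets). A full correlation-matrix copula was not needed for
the sign structure and would add little at these sample sizes.

Per-subject phantom construction targets are that subject's drawn
HVVR/PVVR, sampled from group-specific log-normals fitted to the
published median/IQR — skewed, positive, and consistent with the reported
interquartile ranges.

LSM is observed in 14/44 non-ACLD and 51/118 ACLD subjects; HVPG only in
ACLD (50/118). Missingness is completely at random within those
fractions; correlation analyses are pairwise-complete, matching the
per-variable n of the source analysis.

## 3D U-Net

Architecture: `n_levels` resolutions (default 3, i.e. two 2×2×2 max
poolings); per resolution a block of two 3×3×3 convolutions each followed
by group normalisation (8 groups, clamped to a divisor of the channel
count) and ReLU; channel widths double from `base_channels`
(default 16); decoder mirrors the encoder with nearest-neighbour 2×
upsampling and concatenating skips; a final 1×1×1 convolution yields
per-voxel class scores. Patch sizes must be divisible by the pooling
factor; strides must not exceed the patch.

The layers are implemented directly on NumPy arrays with analytic
backward passes; convolutions run as im2col + one BLAS sgemm per pass,
and the input gradient as the 'same'-padded convolution with the
channel-transposed, spatially flipped kernel, which keeps both passes
GEMM-dominated. Gradients are verified in the tests by directional finite
differences (full network) and a dense einsum oracle (single layer).

Loss: per-voxel cross-entropy plus soft multi-class Dice (1 − mean over
classes of (2Σpg+ε)/(Σp+Σg+ε)), the standard pairing for heavily
class-imbalanced vessel maps; either term alone is configurable.
Optimiser: Adam at 1e-3, batch size 1. Non-finite loss aborts with a
diagnostic.

Training schedule (desk scale): each epoch draws `steps_per_epoch`
(default 1) patches, visiting cases in fixed rotation at per-case,
foreground-biased patch origins chosen once from the stride grid; with
augmentation disabled the schedule is fully deterministic (a zero
learning rate yields a constant loss trace on a single case), and epoch
counts in the hundreds suffice for the high-contrast phantoms used here.
The default desk-scale patch is 64×48×32 with stride 32×24×16; the
full-scale 128×96×64 / 32×24×16 configuration remains available through
`UNetConfig`. Problem sizes in the shipped tests — six 64³ training
phantoms, 200 one-patch epochs, base 16 channels — were chosen as the
smallest configuration at which vessel Dice comfortably exceeds 0.8 on
training cases and 0.6 on held-out phantoms.

Augmentation: elastic deformation (Gaussian-smoothed random displacement
field, spline order 3 for the image, nearest-neighbour for labels),
random flips, 90° rotations (restricted to equal-extent axis pairs so
patch shape is preserved), ±15° rotations, random contrast, Gaussian and
Poisson noise. Geometric transforms are applied identically to image and
label; intensity transforms to the image only.

Inference: sliding window over the stride grid with the final origin
clamped to the boundary, averaging softmax probabilities over overlaps,
then per-voxel argmax (ties break to the lowest class index). Volumes
smaller than the patch are zero-padded symmetrically and predictions
cropped back. Missing spacing metadata in NIfTI inputs triggers a warning
and a 1 mm isotropic assumption.

Cross-validation: stratified k-fold (default k = 3) by group label,
seeded and deterministic; strata smaller than k fall back to an
unstratified partition with a warning. The organ masks can be learned by
the same network with 5 classes (the default in the synthetic pipeline
trains 5 classes) or supplied as ground truth where vessel metrics should
isolate vessel error.

## Statistics layer

Group comparisons use the Kruskal–Wallis test (tie-corrected, chi-square
p) followed by pairwise two-sided Mann–Whitney U tests with Bonferroni
correction, `p_corr = min(1, 3·p_raw)` for the three-group design. The
U test uses the normal approximation with tie and continuity correction,
switching to exact enumeration automatically when both samples are ≤ 8
and tie-free (which doubles as an oracle mode in the tests). All-identical
data yield H = 0, p = 1 rather than an error. Percent decreases between
group medians are `100·(ref − new)/ref`, rounded to one decimal.

Medians and quartiles use linear interpolation (the "type 7" convention).
Spearman correlations use midranks with a t-approximation p-value, no
multiplicity correction, pairwise-complete over missing biomarkers, and
are reported for the whole CLD cohort and the two CLD subgroups.

Staging: ACLD iff FIB-4 ≥ 1.75 (cutoff closed on the ACLD side, chosen
for determinism since no inequality direction is published) and/or a
decompensation history; FIB-4 risk categories are [0, 1.3) low,
[1.3, 2.67] intermediate (boundaries inclusive, matching the printed
"1.3–2.67"), (2.67, ∞) high. Subgroup analyses apply the same machinery
to (non-ACLD, compensated ACLD, decompensated ACLD) and the FIB-4
categories; empty subgroups mark their comparisons undefined without
aborting the run.

## Pipeline

One global seed fans out to per-stage seeds via `numpy.random
.SeedSequence` spawn keys, so stages can be rerun independently yet
reproducibly. Each stage owns a subdirectory with stable file names;
outputs are checksummed into a JSON manifest keyed by the config hash;
completed stages are skipped on rerun (idempotence) and a missing
upstream artifact raises an error naming the stage to rerun. Volumes are
NIfTI with spacing in the header; the cohort and all metric tables are
CSV; configs YAML.

## Known limitations

- Phantom vasculature is geometrically simple (no real hepatic branching
  topology, no vessel-wall contrast, no partial-volume modelling beyond
  the voxel grid); Dice levels on phantoms say nothing quantitative about
  patient MRI.
- The copula is single-factor: it reproduces sign structure and rough
  magnitude, not the full published correlation matrix.
- The NumPy U-Net is single-device and deliberately small; the full
  128×96×64 configuration trains slowly on one CPU.
- Construction tolerance degrades on grids coarser than ~32³ at ~4.5 mm
  because single voxels exceed 1 % of a vessel system's volume.
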