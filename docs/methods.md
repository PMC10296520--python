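# Methods

`dcefoci` implements, end to end, the analysis used to re-classify small
enhancing foci on the *prior* breast MRI of BRCA pathogenic-variant carriers:
dynamic contrast-enhanced (DCE) subtraction imaging, kinetic curve typing, a
dual-resolution patch CNN, and leave-one-out evaluation — exercised on a
synthetic longitudinal cohort generator that emulates the structure of such a
surveillance study. This note records the model, the generator's assumptions,
the numerical choices, and what the synthetic experiments do and do not show.

## The clinical analysis being modeled

Each subject contributes a pair of scans roughly a year apart. On the later
scan a cancer is diagnosed (or the subject remains cancer-free); the question
is whether the corresponding region on the *earlier* scan — typically a
sub-centimeter enhancing focus that radiologists read as benign — can be
classified correctly by a learned model.

A DCE series is one pre-contrast volume plus four post-contrast volumes
(nominal centers 1:25, 3:25, 5:25 and 7:35 min after injection). The working
image is the subtraction of the pre-contrast from the 2nd post-contrast
volume. Lesions are annotated on their central axial slice, and two
percent-change features summarize the ROI-mean signal SE:

    initial enhancement [%] = 100 * (SE_post1 - SE_pre) / SE_pre
    delayed phase [%]       = 100 * (SE_post4 - SE_post1) / SE_post1

binned as initial slow (< 50%) / medium (50–100%) / fast (> 100%) and delayed
washout (< -10%) / plateau (±10%) / persistent (> +10%). We read the interval
wordings as closed: 50, 100 and ±10 belong to medium and plateau
respectively. Divisions are guarded by an epsilon of 1e-6 signal units; the
generator never emits zero baselines, so the guard fires only on malformed
input. Reported percentages are rounded to one decimal; reported
sensitivity/specificity percentages are rounded one-decimal **half-up**
(21/32 prints as 65.6).

## Synthetic cohort generator

The generator writes NIfTI volumes, 2-D central-slice masks, and an RFC-4180
manifest CSV. It emulates the study design, not MR physics: volumes are
signal-enhancement images built directly from four components.

1. **Tissue baseline** — a flat 100 signal units in every frame.
2. **Background parenchymal enhancement (BPE)** — a smooth random field
   (Gaussian-filtered white noise, correlation lengths ~8 mm in-plane, ~6 mm
   through-plane), rectified to be nonnegative, scaled to 12 signal units
   (standard deviation) for minimal–mild BPE and 2.5x that for
   moderate–marked, and ramped linearly with acquisition time so it behaves
   like slow persistent enhancement. Two BPE levels are drawn with
   probabilities (0.67, 0.33), the pooled frequency across groups.
3. **Lesions** — spheres (focus/mass morphology) or in-plane capsule segments
   (non-mass), lightly Gaussian-blurred; the annotation mask is the 0.5 level
   set on the central slice. The lesion's voxel time courses are scaled so
   the ROI mean over that mask equals `B * r_k` *exactly* at every frame,
   where `B` is the lesion's baseline and `r_k` the per-frame ratio implied
   by the subject's kinetic targets (piecewise linear in time between the 1st
   and 4th post-contrast points). The BPE field is zeroed on the lesion's
   soft support so it cannot contaminate the ROI mean. Consequently, at zero
   noise the kinetic module recovers the generating class for 100% of
   subjects by construction — this is the key testability property.
4. **Noise** — additive i.i.d. Gaussian, default sd 5 signal units (SNR 20
   against the tissue baseline), drawn per voxel and frame.

Kinetic classes are drawn per subject from a 3x3 (initial x delayed) simplex
per group, built as the outer product of the study's reported prior-scan
marginals (cancer: slow/medium/fast = 8/13/11 of 32, persistent/plateau/
washout = 23/8/1; cancer-free: 24/15/14 and 45/7/1 of 53). The same class is
reused for the later visit, consistent with the reported stability of kinetic
characteristics across consecutive scans. Within a category, the target
percentage is drawn uniformly from a range that stays several points clear of
the 50/100/±10 boundaries (e.g. plateau targets span ±6.5%), so that
ROI-mean noise flips the recovered class only rarely: with the default noise
and typical mask sizes the percentage error has sd well under 2 points,
giving ≥ 95% class recovery (verified by the acceptance checks).

Diameters are drawn from truncated normals whose *truncated* mean equals the
target exactly (prior cancer lesions 6.1 mm, sd 4.2, range 1.5–17; benign
foci 7.4 mm, sd 4.2, range 1.7–27.3; tumors without a prior abnormality
7.8 mm, sd 4.0): the location parameter is solved numerically so truncation
does not bias the mean. Lesion centers are continuous in-plane but snap to a
slice center through-plane, so the annotated central slice carries the true
equator; without this the mask-derived diameter would be biased low by slice
digitization. Residual in-plane digitization bias is about -0.25 mm.

Morphology labels are drawn from the reported per-group marginals and govern
only the rendered shape. We deliberately do **not** enforce the BI-RADS
"focus < 5 mm" convention when sampling, because the reported morphology
marginals (59% focus) and the diameter distribution (mean 6.1, sd 4.2) are
not jointly consistent with a hard 5-mm cut; labels and sizes are treated as
independent marginals. The cancer-free morphology counts as reported
(12/17/25) total 54 for 53 subjects; they are normalized to a simplex.

Growth between visits follows volume-doubling kinetics: diameter
`d * 2^(days / (3 * Td))` with Td = 46 d (BRCA1) or 52 d (BRCA2). Note a
tension inherited from the source data: these doubling times imply a ~6x
diameter increase over the mean 367.6-day interval, while the observed sizes
(6.1 -> 10.8 mm) imply ~1.8x. The generator keeps the stated doubling times
and simply caps rendered diameters at 40% of the in-plane field of view;
no downstream quantity depends on diagnosis-scan lesion size. A single
`brca1_fraction` (default 0.736, the cancer group's share) applies
cohort-wide, since the gene only enters through the growth model.

Cancer-free subjects always receive an explicitly placed benign focus; a
prominence picker (`find_prominent_focus`, brightest connected component
above the 99.5th subtraction percentile) is provided for BPE-only workflows
but is not part of default generation. Benign foci vanish at follow-up with
probability 0.4; otherwise they are stable in size, location and morphology.
Visit-to-visit co-registration is exact by construction up to a random
in-plane translation of at most 3 voxels.

Determinism: every subject and visit draws from a `numpy` `SeedSequence`
spawned from the cohort seed, so manifests are byte-identical and volumes
bit-identical across runs.

## Patch extraction and normalization

The classifier's inputs are two patches per annotation, cut from the same
subtraction slice: a **local** patch (mask bounding box expanded 20% per
side, bilinearly resampled to 24x24) and a **context** patch (128x128 crop
at native resolution centered on the mask centroid, zero-padded at image
borders). Negative subtraction values are preserved. Before extraction the
subtraction volume is divided by a background intensity reference — its 99th
intensity percentile computed over the volume *excluding the column around
the annotated lesion* — and clipped to [-2, 2]. Excluding the lesion column
matters because the reference must describe the background: a lesion can
occupy more than 1% of a single slice or even of a reduced-resolution
volume, in which case a naive percentile lands inside the lesion and
normalizes away exactly the lesion-to-background contrast the classifier
needs. The annotation is always available at extraction time (the ROI is
marked by the reader), so this is not circular.

## Network and training

Two independent feature extractors — one per input size — each stack
[3x3 conv (same padding) -> ReLU -> 2x2 max-pool stride 2] blocks; outputs
are flattened, concatenated and fed to an MLP (one hidden layer, dropout)
ending in a 2-way softmax (binary cross-entropy in its 2-class softmax
form). Defaults: 16/32 channels for the local branch (24 -> 12 -> 6),
16/32/64/64 for the context branch (128 -> 8), 128 hidden units, dropout
0.25, Adam at 1e-4, 50 epochs, batch 16, horizontal/vertical flip
augmentation, inverse-frequency class weights (the cohort is 32 vs 53).
Only the block pattern and the two input sizes are structural; every width,
depth and schedule choice is exposed in `ModelConfig`. Pooling floors odd
sizes (a 3-px map pools to 1), and a configuration is rejected as soon as a
block would pool a 1-px map.

The branches can be pre-trained by supervised classification of a small
labeled image corpus (each image resized to both input sizes, a temporary
head on the concatenated features); the bundled default corpus is a
generator of four synthetic texture classes (blobs, stripes, checkerboards,
smooth fields), and any user-supplied labeled image set can be substituted.
After pre-training the classifier head is re-initialized. Pre-training is
off by default.

The layers are implemented directly in numpy (channels-last activations;
convolution as an im2col gather plus one BLAS GEMM, with the gather/scatter
and pooling loops compiled via numba when available). Forward/backward passes
were verified against central-difference numerical gradients. Training is
bit-reproducible given a seed; prediction runs in evaluation mode (no
dropout), so duplicated inputs yield identical outputs and argmax ties
resolve to non-cancer.

## Evaluation

The network dataset applies the study's inclusion rule: prior scans of
cancer subjects with a prior-scan abnormality (labeled cancer) plus prior
scans of all cancer-free subjects (labeled non-cancer); cancer subjects
without a prior abnormality are excluded. Leave-one-out cross-validation
trains a fresh model per fold (no warm start) with a per-fold seed derived
from the global seed; each subject is predicted exactly once. A `folds_cap`
option evaluates a stratified subsample of folds for quick runs and flags
the result approximate. Sensitivity and specificity are reported to one
decimal, half-up. A thresholded-mean baseline (per fold, the local-patch
mean cutoff and direction maximizing balanced training accuracy) serves as
an independent yardstick.

## Desk-scale configurations

Study-scale defaults (64x128x128 voxels; the full-width network at 50
epochs) are impractical for routine verification, so `dcefoci.benchmark`
pins one reduced configuration used by the test suite, the acceptance script
and the examples: 16x80x80 voxels at 2x0.66x0.66 mm (53 mm in-plane field of
view — every prior-scan lesion fits at native resolution), a 40-subject
benchmark cohort (15 cancer + 25 cancer-free), and a half-width network
(8/16 and 8/16/32/32 channels, 64 hidden units) trained 12 epochs at 1e-3 —
sized so a full leave-one-out retrains from scratch in every fold in minutes
on one CPU.

The benchmark cohort sets the **contrast-separation knob**
(`CohortParams.contrast_separation`, default off) to 100 signal units — 20x
the default noise sd. With the knob on, each visit first renders its
background (BPE + noise), measures the background's 99th subtraction
percentile, and then places every benign focus's ROI subtraction contrast
*below* that reference (20–50% of it) and every cancer lesion's *above* it
by at least the separation margin. The contrast is realized by scaling the
lesion's pre-contrast baseline, so scale invariance of the ratio features
keeps the kinetic classes exact; anchoring to the measured background makes
the margin survive background-referenced intensity normalization at any BPE
level. This makes the benchmark separable *by construction*: it
verifies the learning machinery (patches, network, optimization, LOO
bookkeeping), not clinical difficulty. With the knob off, lesion and BPE
contrasts overlap heavily and classification is genuinely hard — closer to
the clinical problem, where the reference analysis classified about two
thirds of cancerous foci correctly.

## What the synthetic experiments do not show

The generator reproduces the study's *statistical structure* (group sizes,
lesion sizes, kinetic-class frequencies, BPE prevalence, visit spacing), not
breast anatomy: no fibroglandular morphology, fat suppression, motion or
coil-profile artifacts, no inter-reader segmentation variability, and
enhancement curves are piecewise linear through five points rather than
pharmacokinetic. Passing the synthetic checks therefore validates the
pipeline's correctness and the network's capacity to learn enhancement
contrast at these scales; it says nothing about clinical sensitivity or
specificity on real MRI, which depend on confounders the generator
deliberately omits.

## Known limitations

* One 2-D central slice per lesion (as in the reference analysis); no 3-D
  patches.
* The numpy/numba network is CPU-sized: fine for ~10^2-subject cohorts and
  the default architecture, not for large-scale training.
* `measure_diameter` is the max Feret over boundary-pixel centers; it
  under-reads continuous diameters by a fraction of a pixel.
* The growth model and the reported size pair cannot both hold (see above);
  we follow the stated doubling times.
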