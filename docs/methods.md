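# Methods

`cftpet` implements a computer-aided differential-diagnosis pipeline for
parkinsonian disorders (Parkinson's disease, PD; multiple system atrophy,
MSA; progressive supranuclear palsy, PSP) from dopamine-transporter (DAT)
PET with an anatomical MRI companion, together with a synthetic phantom
generator that makes every stage testable without any imaging data.

## Pipeline model

1. **Segmentation.** Ten ROIs are delineated on the anatomical volume:
   bilateral caudate, putamen, pallidum, midbrain, and an occipital
   reference region.  Two interchangeable backends satisfy the same
   contract: an *atlas* backend (rigid registration of a reference MRI +
   labels to the target, nearest-neighbour propagation; zero training,
   the default) and a *learned* backend — a 3-level encoder-decoder
   network with skip connections, batch normalization and a soft-Dice
   loss.  No deep-learning framework is part of the dependency set, so
   the network is implemented directly in NumPy: convolutions are
   evaluated as 27 shifted GEMM accumulations, gradients are derived by
   hand (verified against numerical differentiation to ~1e-9 relative
   error), and optimization is Adam on soft-Dice.  At the default desk
   scale (32³ voxel phantoms, 8 base channels, 10 training pairs, 20
   epochs) training takes under a minute on one CPU and reaches Dice 1.0
   on held-out phantoms.  When a supplied label map carries occipital
   labels they are accepted as ground truth (mirroring manual
   delineation of the reference region) and override the prediction.
2. **Registration.** The MRI is rigidly aligned to the PET with Mattes
   mutual information (48 bins, dense sampling for determinism), a
   multiresolution pyramid and regular-step gradient descent.  The
   pyramid never coarsens below 16 voxels per axis — coarser levels of
   small volumes create spurious MI basins.  Labels are carried onto the
   PET grid by nearest neighbour; PET intensities are never resampled, so
   features are always read on the native PET grid.  Transforms are
   stored fixed←moving in world-mm RAS with extrinsic x-y-z Euler angles.
3. **Subregioning.** Each caudate and putamen is split into three
   equal-volume subregions (anterior, middle, posterior).  k-means on
   voxel world coordinates (k = 3, 10 restarts, seeded) provides
   centroids; because k-means alone cannot guarantee equal volumes, a
   balanced greedy assignment follows: voxels in decreasing order of
   confidence (margin between best and second-best centroid distance) go
   to the nearest centroid with remaining capacity.  Capacities are
   ⌊V/3⌋ per cluster with the V mod 3 leftover slots given to the most
   anterior clusters, so sizes never differ by more than one voxel and a
   91-voxel nucleus splits 31/30/30.  Cluster naming is by mean +Y
   (anterior) coordinate, ties broken by mean +Z.  Coordinates (not
   intensities) are clustered: intensity clustering could not produce
   named anterior/middle/posterior thirds.
4. **Features.** The striatal-to-occipital ratio of subregion *s* is the
   specific binding ratio SOR_s = (mean_s − mean_occ) / mean_occ with the
   two occipital sides pooled into one reference (one denominator; a
   side-specific reference would partially cancel in the asymmetry
   index).  A `plain_ratio` switch (mean_s / mean_occ) exists because the
   binding-ratio convention, while dominant in the DAT literature, is not
   the only one in use.  Mean (not total) uptake is used: subregion
   volumes are equal by construction, so the two differ only by a factor,
   and means are independent of the scanner grid.  The asymmetry index of
   a left/right pair is AI = (SOR_high − SOR_low) / mean(SOR_L, SOR_R) ∈
   [0, 2] for nonnegative SORs; it is computed for the six
   caudate/putamen subregion pairs only (pallidum and midbrain contribute
   SOR features but no AI).  Feature sets: `striatum` (14 SORs),
   `midbrain` (2), `striatum+midbrain` (16).  The classifier consumes
   SORs only by default; `include_asymmetry` adds the six AIs.
5. **Classification.** A linear SVM with squared hinge loss (primal
   solver, deterministic), one-vs-rest for the three-class problem.
   Features are standardized with statistics from the training rows only;
   the cost parameter is chosen by inner stratified cross-validation
   (5 folds, capped by the smallest class) over a log-spaced grid
   10⁻³…10³.  Evaluation is leave-one-out cross-validation (LOOCV) with a
   structural no-leakage guarantee: the held-out subject is excluded from
   the training rows and refused in any augment pool.  Logistic-regression
   and random-forest backends sit behind the same interface for
   comparison.  Class imbalance is left unweighted by default (a
   `class_weight` switch exists).
6. **Stage strategies.** With patients split into early (ES, ≤24 months)
   and advanced (AS) stage, four training strategies are compared, all
   testing on the ES pool: (1) LOOCV over ES with the full AS pool added
   to every training fold; (2) LOOCV within ES; (3) train on all AS, test
   all ES; (4) train on a seeded AS subsample of ES size, test all ES.
7. **Importance.** Per-feature contributions of the 14 striatal SORs come
   from impurity-based random-forest importances (500 trees), averaged
   over 10 seeded fits and normalized to sum to one; a
   permutation-importance switch exists for users wary of impurity bias.
   Bilateral aggregates (7) and nucleus aggregates (caudate, putamen,
   pallidum) are exact sums, reported as half-up percentages with one
   decimal.  The value of the midbrain add-on is tested by McNemar's
   exact test (binomial on discordant pairs; the continuity-corrected χ²
   variant is available) on per-subject LOOCV correctness of the 16- vs
   14-feature models — the exact form is preferred because discordant
   counts are small at n ≈ 100.
8. **Evaluation.** Confusion matrices are stored rows = predicted,
   columns = true, class order (PD, MSA, PSP).  Per-class
   sensitivity/specificity/PPV/NPV use the one-vs-rest collapse; overall
   accuracy is trace/total; AUC is the Mann–Whitney rank statistic with
   midrank ties.  Metrics with zero denominators are flagged as
   undefined rather than raised, so degenerate runs still report.
   Display rounding is half-up to one decimal of percent.

## The phantom generator

Each subject is a pair of 64³ volumes (2 mm isotropic by default; tests
use 32³ at 4 mm) on a shared RAS grid centred on the origin, with ten
mirror-symmetric ellipsoidal regions.  The MRI has intensity
= region code × 10 + N(0, 1) — the simplest contrast a segmenter can
learn.  The PET plants, per subregion, uptake = occipital ×
(1 + SOR) + N(0, noise_sd), with the occipital region at its reference
uptake (1.0) and a low extra-striatal background (0.3).

Per subject, each of the six caudate/putamen subregion pairs draws a
bilateral level *s* from the group's Gaussian (truncated above −0.99:
tracer concentration is nonnegative) and an asymmetry index *a* from the
group's Gaussian clipped to [0, 2]; the sides get s(1 ± a/2), the higher
side assigned left or right by a fair coin (only the magnitude of
asymmetry is characterized at the group level).  When s ≤ 0.02 the sides
are left symmetric — no meaningful asymmetry is realizable around a
near-zero level — and AI = 0 is recorded.  Pallidum and midbrain draw a
single bilateral level.  The uptake gradient inside a nucleus is
piecewise-constant over the three anatomical thirds, realized with the
same balanced tripartition used at feature extraction (both sides default
to partition seed 0), so a noise-free phantom round-trips its planted
SORs and AIs exactly up to float storage.

Default group profiles carry the published cohort means/SDs for the six
subregional SORs and AIs in each of PD, MSA, PSP and normal controls.
Pallidum and midbrain levels have no published group table; the package
fixes plausible defaults (pallidum 0.40/0.55/0.45/0.90 ± ~0.3 for
PD/MSA/PSP/NC; midbrain 0.35/0.33/0.30/0.55 ± 0.25) with the midbrain
nearly group-invariant, consistent with the finding that midbrain
features contribute little to discrimination.  Default cohort
composition is 50 PD / 37 MSA / 20 PSP / 22 NC with early-stage
fractions 22.0% / 45.9% / 40.0%.  Stages are assigned by exact counts
(round(fraction × n), seeded permutation) rather than independent
Bernoulli draws so the default cohort reproduces the 36 ES / 71 AS split
the strategy definitions assume.

What the generator does **not** emulate: realistic MR tissue contrast,
partial-volume and point-spread effects, attenuation/scatter, head
motion, and within-subject correlation between subregional SORs (no such
correlation structure is published; draws are independent).  Passing
tests therefore demonstrate the correctness of the pipeline's
*machinery* — geometry, bookkeeping, statistics — not clinical-grade
performance on real images; on phantom cohorts drawn from the published
group distributions the multiclass LOOCV accuracy (~55–60%) exceeds the
1/3 chance level decisively but falls short of the ~80% reported on real
data, as expected when between-group covariance structure is unknown and
omitted.

## Numerical choices and ties

* Per-voxel class ties in segmentation break toward the lowest region
  code (argmax-first); k-means cluster naming ties break by mean +Z;
  greedy assignment iterates voxels in a stable sort order — all for
  bit-reproducibility.
* Every random draw descends from one global seed through named
  substreams, `sha256(seed:stage:subject) mod 2³¹`, so adding or removing
  a subject does not perturb the draws of any other.
* Registration short-circuits byte-identical same-grid inputs to the
  identity transform: the MI objective has a noisy gradient exactly at
  the overlap point and can walk away from a perfect start.
* Degenerate inputs fail loudly: constant volumes refuse registration,
  sub-3-voxel nuclei refuse tripartition, single-class training sets
  refuse fitting, paired volumes with mismatched affines are never
  silently reoriented.

## A note on LOOCV permutation nulls

With permuted labels and uninformative features, LOOCV accuracy of
margin classifiers is systematically *below* the nominal chance level:
leaving one subject out always makes its class the training minority,
and on null data decision scores hover near zero, so that tiny
systematic shift decides many predictions (measured ≈ 0.28–0.29 against
a 1/3 nominal level, robust to sample size).  This is a property of the
procedure, not a bug.  The chance-level calibration test therefore uses
the imbalance-insensitive configuration (logistic backend with balanced
class weights, measured within one standard error of 1/3), and the
default SVM is checked one-sidedly for the absence of *optimistic* bias,
which is what a leakage defect would produce.

## Problem sizes used in tests

Tests run phantoms at 32³ (4 mm voxels), where every region retains ≥ 8
voxels and the pipeline is exercised end-to-end in seconds.  The
registration-recovery study runs at the full 64³ (2 mm) resolution
because mutual information on 4 mm voxels cannot resolve half-millimetre
shifts.  Cohort-level statistics use 25 subjects per group for mean
recovery and the full 107 + 22 default cohort for classifier checks.
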