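# Methods

This note documents the models, the synthetic data the package tests
itself on, the numerical choices, and the limits of what the tests show.

## Parcellation pipeline

**Decomposition.** Voxel time courses are standardized per subject
(zero mean, unit population variance; constant columns are zeroed and
flagged) and subjects are concatenated along time. The dictionary-learning
objective `1/2 ||X - DA||_F^2 + lambda ||A||_1` with unit-norm temporal
atoms is minimized by batch alternation:

* *Sparse coding* — each voxel's coefficient column is an independent
  lasso problem, solved by cyclic coordinate descent over the K
  coefficients (vectorized across voxels) with an explicit KKT stopping
  rule (residual <= 1e-7 by default; the tested contract is 1e-6). Warm
  starts across alternations keep later iterations cheap.
* *Dictionary update* — block coordinate descent over atoms with
  projection onto the unit L2 ball. Atoms that land strictly inside the
  ball are rescaled to unit norm with the matching coefficient row scaled
  down, which leaves `DA` unchanged and can only lower the L1 penalty, so
  the recorded per-alternation objective is non-increasing (asserted in
  tests to 1e-9 relative). Dead atoms (zero coefficient rows) are replaced
  by the worst-reconstructed data columns, ties to the lowest voxel index.

The batch solver is the contract because its monotone objective is
testable; an online solver would converge faster on huge data but offers
no such invariant. Initial atoms are data columns picked by a farthest-
first sweep on a row-subsampled column-correlation matrix, restricted to
columns with at least 3 strong (|r| >= 0.5) neighbours so isolated noise
voxels are never picked. This is the single most important numerical
choice in the package: with random or naive initialization the alternation
routinely merges planted components.

`lambda` is not reported for this family of analyses, so the default is
calibrated by bisection on a 200-column subsample to give a mean per-voxel
support of about K/10 (at least 1); the value used is logged in the
decomposition manifest. Component signs are canonicalized so the dominant
entry of every spatial map is positive — the thresholding stage works on
positive z scores, and sign-flipped components would otherwise be
unreachable.

**Dual regression.** Ordinary least squares at both stages, no intercept
(inputs are demeaned by standardization). Regressors — group-map rows in
the spatial stage, time-course columns in the temporal stage — are scaled
to unit variance first so coefficient magnitudes are comparable across
subjects; the group t-test depends on that comparability. Rank-deficient
designs raise an error naming the collinear or zero-variance components.

**Group inference and labeling.** One-sample t per (component, voxel),
df = n-1; zero across-subject variance yields t = 0 with a warning
counter. t maps to z through matched tail probabilities computed on the
survival side (tail probabilities are clipped at 1e-300 so z stays finite
for the enormous statistics planted data produces). Two-sided p values are
pooled over all K x V tests for multiplicity control; the default is
Benjamini-Hochberg FDR with a Bonferroni option — the source analysis
names a single "Bonferroni FDR" procedure, which is contradictory, so both
are exposed and the choice is recorded in provenance. The global threshold
is applied to the FDR-surviving z values (correction precedes
thresholding). The sweep counts, per threshold, unassigned voxels
(`n_zeros`) and surplus assignments (`n_overlap = sum_v max(0, m_v - 1)`,
the total number of assignments beyond the first; a voxels-with-overlap
count is available behind a flag since the original count definition is
not stated). The default selection policy minimizes
`n_zeros + gamma * n_overlap` with gamma = 0.1, weighting unassigned
voxels ten times as heavily, which encodes the stated preference for
covering the voxel set; ties resolve to the smaller threshold, and a
manual override exists. Labels are the argmax of surviving z at or above
the threshold, ties to the lowest component index, 0 = unassigned.
Hemispheres run fully independently; label namespaces are only combined
by counting at report time.

## Evaluation

**Homogeneity.** Per parcel and subject, the leading eigenvalue of the
voxel covariance of standardized time courses over its trace. Bounded by
[1/min(T, parcel size), 1]; parcels below 2 voxels are skipped with a
warning. Summarized as mean over parcels, then over subjects.

**DCBC.** Pearson correlations of all voxel pairs per subject, averaged
across subjects afterwards (Fisher-z averaging exists behind a flag,
default off — the source gives no indication of a transform). Pairs are
classified within (same nonzero label) or between (different nonzero
labels); anything touching label 0 is excluded, as are pairs beyond the
last bin edge. Distance bins are half-open (lo, hi], default (0,3] ...
(27,30] mm. The global DCBC is a weighted sum of per-bin within-minus-
between differences; bins lacking either pair type get weight 0, the rest
are weighted by the harmonic mean of their two pair counts (uniform
weighting available) — the weighting scheme is inherited from the DCBC
literature rather than specified here, and harmonic pair-count weighting
was chosen to control the variance of sparsely populated bins. Local DCBC
applies the same machinery to the voxels of two face-adjacent (6-
connectivity) regions, with between-pairs drawn only across that boundary.
The vectorized implementation is tested bin-for-bin against an exhaustive
pair-enumeration oracle on grids up to 200 voxels.

**Connectivity contrast.** The parcel-masked group map is the single
regressor of a spatial regression (`tc = X a / (a^T a)`); correlations
with target columns are Fisher-z transformed before an unpaired two-sample
t-test (a paired mode and a raw-r mode exist as config — the transform is
standard for correlation inference, and the unpaired test mirrors the
described procedure even when both conditions come from the same
subjects). Correction reuses the parcellation module's machinery.

## Synthetic data

The generator emulates the structure the pipeline assumes, not the full
phenomenology of BOLD:

* K_true spatially compact regions grown on the lattice by farthest-first
  seeding plus nearest-seed assignment (compactness is required for
  distance-matched boundary statistics to be meaningful).
* Per-subject temporal atoms: white Gaussian series smoothed by a 5-sample
  moving average, then standardized — short-range autocorrelation without
  an HRF model. Atoms are independent across subjects; spatial loadings
  (uniform 0.8-1.2 on each region's support) are shared, with 10%
  multiplicative per-subject jitter by default.
* Noise: i.i.d. Gaussian by default, optional AR(1). One sigma per
  subject equal to mean(per-voxel signal sd)/snr, so the voxel-averaged
  signal/noise sd ratio equals the requested SNR (within 5% for V >= 100,
  tested). Unassigned voxels carry the same noise floor but no signal.
* Two-condition datasets plant seed-to-target correlations at exact
  population values `r * s + sqrt(1-r^2) * noise` per condition.

Defaults mirror the study conditions exercised by the tests: 20 subjects,
T = 200, V = 1000 per hemisphere, SNR 5-10, dictionary size equal to the
planted component count (8 for recovery tests, 32 for the two-hemisphere
parcel-count run). These are desk-scale stand-ins for the original
multi-thousand-voxel, 60-subject analyses; passing tests demonstrate that
the algorithms recover planted structure under the model's own
assumptions, not that real movie-watching BOLD satisfies those
assumptions (no HRF, no physiological noise, no spatial smoothness of
noise, volumetric lattice instead of a surface coordinate system).

## Known limitations

* No automatic selection of the dictionary size K; it is a fixed input,
  and over-segmentation shows up downstream as negative local DCBC
  boundaries rather than being prevented.
* No spatial-contiguity enforcement or island cleanup after labeling.
* The pipeline's built-in evaluation runs on the same synthetic subjects
  used for development rather than a held-out set; a separate validation
  set can be generated with a different seed and passed to the evaluation
  functions directly.
* The online/mini-batch dictionary solver common for very large data is
  not implemented; the batch path is the contract.
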