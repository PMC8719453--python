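# cerebparc

Data-driven functional parcellation of voxel-wise BOLD fMRI via a
dual-regression-like sparse representation framework, with quantitative
evaluation by functional homogeneity and the distance-controlled boundary
coefficient (DCBC), and a seed-based two-condition connectivity contrast.

## Who this is for

Researchers subdividing a brain structure (the motivating case is the
cerebellum) into fine functional regions from multi-subject fMRI without a
prior atlas. The package implements the full analysis as a tested library
plus CLI, and ships a synthetic BOLD generator with planted ground truth so
every stage of the pipeline can be validated end to end.

## The model

Standardized, temporally concatenated multi-subject data `X` (time x voxel)
is factorized by dictionary learning with an L1 sparsity penalty:

    min_{D,A}  1/2 ||X - D A||_F^2 + lambda ||A||_1,   ||d_k||_2 = 1

where the columns of `D` are temporal atoms (representative activity
patterns) and the rows of the sparse matrix `A` are group spatial maps.
Dual regression then yields subject-specific quantities: spatial regression
`TC_s = X_s A^T (A A^T)^{-1}` gives subject time courses; temporal
regression `B_s = (TC^T TC)^{-1} TC^T X_s` gives subject spatial maps. A
one-sample t-test over subjects per (component, voxel), conversion to z
scores, FDR control, and a single global z threshold produce the hard
parcellation: each voxel takes the label of the strongest surviving
component (0 = unassigned). The threshold is swept (1.6 to 3.0 in 0.1
steps) and chosen to balance unassigned voxels against multiply-assigned
voxels, preferring fewer unassigned ones.

Evaluation:

* **Homogeneity** — per parcel and subject, the eigen ratio
  `lambda_1 / sum_i lambda_i` of the parcel's time-course covariance.
* **DCBC** — mean within-region minus between-region voxel-pair Pearson
  correlation, compared only within matched spatial-distance bins
  ((0,3], ..., (27,30] mm) and aggregated with harmonic pair-count weights;
  the *local* DCBC scores one boundary from the two regions flanking it.
* **Connectivity contrast** — a parcel-masked spatial regression extracts a
  seed time course per subject and condition; Pearson correlations with
  target time courses are Fisher-z transformed and contrasted between
  conditions with a two-sample t-test plus FDR correction.

## Worked example

```python
import numpy as np
from sklearn.metrics import adjusted_rand_score
from cerebparc import (generate_geometry, generate_group_dataset,
                       pairwise_bin_correlations, global_dcbc, homogeneity_table)
from cerebparc.pipeline import parcellate_subjects

geom = generate_geometry((8, 8, 8), 2.0)                  # 512-voxel lattice
series, truth = generate_group_dataset(geom, K_true=6, n_subjects=12, T=150,
                                       snr=5.0, unassigned_fraction=0.0, seed=0)
res = parcellate_subjects(series, K=6, seed=0)
parc = res["parcellation"]
print("chosen z threshold :", res["threshold"])
print("unassigned voxels  :", int((parc.labels == 0).sum()), "of", geom.n_voxels)
print("distinct parcels   :", len(np.unique(parc.labels[parc.labels > 0])))
print("ARI vs planted     :", round(adjusted_rand_score(truth.true_labels, parc.labels), 3))
print("global DCBC        :", round(global_dcbc(pairwise_bin_correlations(series, parc, geom)), 3))
print("mean homogeneity   :", round(homogeneity_table(series, parc).summary(), 3))
```

Output:

```
chosen z threshold : 3.0
unassigned voxels  : 0 of 512
distinct parcels   : 6
ARI vs planted     : 1.0
global DCBC        : 0.949
mean homogeneity   : 0.96
```

Six compact regions were planted at SNR 5 and all six are recovered exactly
(adjusted Rand index 1.0). The strongly positive global DCBC says that
voxel pairs inside a parcel correlate far more than equally distant pairs
straddling a boundary; mean homogeneity 0.96 says the first principal
component explains 96% of each parcel's time-course variance.

The same pipeline is available from the shell:

```bash
cerebparc run-all --outdir run --seed 0
cerebparc simulate --grid-shape 8 8 8 --k-true 6 --n-subjects 12 --t 150 \
    --snr 5 --outdir sim
```

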