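"""Synthetic multi-subject BOLD data with planted spatial components.

The generator emulates the structure the parcellation pipeline assumes:
each subject's time x voxel matrix is a mixture of a small number of
temporally smooth atoms (one per functional region) with sparse,
spatially compact loadings shared across subjects, plus noise.  Region
support, loadings, atoms and the noise level are all returned as ground
truth so recovery can be scored.

A second generator plants condition-specific seed-to-target connectivity
(movie-like vs rest-like) for exercising the connectivity contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.spatial.distance import cdist

from .bold import BoldSeries
from .errors import InvalidArgumentError
from .geometry import VoxelGeometry

__all__ = [
    "SyntheticTruth",
    "generate_group_dataset",
    "generate_two_condition_dataset",
    "grow_regions",
    "smooth_random_series",
]


@dataclass
class SyntheticTruth:
    """Ground truth of a planted dataset.

    ``connectivity_plan`` rows are
    ``(seed_component, target_indices, r_condition_A, r_condition_B)``.
    """

    true_labels: np.ndarray           # (V,) ints in 0..K_true, 0 = unassigned
    true_atoms: list                  # per-subject (T, K_true) temporal atoms
    true_maps: np.ndarray             # (K_true, V) loadings
    snr: float
    seed: int
    connectivity_plan: list = field(default_factory=list)


def smooth_random_series(rng: np.random.Generator, T: int, K: int, window: int = 5) -> np.ndarray:
    """(T, K) standardized smooth series: white noise -> moving average.

    The moving-average window induces short-range autocorrelation similar
    in spirit to BOLD without committing to an HRF model.
    """
    w = rng.standard_normal((T, K))
    if window > 1:
        w = uniform_filter1d(w, size=window, axis=0, mode="nearest")
    w = w - w.mean(axis=0)
    sd = w.std(axis=0)
    sd[sd == 0] = 1.0
    return w / sd


def grow_regions(geometry: VoxelGeometry, K: int, rng: np.random.Generator) -> np.ndarray:
    """Partition the lattice into K spatially compact regions (labels 1..K).

    Farthest-first seeding followed by nearest-seed (Voronoi) assignment;
    ties break toward the lower region index.  Compactness matters: the
    distance-controlled boundary statistics are meaningless for spatially
    scattered labels.
    """
    V = geometry.n_voxels
    if K > V:
        raise InvalidArgumentError(f"cannot grow {K} regions on {V} voxels")
    coords = geometry.coords
    first = int(rng.integers(V))
    seeds = [first]
    dmin = np.linalg.norm(coords - coords[first], axis=1)
    for _ in range(K - 1):
        nxt = int(np.argmax(dmin))
        seeds.append(nxt)
        dmin = np.minimum(dmin, np.linalg.norm(coords - coords[nxt], axis=1))
    d = cdist(coords, coords[seeds])
    return np.argmin(d, axis=1).astype(np.int64) + 1


def _noise(rng, shape, ar_phi):
    e = rng.standard_normal(shape)
    if ar_phi:
        out = np.empty_like(e)
        out[0] = e[0]
        c = np.sqrt(1.0 - ar_phi**2)
        for t in range(1, shape[0]):
            out[t] = ar_phi * out[t - 1] + c * e[t]
        return out
    return e


def generate_group_dataset(
    geometry: VoxelGeometry,
    K_true: int,
    n_subjects: int,
    T: int,
    snr: float,
    overlap_fraction: float = 0.0,
    unassigned_fraction: float = 0.0,
    seed: int = 0,
    subject_jitter: float = 0.1,
    smooth_window: int = 5,
    ar_phi: Optional[float] = None,
) -> Tuple[List[BoldSeries], SyntheticTruth]:
    """Plant K_true compact components in a multi-subject dataset.

    Each subject s gets ``data = D_s @ A_s + sigma * E_s`` where the
    temporal atoms ``D_s`` are per-subject smooth random series, the
    loadings ``A_s`` are the shared sparse group maps with optional
    multiplicative per-subject jitter, and ``sigma`` is set so that the
    per-voxel signal/noise standard-deviation ratio averaged over
    signal-carrying voxels equals ``snr``.  ``snr=inf`` disables noise.

    ``overlap_fraction`` of the assigned voxels receive a secondary
    half-strength loading on another component; ``unassigned_fraction``
    of the voxels carry no signal at all (label 0).
    """
    V = geometry.n_voxels
    if K_true < 2:
        raise InvalidArgumentError("K_true must be >= 2")
    if K_true > V:
        raise InvalidArgumentError(f"K_true={K_true} exceeds V={V}")
    if n_subjects < 2:
        raise InvalidArgumentError("n_subjects must be >= 2")
    if T <= K_true:
        raise InvalidArgumentError("T must exceed K_true")
    if not (0 <= overlap_fraction < 0.5 and 0 <= unassigned_fraction < 0.5):
        raise InvalidArgumentError("overlap/unassigned fractions must be in [0, 0.5)")
    if not (np.isinf(snr) or snr > 0):
        raise InvalidArgumentError("snr must be positive (or inf)")

    rng = np.random.default_rng(seed)
    labels = grow_regions(geometry, K_true, rng)

    # drop a fraction of voxels to 'unassigned', keeping >= 2 voxels per region
    n_drop = int(np.floor(unassigned_fraction * V))
    if n_drop:
        order = rng.permutation(V)
        counts = np.bincount(labels, minlength=K_true + 1)
        dropped = 0
        for v in order:
            if dropped == n_drop:
                break
            lab = labels[v]
            if counts[lab] > 2:
                labels[v] = 0
                counts[lab] -= 1
                dropped += 1

    A_true = np.zeros((K_true, V))
    assigned = labels > 0
    A_true[labels[assigned] - 1, np.flatnonzero(assigned)] = rng.uniform(
        0.8, 1.2, size=int(assigned.sum())
    )
    n_overlap = int(round(overlap_fraction * assigned.sum()))
    if n_overlap:
        picks = rng.choice(np.flatnonzero(assigned), size=n_overlap, replace=False)
        for v in picks:
            others = [k for k in range(K_true) if k != labels[v] - 1]
            k2 = others[int(rng.integers(len(others)))]
            A_true[k2, v] = 0.5 * rng.uniform(0.8, 1.2)

    series = []
    atoms = []
    for s in range(n_subjects):
        D_s = smooth_random_series(rng, T, K_true, window=smooth_window)
        atoms.append(D_s)
        A_s = A_true.copy()
        if subject_jitter:
            A_s = A_s * (1.0 + subject_jitter * rng.standard_normal(A_s.shape))
        signal = D_s @ A_s
        if np.isinf(snr):
            data = signal
        else:
            sig_sd = signal[:, assigned].std(axis=0)
            sigma = sig_sd.mean() / snr
            data = signal + sigma * _noise(rng, (T, V), ar_phi)
        series.append(
            BoldSeries(
                subject_id=f"sub-{s:03d}",
                condition="synthetic",
                data=data,
                geometry=geometry,
            )
        )

    truth = SyntheticTruth(
        true_labels=labels,
        true_atoms=atoms,
        true_maps=A_true,
        snr=float(snr),
        seed=int(seed),
    )
    return series, truth


def generate_two_condition_dataset(
    geometry_seed_region: VoxelGeometry,
    n_cortex_targets: int,
    n_subjects: int,
    T: int,
    r_A: float,
    r_B: float,
    seed: int = 0,
    n_true_targets: Optional[int] = None,
    snr: float = 10.0,
    smooth_window: int = 5,
) -> Tuple[List[BoldSeries], List[BoldSeries], dict, SyntheticTruth]:
    """Plant condition-specific seed-to-target connectivity.

    In each condition and subject the seed region's voxels share one
    smooth time course (plus noise at ``snr``); a designated subset of
    the ``n_cortex_targets`` target columns is built as
    ``r * s + sqrt(1 - r^2) * noise`` so its population correlation with
    the seed course is ``r`` (``r_A`` in condition A, ``r_B`` in B).
    Non-target columns are independent noise.

    Returns (series_A, series_B, targets, truth) with
    ``targets = {"A": [T x M per subject], "B": [...]}``.
    """
    if not (-1.0 < r_A < 1.0 and -1.0 < r_B < 1.0):
        raise InvalidArgumentError("|r| must be < 1")
    if n_cortex_targets < 1:
        raise InvalidArgumentError("n_cortex_targets must be >= 1")
    if n_subjects < 2:
        raise InvalidArgumentError("n_subjects must be >= 2")
    rng = np.random.default_rng(seed)
    V = geometry_seed_region.n_voxels
    if n_true_targets is None:
        n_true_targets = max(1, n_cortex_targets // 5)
    n_true_targets = min(n_true_targets, n_cortex_targets)
    target_idx = np.arange(n_true_targets)

    loading = rng.uniform(0.8, 1.2, size=V)
    sigma = loading.mean() / snr if np.isfinite(snr) else 0.0

    def one_condition(cond: str, r: float):
        ser, tgt = [], []
        for s in range(n_subjects):
            seed_tc = smooth_random_series(rng, T, 1, window=smooth_window)[:, 0]
            data = np.outer(seed_tc, loading) + sigma * rng.standard_normal((T, V))
            ser.append(
                BoldSeries(
                    subject_id=f"sub-{s:03d}",
                    condition=cond,
                    data=data,
                    geometry=geometry_seed_region,
                )
            )
            M = n_cortex_targets
            noise = rng.standard_normal((T, M))
            noise = (noise - noise.mean(axis=0)) / noise.std(axis=0)
            targets = noise.copy()
            targets[:, target_idx] = (
                r * seed_tc[:, None] + np.sqrt(1.0 - r**2) * noise[:, target_idx]
            )
            tgt.append(targets)
        return ser, tgt

    series_A, targets_A = one_condition("movie", r_A)
    series_B, targets_B = one_condition("rest", r_B)

    truth = SyntheticTruth(
        true_labels=np.ones(V, dtype=np.int64),
        true_atoms=[],
        true_maps=loading[None, :],
        snr=float(snr),
        seed=int(seed),
        connectivity_plan=[(1, target_idx.copy(), float(r_A), float(r_B))],
    )
    return series_A, series_B, {"A": targets_A, "B": targets_B}, truth
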