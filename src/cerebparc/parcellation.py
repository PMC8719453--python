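"""Group inference and hard labeling of the voxel set.

Subject-specific spatial maps are aggregated with a one-sample t-test
per (component, voxel), converted to z scores, corrected for multiple
comparisons (Benjamini-Hochberg FDR by default, Bonferroni optional),
then a single global z threshold is applied to every component's
significance map.  The threshold is swept over a grid and chosen to
balance unassigned voxels against multiply-assigned voxels, weighting
unassigned more heavily.  Each voxel is labelled by the component with
the largest surviving z at or above the threshold (0 = unassigned).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dual_regression import SubjectMaps
from .errors import InvalidArgumentError
from .geometry import VoxelGeometry

__all__ = [
    "SignificanceMaps",
    "ThresholdSweep",
    "Parcellation",
    "group_t_maps",
    "t_to_z",
    "multiplicity_correct",
    "sweep_threshold",
    "choose_threshold",
    "assign_labels",
]

_TINY_P = 1e-300  # keeps z finite for arbitrarily large |t|


@dataclass
class SignificanceMaps:
    """Per-component z maps plus the multiplicity-corrected survivor mask."""

    Z: np.ndarray                 # (K, V)
    df: int
    correction: str               # 'bh-fdr' | 'bonferroni' | 'none'
    q: float
    surviving_mask: np.ndarray    # (K, V) bool

    def thresholding_view(self) -> np.ndarray:
        """Z with non-surviving entries zeroed; input to threshold/labeling."""
        return np.where(self.surviving_mask, self.Z, 0.0)


@dataclass
class ThresholdSweep:
    thresholds: np.ndarray
    n_overlap: np.ndarray
    n_zeros: np.ndarray
    chosen: Optional[float] = None
    policy: Optional[dict] = None


@dataclass
class Parcellation:
    """Hard voxel labeling: integers 0..K, 0 = unassigned."""

    labels: np.ndarray
    geometry: Optional[VoxelGeometry]
    K: int
    threshold: float
    provenance: dict = field(default_factory=dict)

    @property
    def n_assigned(self) -> int:
        return int((self.labels > 0).sum())

    def label_counts(self) -> dict:
        labs, counts = np.unique(self.labels[self.labels > 0], return_counts=True)
        return {int(l): int(c) for l, c in zip(labs, counts)}


def group_t_maps(subject_maps: List[SubjectMaps]):
    """One-sample t statistic of each map coefficient against zero.

    Voxels with zero across-subject variance get t = 0 (counted in a
    warning) rather than an undefined statistic.  Returns (T_stat, df)
    with df = n_subjects - 1.
    """
    if len(subject_maps) < 3:
        raise InvalidArgumentError("need at least 3 subjects for a group t-test")
    stack = np.stack([m.B for m in subject_maps], axis=0)   # (n, K, V)
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    degenerate = sd == 0.0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} (component, voxel) cells have zero "
            "across-subject variance; t set to 0",
            RuntimeWarning,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        T_stat = np.where(degenerate, 0.0, mean / (sd / np.sqrt(n)))
    return T_stat, n - 1


def t_to_z(T_stat: np.ndarray, df: int) -> np.ndarray:
    """Map t statistics to z scores through matched tail probabilities.

    Uses the survival function on the side away from the bulk so tiny
    tail probabilities stay accurate; sign-symmetric and monotone in t.
    """
    if df < 1:
        raise InvalidArgumentError("df must be >= 1")
    t = np.asarray(T_stat, dtype=np.float64)
    at = np.abs(t)
    sf = np.clip(stats.t.sf(at, df), _TINY_P, None)
    z = stats.norm.isf(sf)
    return np.sign(t) * z


def multiplicity_correct(
    Z: np.ndarray, df: int, q: float = 0.05, method: str = "bh-fdr"
) -> SignificanceMaps:
    """Two-sided multiplicity control pooled over all K x V tests."""
    if not (0.0 < q < 1.0):
        raise InvalidArgumentError(f"q must be in (0, 1), got {q}")
    if method not in ("bh-fdr", "bonferroni", "none"):
        raise InvalidArgumentError(f"unknown correction method {method!r}")
    Z = np.asarray(Z, dtype=np.float64)
    p = 2.0 * stats.norm.sf(np.abs(Z))
    if method == "none":
        mask = p <= q
    else:
        sm_method = "fdr_bh" if method == "bh-fdr" else "bonferroni"
        reject, *_ = multipletests(p.ravel(), alpha=q, method=sm_method)
        mask = reject.reshape(Z.shape)
    return SignificanceMaps(Z=Z, df=int(df), correction=method, q=float(q),
                            surviving_mask=mask)


def sweep_threshold(
    sig: SignificanceMaps, t_min: float = 1.6, t_max: float = 3.0, step: float = 0.1,
    overlap_count: str = "surplus",
) -> ThresholdSweep:
    """Count unassigned and multiply-assigned voxels over a threshold grid.

    For threshold theta, with m_v the number of surviving components whose
    z at voxel v is >= theta: n_zeros = #{v: m_v = 0} and
    n_overlap = sum_v max(0, m_v - 1) (total surplus assignments).
    ``overlap_count='voxels'`` counts #{v: m_v > 1} instead.
    """
    if not (t_min < t_max) or step <= 0:
        raise InvalidArgumentError("need t_min < t_max and step > 0")
    if overlap_count not in ("surplus", "voxels"):
        raise InvalidArgumentError(f"unknown overlap_count {overlap_count!r}")
    n_steps = int(round((t_max - t_min) / step))
    thresholds = np.round(t_min + step * np.arange(n_steps + 1), 10)
    thresholds = thresholds[thresholds <= t_max + 1e-12]
    Zv = sig.thresholding_view()
    n_overlap = np.empty(len(thresholds), dtype=np.int64)
    n_zeros = np.empty(len(thresholds), dtype=np.int64)
    for i, th in enumerate(thresholds):
        m = (Zv >= th).sum(axis=0)
        n_zeros[i] = int((m == 0).sum())
        if overlap_count == "surplus":
            n_overlap[i] = int(np.maximum(m - 1, 0).sum())
        else:
            n_overlap[i] = int((m > 1).sum())
    return ThresholdSweep(thresholds=thresholds, n_overlap=n_overlap, n_zeros=n_zeros)


def choose_threshold(
    sweep: ThresholdSweep, gamma: float = 0.1, manual: Optional[float] = None
) -> float:
    """Pick the threshold minimizing J = n_zeros + gamma * n_overlap.

    Unassigned voxels are weighted more heavily than surplus assignments
    (gamma < 1), matching a preference for covering the voxel set.  Ties
    resolve to the smaller threshold.  ``manual`` overrides the policy.
    """
    if len(sweep.thresholds) == 0:
        raise InvalidArgumentError("empty sweep")
    if manual is not None:
        sweep.chosen = float(manual)
        sweep.policy = {"name": "manual", "threshold": float(manual)}
        return float(manual)
    J = sweep.n_zeros + gamma * sweep.n_overlap
    idx = int(np.argmin(J))  # first minimum = smallest threshold
    sweep.chosen = float(sweep.thresholds[idx])
    sweep.policy = {"name": "balance", "gamma": float(gamma)}
    return sweep.chosen


def assign_labels(
    sig: SignificanceMaps,
    threshold: float,
    geometry: Optional[VoxelGeometry] = None,
    provenance: Optional[dict] = None,
) -> Parcellation:
    """Label each voxel by the strongest surviving component above threshold.

    label(v) = argmax_k Z_kv among surviving components with Z_kv >=
    threshold (1-based); no qualifying component -> 0.  Exact ties break
    to the lowest component index.
    """
    Zv = sig.thresholding_view()
    qualifies = Zv >= threshold
    masked = np.where(qualifies, Zv, -np.inf)
    any_q = qualifies.any(axis=0)
    labels = np.where(any_q, np.argmax(masked, axis=0) + 1, 0).astype(np.int64)
    prov = {"correction": sig.correction, "q": sig.q, "df": sig.df,
            "threshold": float(threshold)}
    if provenance:
        prov.update(provenance)
    return Parcellation(
        labels=labels,
        geometry=geometry,
        K=int(sig.Z.shape[0]),
        threshold=float(threshold),
        provenance=prov,
    )
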