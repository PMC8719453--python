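"""Parcellation quality metrics.

Two families of metrics are computed on a labelled voxel set:

* **Functional homogeneity** — per parcel and subject, the fraction of
  the parcel's time-course variance captured by the first principal
  component (the leading eigenvalue of the voxel covariance over its
  trace).

* **Distance-controlled boundary coefficient (DCBC)** — the difference
  between mean correlations of within-region and between-region voxel
  pairs, compared only among pairs at matched spatial distances (3 mm
  bins out to 30 mm by default) and aggregated over bins.  A *local*
  DCBC restricts the computation to the two regions flanking one
  specific boundary.  Positive values indicate boundaries that separate
  functionally distinct tissue.

Correlations are computed per subject and then averaged across subjects.
Unassigned voxels (label 0) are excluded from all pair statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .bold import BoldSeries
from .decomposition import standardize_series
from .errors import (
    EmptyResultError,
    InvalidArgumentError,
    UndefinedResultError,
)
from .geometry import VoxelGeometry
from .parcellation import Parcellation

__all__ = [
    "HomogeneityResult",
    "DcbcResult",
    "BoundaryTable",
    "default_bin_edges",
    "homogeneity",
    "homogeneity_table",
    "pairwise_bin_correlations",
    "global_dcbc",
    "region_adjacency",
    "local_dcbc",
    "boundary_table",
    "negative_boundary_report",
]


def default_bin_edges() -> np.ndarray:
    """(0,3], (3,6], ..., (27,30] mm."""
    return np.arange(0.0, 33.0, 3.0)[:11]


@dataclass
class HomogeneityResult:
    """Long table of per-(subject, parcel) leading-eigenvalue ratios."""

    table: pd.DataFrame   # columns: subject, parcel, size, eigen_ratio

    def summary(self) -> float:
        """Mean over parcels within subject, then over subjects."""
        return float(self.table.groupby("subject")["eigen_ratio"].mean().mean())


@dataclass
class DcbcResult:
    bin_edges: np.ndarray
    within_corr: np.ndarray      # per-bin mean within-region correlation
    between_corr: np.ndarray
    n_within_pairs: np.ndarray
    n_between_pairs: np.ndarray
    weight: np.ndarray           # 0 for bins lacking either pair type
    global_dcbc: float = np.nan


@dataclass
class BoundaryTable:
    """Per-boundary local DCBC for every pair of face-adjacent regions."""

    table: pd.DataFrame  # region_a, region_b, n_adjacent_voxel_pairs, local_dcbc


def _standardized_data(series: BoldSeries) -> np.ndarray:
    if not series.standardized:
        series = standardize_series(series)
    return series.data


def homogeneity(series: BoldSeries, parc: Parcellation) -> HomogeneityResult:
    """PCA eigen-ratio of each parcel's time courses for one subject.

    For each parcel with >= 2 voxels, the ratio lambda_1 / sum(lambda)
    of the voxel-by-voxel covariance eigenvalues; parcels with < 2
    voxels are skipped with a warning.
    """
    labels = parc.labels
    if not (labels > 0).any():
        raise InvalidArgumentError("parcellation has no assigned voxels")
    Z = _standardized_data(series)
    rows = []
    skipped = 0
    for lab in np.unique(labels[labels > 0]):
        idx = np.flatnonzero(labels == lab)
        if idx.size < 2:
            skipped += 1
            continue
        sub = Z[:, idx]
        cov = np.cov(sub, rowvar=False)
        eig = np.linalg.eigvalsh(cov)
        ratio = float(eig[-1] / eig.sum())
        rows.append((series.subject_id, int(lab), int(idx.size), ratio))
    if skipped:
        warnings.warn(f"{skipped} parcels with < 2 voxels skipped", RuntimeWarning)
    return HomogeneityResult(
        table=pd.DataFrame(rows, columns=["subject", "parcel", "size", "eigen_ratio"])
    )


def homogeneity_table(series_list: Sequence[BoldSeries], parc: Parcellation) -> HomogeneityResult:
    """Concatenated per-subject homogeneity tables."""
    tables = [homogeneity(s, parc).table for s in series_list]
    return HomogeneityResult(table=pd.concat(tables, ignore_index=True))


def _bin_index(dist: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Half-open (lo, hi] bin index; -1 or n_bins for out-of-range."""
    return np.searchsorted(edges, dist, side="left") - 1


def _binned_pair_stats(
    data_list: List[np.ndarray],
    coords: np.ndarray,
    labels: np.ndarray,
    edges: np.ndarray,
    weighting: str,
    fisher_average: bool = False,
) -> DcbcResult:
    """Core DCBC computation on an explicit voxel subset.

    ``data_list`` holds standardized T x V matrices (one per subject)
    restricted to the voxels described by ``coords`` / ``labels``.
    """
    n_bins = len(edges) - 1
    iu0, iu1 = np.triu_indices(len(labels), k=1)
    dist = pdist(coords)
    bins = _bin_index(dist, edges)
    li, lj = labels[iu0], labels[iu1]
    valid = (bins >= 0) & (bins < n_bins) & (li > 0) & (lj > 0)
    within = valid & (li == lj)
    between = valid & (li != lj)
    if not within.any() and not between.any():
        raise EmptyResultError("no qualifying voxel pairs in any distance bin")

    n_w = np.bincount(bins[within], minlength=n_bins)
    n_b = np.bincount(bins[between], minlength=n_bins)

    sum_w = np.zeros(n_bins)
    sum_b = np.zeros(n_bins)
    for Z in data_list:
        T = Z.shape[0]
        R = (Z.T @ Z) / T  # columns standardized with population std
        r = R[iu0, iu1]
        if fisher_average:
            r = np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12))
        sum_w += np.bincount(bins[within], weights=r[within], minlength=n_bins)
        sum_b += np.bincount(bins[between], weights=r[between], minlength=n_bins)
    S = len(data_list)
    with np.errstate(invalid="ignore", divide="ignore"):
        within_corr = np.where(n_w > 0, sum_w / (n_w * S), np.nan)
        between_corr = np.where(n_b > 0, sum_b / (n_b * S), np.nan)
    if fisher_average:
        within_corr = np.tanh(within_corr)
        between_corr = np.tanh(between_corr)

    eligible = (n_w > 0) & (n_b > 0)
    weight = np.zeros(n_bins)
    if eligible.any():
        if weighting == "harmonic":
            raw = (n_w * n_b / (n_w + n_b).clip(min=1)).astype(float)
        elif weighting == "uniform":
            raw = np.ones(n_bins)
        else:
            raise InvalidArgumentError(f"unknown weighting {weighting!r}")
        raw = np.where(eligible, raw, 0.0)
        weight = raw / raw.sum()

    res = DcbcResult(
        bin_edges=edges.copy(),
        within_corr=within_corr,
        between_corr=between_corr,
        n_within_pairs=n_w,
        n_between_pairs=n_b,
        weight=weight,
    )
    if eligible.any():
        res.global_dcbc = float(
            np.sum(weight[eligible] * (within_corr[eligible] - between_corr[eligible]))
        )
    return res


def pairwise_bin_correlations(
    series_list: Sequence[BoldSeries],
    parc: Parcellation,
    geometry: Optional[VoxelGeometry] = None,
    bin_edges: Optional[np.ndarray] = None,
    weighting: str = "harmonic",
    fisher_average: bool = False,
) -> DcbcResult:
    """Distance-binned within/between-region pair correlations.

    Pearson correlation of every voxel pair (per subject, then averaged
    over subjects), classified within (same nonzero label) or between
    (different nonzero labels), binned by Euclidean distance.  Pairs
    touching unassigned voxels or beyond the last bin edge are ignored.
    """
    if len(series_list) < 1:
        raise InvalidArgumentError("need at least one subject")
    geom = geometry or parc.geometry or series_list[0].geometry
    edges = np.asarray(bin_edges if bin_edges is not None else default_bin_edges(),
                       dtype=np.float64)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise InvalidArgumentError("bin edges must be increasing with >= 2 entries")
    data = [_standardized_data(s) for s in series_list]
    return _binned_pair_stats(data, geom.coords, parc.labels, edges, weighting,
                              fisher_average=fisher_average)


def global_dcbc(d: DcbcResult) -> float:
    """Weighted sum over bins of (within - between) correlation.

    Weights are proportional to the harmonic mean of the within/between
    pair counts (or uniform, per the result's construction) and sum to 1
    over bins holding both pair types.
    """
    eligible = d.weight > 0
    if not eligible.any():
        raise UndefinedResultError("no bin holds both within and between pairs")
    return float(np.sum(d.weight[eligible] *
                        (d.within_corr[eligible] - d.between_corr[eligible])))


def region_adjacency(parc: Parcellation, geometry: Optional[VoxelGeometry] = None):
    """Pairs of distinct nonzero labels sharing a lattice face.

    Returns a list of (region_a, region_b) tuples with region_a <
    region_b, each backed by at least one 6-connected voxel pair.
    """
    geom = geometry or parc.geometry
    pairs = geom.face_adjacent_pairs()
    la = parc.labels[pairs[:, 0]]
    lb = parc.labels[pairs[:, 1]]
    keep = (la > 0) & (lb > 0) & (la != lb)
    ab = np.sort(np.stack([la[keep], lb[keep]], axis=1), axis=1)
    if ab.size == 0:
        return []
    uniq = np.unique(ab, axis=0)
    return [(int(a), int(b)) for a, b in uniq]


def _adjacency_counts(parc, geom):
    pairs = geom.face_adjacent_pairs()
    la = parc.labels[pairs[:, 0]]
    lb = parc.labels[pairs[:, 1]]
    keep = (la > 0) & (lb > 0) & (la != lb)
    ab = np.sort(np.stack([la[keep], lb[keep]], axis=1), axis=1)
    uniq, counts = np.unique(ab, axis=0, return_counts=True)
    return {(int(a), int(b)): int(c) for (a, b), c in zip(uniq, counts)}


def local_dcbc(
    series_list: Sequence[BoldSeries],
    parc: Parcellation,
    geometry: Optional[VoxelGeometry],
    region_a: int,
    region_b: int,
    bin_edges: Optional[np.ndarray] = None,
    weighting: str = "harmonic",
) -> float:
    """DCBC restricted to the voxels of two face-adjacent regions.

    Within pairs come from a-a and b-b, between pairs from a-b only.
    """
    geom = geometry or parc.geometry or series_list[0].geometry
    a, b = sorted((int(region_a), int(region_b)))
    if (a, b) not in region_adjacency(parc, geom):
        raise InvalidArgumentError(f"regions {a} and {b} share no boundary")
    edges = np.asarray(bin_edges if bin_edges is not None else default_bin_edges(),
                       dtype=np.float64)
    idx = np.flatnonzero((parc.labels == a) | (parc.labels == b))
    data = [_standardized_data(s)[:, idx] for s in series_list]
    res = _binned_pair_stats(data, geom.coords[idx], parc.labels[idx], edges, weighting)
    return global_dcbc(res)


def boundary_table(
    series_list: Sequence[BoldSeries],
    parc: Parcellation,
    geometry: Optional[VoxelGeometry] = None,
    bin_edges: Optional[np.ndarray] = None,
    weighting: str = "harmonic",
) -> BoundaryTable:
    """Local DCBC for every boundary between face-adjacent regions."""
    geom = geometry or parc.geometry or series_list[0].geometry
    edges = np.asarray(bin_edges if bin_edges is not None else default_bin_edges(),
                       dtype=np.float64)
    counts = _adjacency_counts(parc, geom)
    data = [_standardized_data(s) for s in series_list]
    rows = []
    for (a, b), n_adj in sorted(counts.items()):
        idx = np.flatnonzero((parc.labels == a) | (parc.labels == b))
        sub = [Z[:, idx] for Z in data]
        try:
            res = _binned_pair_stats(sub, geom.coords[idx], parc.labels[idx],
                                     edges, weighting)
            val = global_dcbc(res)
        except (EmptyResultError, UndefinedResultError):
            val = np.nan
        rows.append((a, b, n_adj, val))
    return BoundaryTable(
        table=pd.DataFrame(
            rows, columns=["region_a", "region_b", "n_adjacent_voxel_pairs", "local_dcbc"]
        )
    )


def negative_boundary_report(bt: BoundaryTable) -> dict:
    """Proportion (4-decimal) and count of boundaries with negative local DCBC."""
    tab = bt.table.dropna(subset=["local_dcbc"])
    total = len(tab)
    if total == 0:
        raise InvalidArgumentError("boundary table holds no scored boundaries")
    n_neg = int((tab["local_dcbc"] < 0).sum())
    return {
        "n_boundaries": total,
        "n_negative": n_neg,
        "proportion_negative": round(n_neg / total, 4),
    }
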