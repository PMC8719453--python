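"""Parcel-seeded connectivity and the two-condition contrast.

For one parcel, its group spatial map is masked to the parcel's voxels
and used as the single regressor in a spatial regression of a subject's
data, giving one seed time course.  Pearson correlations between that
course and a set of target time courses form the subject's connectivity
map.  Maps from two conditions are contrasted target-by-target with a
two-sample t-test on Fisher-z-transformed correlations, followed by
multiplicity correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import IncompatibleInputError, InvalidArgumentError
from .parcellation import Parcellation

__all__ = [
    "ConnectivityMap",
    "ConditionContrast",
    "masked_seed_timecourse",
    "connectivity_map",
    "contrast_conditions",
]


@dataclass
class ConnectivityMap:
    subject_id: str
    condition: str
    parcel: int
    r: np.ndarray        # (M,) per-target Pearson correlations


@dataclass
class ConditionContrast:
    parcel: int
    t_map: np.ndarray
    df: int
    p: np.ndarray
    surviving_mask: np.ndarray
    direction: np.ndarray   # sign of t where surviving, else 0


def masked_seed_timecourse(
    X_s: np.ndarray, group_map_row: np.ndarray, parc: Parcellation, parcel_id: int
) -> np.ndarray:
    """Single-regressor spatial regression on the parcel-masked group map.

    The component's spatial map is zeroed outside the parcel's voxels;
    the returned course is ``X a / (a^T a)``.
    """
    X_s = np.asarray(X_s, dtype=np.float64)
    a = np.asarray(group_map_row, dtype=np.float64).copy()
    if a.shape[0] != X_s.shape[1]:
        raise IncompatibleInputError(
            f"map has {a.shape[0]} voxels but data has {X_s.shape[1]}"
        )
    inside = parc.labels == parcel_id
    if not inside.any():
        raise InvalidArgumentError(f"parcel {parcel_id} is empty")
    a[~inside] = 0.0
    denom = float(a @ a)
    if denom <= 0.0:
        raise InvalidArgumentError(
            f"group map is zero on every voxel of parcel {parcel_id}"
        )
    return (X_s @ a) / denom


def connectivity_map(
    tc: np.ndarray,
    targets: np.ndarray,
    subject_id: str = "",
    condition: str = "",
    parcel: int = 0,
) -> ConnectivityMap:
    """Pearson correlation of the seed course with each target column.

    Constant target columns get r = 0 with a warning.
    """
    tc = np.asarray(tc, dtype=np.float64).ravel()
    targets = np.asarray(targets, dtype=np.float64)
    if targets.ndim != 2 or targets.shape[1] < 1:
        raise InvalidArgumentError("targets must be a T x M matrix with M >= 1")
    if targets.shape[0] != tc.shape[0]:
        raise IncompatibleInputError(
            f"seed course has {tc.shape[0]} samples but targets have {targets.shape[0]}"
        )
    zc = tc - tc.mean()
    sd_c = zc.std()
    if sd_c < 1e-12:
        raise InvalidArgumentError("seed time course is constant")
    Yt = targets - targets.mean(axis=0)
    sd_t = Yt.std(axis=0)
    constant = sd_t < 1e-12
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant target columns; r set to 0",
            RuntimeWarning,
        )
    sd_safe = np.where(constant, 1.0, sd_t)
    r = (zc @ Yt) / (tc.shape[0] * sd_c * sd_safe)
    r[constant] = 0.0
    r = np.clip(r, -1.0, 1.0)
    return ConnectivityMap(subject_id=subject_id, condition=condition,
                           parcel=int(parcel), r=r)


def contrast_conditions(
    maps_A: List[ConnectivityMap],
    maps_B: List[ConnectivityMap],
    q: float = 0.05,
    method: str = "bh-fdr",
    transform: str = "fisher",
    paired: bool = False,
) -> ConditionContrast:
    """Per-target two-sample t-test between conditions.

    Correlations are Fisher-z transformed by default (``transform='r'``
    tests raw correlations); p values are two-sided and pooled over
    targets for multiplicity correction.
    """
    if len(maps_A) < 3 or len(maps_B) < 3:
        raise InvalidArgumentError("need at least 3 subjects per condition")
    RA = np.stack([m.r for m in maps_A], axis=0)
    RB = np.stack([m.r for m in maps_B], axis=0)
    if RA.shape[1] != RB.shape[1]:
        raise IncompatibleInputError("conditions cover different target sets")
    if transform == "fisher":
        RA = np.arctanh(np.clip(RA, -1 + 1e-12, 1 - 1e-12))
        RB = np.arctanh(np.clip(RB, -1 + 1e-12, 1 - 1e-12))
    elif transform != "r":
        raise InvalidArgumentError(f"unknown transform {transform!r}")
    if paired:
        if RA.shape[0] != RB.shape[0]:
            raise InvalidArgumentError("paired test requires equal subject counts")
        t, p = stats.ttest_rel(RA, RB, axis=0)
        df = RA.shape[0] - 1
    else:
        t, p = stats.ttest_ind(RA, RB, axis=0)
        df = RA.shape[0] + RB.shape[0] - 2
    if not (0.0 < q < 1.0):
        raise InvalidArgumentError(f"q must be in (0, 1), got {q}")
    sm_method = {"bh-fdr": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if sm_method is None:
        raise InvalidArgumentError(f"unknown correction method {method!r}")
    reject, *_ = multipletests(p, alpha=q, method=sm_method)
    direction = np.where(reject, np.sign(t), 0.0)
    return ConditionContrast(
        parcel=maps_A[0].parcel,
        t_map=np.asarray(t),
        df=int(df),
        p=np.asarray(p),
        surviving_mask=reject,
        direction=direction,
    )
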