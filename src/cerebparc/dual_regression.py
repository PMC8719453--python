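"""Dual regression: group spatial maps -> subject time courses -> subject maps.

Stage 1 (spatial regression) regresses each time point's voxel pattern on
the K group maps, yielding a T x K matrix of subject-specific time
courses.  Stage 2 (temporal regression) regresses each voxel's time
course on those K time courses, yielding a K x V subject-specific map.
Regressors are variance-normalized at both stages so coefficient scales
are comparable across subjects, which the group t-test downstream relies
on.  No intercept: inputs are demeaned by standardization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import RankDeficiencyError, InvalidArgumentError

__all__ = ["SubjectTimecourses", "SubjectMaps", "spatial_regression", "temporal_regression"]


@dataclass
class SubjectTimecourses:
    subject_id: str
    TC: np.ndarray                # (T_s, K)
    source: str = "full-map"      # or "masked-map"


@dataclass
class SubjectMaps:
    subject_id: str
    B: np.ndarray                 # (K, V)


def _normalize_rows(A: np.ndarray, what: str) -> np.ndarray:
    sd = A.std(axis=1)
    bad = np.flatnonzero(sd < 1e-12)
    if bad.size:
        raise RankDeficiencyError(
            f"{what} {bad.tolist()} have (near-)zero variance", components=bad
        )
    return A / sd[:, None]


def spatial_regression(X_s: np.ndarray, A: np.ndarray, subject_id: str = "") -> SubjectTimecourses:
    """OLS of each time point's voxel pattern on the K group maps.

    ``TC = X_s A_n^T (A_n A_n^T)^{-1}`` with variance-normalized map rows.
    """
    X_s = np.asarray(X_s, dtype=np.float64)
    A = np.asarray(A, dtype=np.float64)
    if X_s.shape[1] != A.shape[1]:
        raise InvalidArgumentError(
            f"X has {X_s.shape[1]} voxels but maps have {A.shape[1]}"
        )
    An = _normalize_rows(A, "group map rows")
    gram = An @ An.T
    rank = np.linalg.matrix_rank(gram)
    if rank < A.shape[0]:
        corr = np.corrcoef(An)
        np.fill_diagonal(corr, 0.0)
        ii, jj = np.nonzero(np.abs(corr) > 1.0 - 1e-10)
        dup = sorted({int(k) for k in np.concatenate([ii, jj])}) if ii.size else []
        raise RankDeficiencyError(
            f"group maps are rank deficient (rank {rank} < K {A.shape[0]}); "
            f"collinear components: {dup}",
            components=dup,
        )
    TC = np.linalg.solve(gram, An @ X_s.T).T
    return SubjectTimecourses(subject_id=subject_id, TC=TC, source="full-map")


def temporal_regression(X_s: np.ndarray, TC: np.ndarray, subject_id: str = "") -> SubjectMaps:
    """Per-voxel multiple regression on the K subject time courses.

    ``B = (TC_n^T TC_n)^{-1} TC_n^T X_s`` with variance-normalized
    time-course columns.
    """
    X_s = np.asarray(X_s, dtype=np.float64)
    TC = np.asarray(TC, dtype=np.float64)
    if X_s.shape[0] != TC.shape[0]:
        raise InvalidArgumentError(
            f"X has {X_s.shape[0]} time points but TC has {TC.shape[0]}"
        )
    TCn = _normalize_rows(TC.T, "time-course columns").T
    gram = TCn.T @ TCn
    rank = np.linalg.matrix_rank(gram)
    if rank < TC.shape[1]:
        raise RankDeficiencyError(
            f"subject time courses are rank deficient (rank {rank} < K {TC.shape[1]})"
        )
    B = np.linalg.solve(gram, TCn.T @ X_s)
    return SubjectMaps(subject_id=subject_id, B=B)
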