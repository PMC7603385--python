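"""Functional-connectivity features from ROI time series.

Every subject's T x R time-series matrix is reduced to an R x R Pearson
correlation ("connectivity") matrix and then to the vector of its
R(R-1)/2 upper-triangle entries.  All downstream feature indices refer
to that vector, so the index <-> region-pair convention is fixed here:
row-major order over 0-based indices, (0,1), (0,2), ..., (0,R-1),
(1,2), ...  This matches ``numpy.triu_indices(R, k=1)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .synthetic import SubjectRecord

__all__ = [
    "FeatureIndexMap",
    "ConnectivityFeatures",
    "pearson_correlation",
    "connectivity_matrix",
    "vectorize_upper",
    "devectorize_upper",
    "feature_to_pair",
    "pair_to_feature",
    "n_features",
    "build_design_matrix",
    "load_cohort",
    "save_design_matrix",
]


def n_features(R: int) -> int:
    """Number of unique region pairs, R(R-1)/2."""
    if R < 2:
        raise ValueError(f"need at least 2 regions, got R={R}")
    return R * (R - 1) // 2


@dataclass(frozen=True)
class FeatureIndexMap:
    """Bijection between feature indices and unordered region pairs.

    Feature ``p`` corresponds to the upper-triangle cell ``(j, k)`` with
    ``0 <= j < k < R`` taken in row-major order.
    """

    R: int

    def __post_init__(self) -> None:
        if self.R < 2:
            raise ValueError(f"need at least 2 regions, got R={self.R}")

    @property
    def n_features(self) -> int:
        return n_features(self.R)

    def pair_of(self, p: int) -> tuple[int, int]:
        return feature_to_pair(p, self.R)

    def index_of(self, j: int, k: int) -> int:
        return pair_to_feature(j, k, self.R)

    def pairs(self) -> list[tuple[int, int]]:
        rows, cols = np.triu_indices(self.R, k=1)
        return list(zip(rows.tolist(), cols.tolist()))


@dataclass
class ConnectivityFeatures:
    """One subject's connectivity matrix and its upper-triangle vector."""

    subject_id: str
    C: np.ndarray
    F: np.ndarray
    R: int


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation of two equal-length series.

    Mean-centered cross-product over the product of centered norms.
    Raises on length mismatch, short input or zero variance instead of
    returning NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1:
        raise ValueError("inputs must be 1-D")
    if x.shape[0] != y.shape[0]:
        raise ValueError(f"length mismatch: {x.shape[0]} vs {y.shape[0]}")
    if x.shape[0] < 3:
        raise ValueError("need at least 3 time points")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(np.sum(xc * xc))
    sy = np.sqrt(np.sum(yc * yc))
    if sx == 0.0 or sy == 0.0:
        raise ValueError("zero-variance input")
    r = float(np.sum(xc * yc) / (sx * sy))
    return float(np.clip(r, -1.0, 1.0))


def connectivity_matrix(record: SubjectRecord) -> ConnectivityFeatures:
    """Pairwise Pearson correlation matrix for one subject.

    Returns a symmetric R x R matrix with unit diagonal.  A region with
    zero variance is a hard error naming the offending column: silently
    propagating NaN correlations would poison every later stage.
    """
    ts = np.asarray(record.timeseries, dtype=float)
    if ts.ndim != 2:
        raise ValueError("timeseries must be a T x R matrix")
    T, R = ts.shape
    if T < 3:
        raise ValueError("need at least 3 time points")
    if R < 2:
        raise ValueError("need at least 2 regions")
    if not np.all(np.isfinite(ts)):
        raise ValueError("non-finite values in time series")
    sd = ts.std(axis=0)
    bad = np.flatnonzero(sd == 0.0)
    if bad.size:
        raise ValueError(
            f"zero-variance region(s) {bad.tolist()} for subject {record.subject_id}"
        )
    C = np.corrcoef(ts, rowvar=False)
    C = np.clip(C, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    C = (C + C.T) / 2.0
    imap = FeatureIndexMap(R)
    return ConnectivityFeatures(
        subject_id=record.subject_id, C=C, F=vectorize_upper(C, imap), R=R
    )


def vectorize_upper(C: np.ndarray, index_map: FeatureIndexMap | None = None) -> np.ndarray:
    """Upper-triangle entries of a symmetric matrix in row-major order."""
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {C.shape}")
    R = C.shape[0]
    if index_map is not None and index_map.R != R:
        raise ValueError(f"index map built for R={index_map.R}, matrix has R={R}")
    rows, cols = np.triu_indices(R, k=1)
    return C[rows, cols].copy()


def devectorize_upper(F: np.ndarray, R: int, diagonal: float = 1.0) -> np.ndarray:
    """Inverse of :func:`vectorize_upper`; fills a symmetric matrix."""
    F = np.asarray(F, dtype=float)
    if F.shape != (n_features(R),):
        raise ValueError(f"expected {n_features(R)} features for R={R}, got {F.shape}")
    C = np.full((R, R), diagonal, dtype=float)
    rows, cols = np.triu_indices(R, k=1)
    C[rows, cols] = F
    C[cols, rows] = F
    return C


def feature_to_pair(p: int, R: int) -> tuple[int, int]:
    """Region pair (j, k), j < k, of feature index ``p``.

    Closed form inversion of the row-major upper-triangle enumeration:
    feature index p = j*R - j(j+1)/2 + (k - j - 1).
    """
    n = n_features(R)
    if not 0 <= p < n:
        raise IndexError(f"feature index {p} out of range for R={R} (n={n})")
    # remaining(j) = number of features with first index >= j
    j = int((2 * R - 1 - np.sqrt((2 * R - 1) ** 2 - 8 * p)) // 2)
    # guard against float round-off at block boundaries
    while pair_to_feature(j, j + 1, R) > p:
        j -= 1
    while j + 1 < R - 1 and pair_to_feature(j + 1, j + 2, R) <= p:
        j += 1
    k = p - pair_to_feature(j, j + 1, R) + j + 1
    return j, k


def pair_to_feature(j: int, k: int, R: int) -> int:
    """Feature index of region pair (j, k); order-insensitive, j != k."""
    if j == k:
        raise ValueError("self-pairs have no feature index")
    if j > k:
        j, k = k, j
    if not (0 <= j < k < R):
        raise IndexError(f"pair ({j},{k}) out of range for R={R}")
    return j * R - j * (j + 1) // 2 + (k - j - 1)


def build_design_matrix(
    subjects: Sequence[SubjectRecord],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack per-subject feature vectors into the m x n design matrix.

    Returns ``(CONN, labels, sites)`` where row i of CONN is subject i's
    upper-triangle correlation vector, n = R(R-1)/2.
    """
    if len(subjects) == 0:
        raise ValueError("no subjects")
    Rs = {np.asarray(s.timeseries).shape[1] for s in subjects}
    if len(Rs) != 1:
        raise ValueError(f"inconsistent region counts across subjects: {sorted(Rs)}")
    rows = [connectivity_matrix(s).F for s in subjects]
    CONN = np.vstack(rows)
    labels = np.array([s.label for s in subjects], dtype=int)
    sites = np.array([s.site for s in subjects], dtype=object)
    return CONN, labels, sites


def load_cohort(directory: str | Path, header: bool = False) -> list[SubjectRecord]:
    """Read a cohort written by :func:`tsfs.synthetic.write_cohort`."""
    directory = Path(directory)
    pheno = pd.read_csv(directory / "phenotype.csv", dtype={"subject_id": str, "site": str})
    subjects = []
    for row in pheno.itertuples(index=False):
        ts = pd.read_csv(
            directory / f"{row.subject_id}.csv", header=0 if header else None
        ).to_numpy(dtype=float)
        subjects.append(
            SubjectRecord(
                subject_id=str(row.subject_id),
                site=str(row.site),
                label=int(row.label),
                timeseries=ts,
            )
        )
    return subjects


def save_design_matrix(
    CONN: np.ndarray,
    labels: np.ndarray,
    sites: np.ndarray,
    R: int,
    path: str | Path,
) -> None:
    """Write the design matrix as CSV plus a sidecar JSON with the index convention."""
    path = Path(path)
    df = pd.DataFrame(CONN, columns=[f"f{p}" for p in range(CONN.shape[1])])
    df.insert(0, "label", labels)
    df.insert(0, "site", sites)
    df.to_csv(path, index=False)
    sidecar = {
        "R": int(R),
        "n_features": int(CONN.shape[1]),
        "index_order": "row-major upper triangle, 0-based: (0,1),(0,2),...,(1,2),...",
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
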