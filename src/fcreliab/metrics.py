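"""Test-retest reliability statistics for FC matrices.

Four estimators are provided, all operating on a complete subject x scan
crossing of FC matrices from ONE acquisition condition:

* ``edgewise_icc`` / ``mean_icc`` — univariate ICC(2,1) (two-way
  random-effects, absolute agreement, single measurement) per edge,
  averaged parcels-then-vertices to one ROI value.
* ``i2c2`` — image intraclass correlation, the multivariate
  generalisation ``1 - trace(Ku)/trace(Ko)`` where Ko is total and Ku
  within-subject variability summed over all edges.
* ``discriminability`` — fraction of anchor comparisons in which the
  between-subject distance exceeds the within-subject distance (ties
  half credit); a lower bound on subsequent classification accuracy.
* ``fingerprinting`` — fraction of subjects whose repeat scan is
  strictly the nearest neighbour of their first scan (and vice versa).

Distances are Euclidean between vectorised FC matrices with a shared
NaN mask, optionally on the Fisher-z scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import ValidationError
from .pipeline import FCMatrix, shared_nan_mask, vectorize_fc

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Pairwise Euclidean distances between scans of one condition."""

    values: np.ndarray
    index: list[tuple[str, int]]  # (subject_id, scan_index), grouped by subject
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        M = len(self.index)
        if self.values.shape != (M, M):
            raise ValidationError("distance matrix shape must match its index")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValidationError("distance matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValidationError("distance matrix diagonal must be zero")
        if self.values.min() < 0:
            raise ValidationError("distances must be non-negative")
        counts: dict[str, int] = {}
        for sid, _ in self.index:
            counts[sid] = counts.get(sid, 0) + 1
        if len(set(counts.values())) > 1:
            raise ValidationError("every subject needs the same number of scans")
        self._n_scans = next(iter(counts.values()))
        self._subjects = sorted(counts)

    @property
    def subjects(self) -> list[str]:
        return self._subjects

    @property
    def n_scans(self) -> int:
        return self._n_scans

    def rows_of(self, subject: str) -> np.ndarray:
        return np.array([i for i, (s, _) in enumerate(self.index) if s == subject])


@dataclass
class IccComponents:
    """Two-way ANOVA mean squares behind an ICC(2,1) value."""

    MSR: float
    MSC: float
    MSE: float
    k: int
    n: int


@dataclass
class I2c2Components:
    trace_Ko: float
    trace_Ku: float
    J: int


@dataclass
class ReliabilityEstimate:
    measure: str
    value: float
    roi: str
    condition: str
    n_subjects: int
    n_trs: int | None = None


VALID_MEASURES = ("mean_icc", "i2c2", "discr", "fingerprint")


def _stack(
    fcs: Mapping[tuple[str, int], FCMatrix]
) -> tuple[list[str], list[int], np.ndarray, np.ndarray]:
    """Order scans (subject-major), check the crossing, return keys and shapes."""
    if not fcs:
        raise ValidationError("empty FC matrix set")
    subjects = sorted({s for s, _ in fcs})
    scan_idx = sorted({j for _, j in fcs})
    shape = next(iter(fcs.values())).shape
    for (s, j), fc in fcs.items():
        if fc.shape != shape:
            raise ValidationError(
                f"FC matrix for ({s}, scan {j}) has shape {fc.shape}, expected {shape}"
            )
    missing = [(s, j) for s in subjects for j in scan_idx if (s, j) not in fcs]
    if missing:
        raise ValidationError(f"incomplete subject x scan crossing; missing {missing}")
    return subjects, scan_idx, np.array(shape), shape


def fc_data_array(
    fcs: Mapping[tuple[str, int], FCMatrix],
    fisher_z: bool = False,
) -> tuple[np.ndarray, list[str], list[int], np.ndarray]:
    """(n_subjects, n_scans, n_edges) array over the shared-mask edges."""
    subjects, scan_idx, _, _ = _stack(fcs)
    mask = shared_nan_mask(fcs.values())
    n_dropped = int((~mask).sum())
    if n_dropped:
        logger.info("dropping %d edge(s) NaN in at least one scan", n_dropped)
    rows = [
        [vectorize_fc(fcs[(s, j)], fisher_z=fisher_z, mask=mask) for j in scan_idx]
        for s in subjects
    ]
    return np.array(rows), subjects, scan_idx, mask


def distance_matrix(
    fcs: Mapping[tuple[str, int], FCMatrix], fisher_z: bool = False
) -> DistanceMatrix:
    """Euclidean distances between all vectorised FC matrices of a condition."""
    X, subjects, scan_idx, _ = fc_data_array(fcs, fisher_z=fisher_z)
    n, k, E = X.shape
    flat = X.reshape(n * k, E)
    D = squareform(pdist(flat, metric="euclidean"))
    index = [(s, j) for s in subjects for j in scan_idx]
    return DistanceMatrix(values=D, index=index)


# ---------------------------------------------------------------------------
# ICC(2,1)


def icc_a1(X: np.ndarray) -> np.ndarray:
    """Vectorised ICC(2,1) over the trailing axis of an (n, k, E) array.

    Two-way random-effects decomposition into subject (row), measurement
    (column) and error mean squares, then
    ``(MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))``.
    Edges with zero total variance (or zero denominator) return NaN.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        X = X[:, :, None]
    n, k, _ = X.shape
    if n < 3:
        raise ValidationError("ICC(2,1) requires at least 3 subjects")
    if k < 2:
        raise ValidationError("ICC(2,1) requires at least 2 scans per subject")
    grand = X.mean(axis=(0, 1))
    row = X.mean(axis=1)
    col = X.mean(axis=0)
    SSR = k * ((row - grand) ** 2).sum(axis=0)
    SSC = n * ((col - grand) ** 2).sum(axis=0)
    resid = X - row[:, None, :] - col[None, :, :] + grand
    SSE = (resid**2).sum(axis=(0, 1))
    MSR = SSR / (n - 1)
    MSC = SSC / (k - 1)
    MSE = SSE / ((n - 1) * (k - 1))
    denom = MSR + (k - 1) * MSE + (k / n) * (MSC - MSE)
    total = SSR + SSC + SSE
    with np.errstate(invalid="ignore", divide="ignore"):
        icc = (MSR - MSE) / denom
    icc = np.where((total == 0) | (denom == 0), np.nan, icc)
    return icc


def icc_components(table: np.ndarray) -> IccComponents:
    """ANOVA mean squares for a single n x k table."""
    table = np.asarray(table, dtype=float)
    n, k = table.shape
    grand = table.mean()
    MSR = k * ((table.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    MSC = n * ((table.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    resid = table - table.mean(axis=1, keepdims=True) - table.mean(axis=0) + grand
    MSE = (resid**2).sum() / ((n - 1) * (k - 1))
    return IccComponents(MSR=MSR, MSC=MSC, MSE=MSE, k=k, n=n)


def edgewise_icc(
    fcs: Mapping[tuple[str, int], FCMatrix], fisher_z: bool = False
) -> np.ndarray:
    """ICC(2,1) of every FC edge, returned on the vertices x parcels grid.

    Edges dropped by the shared NaN mask (and zero-variance edges) are NaN.
    """
    X, _, _, mask = fc_data_array(fcs, fisher_z=fisher_z)
    shape = next(iter(fcs.values())).shape
    out = np.full(shape[0] * shape[1], np.nan)
    out[mask] = icc_a1(X)
    return out.reshape(shape)


def mean_icc(icc_matrix: np.ndarray) -> tuple[np.ndarray, float]:
    """Average parcels-per-vertex, then vertices, ignoring NaN edges."""
    icc_matrix = np.asarray(icc_matrix, dtype=float)
    if icc_matrix.size == 0:
        raise ValidationError("empty ICC matrix")
    n_nan = int(np.isnan(icc_matrix).sum())
    if n_nan:
        logger.info("mean_icc ignoring %d NaN edge(s)", n_nan)
    all_nan_rows = np.all(np.isnan(icc_matrix), axis=1)
    if all_nan_rows.any():
        logger.warning("%d vertex row(s) are all-NaN", int(all_nan_rows.sum()))
    import warnings as _warnings

    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        per_vertex = np.nanmean(icc_matrix, axis=1)
        roi_mean = float(np.nanmean(per_vertex))
    return per_vertex, roi_mean


_ICC_BINS = (
    (0.2, "poor"),
    (0.4, "fair"),
    (0.6, "moderate"),
    (0.8, "good"),
    (math.inf, "excellent"),
)


def classify_icc(value: float) -> str:
    """Conventional ICC quality label (half-open bins, boundaries upward)."""
    if not np.isfinite(value):
        return "undefined"
    for upper, label in _ICC_BINS:
        if value < upper:
            return label
    return "excellent"


# ---------------------------------------------------------------------------
# I2C2


def i2c2_components(X: np.ndarray) -> I2c2Components:
    """Total and within-subject variability traces of an (n, J, V) array."""
    X = np.asarray(X, dtype=float)
    n, J, _ = X.shape
    if J < 2:
        raise ValidationError("I2C2 requires at least 2 scans per subject")
    grand = X.mean(axis=(0, 1))
    subj = X.mean(axis=1)
    trace_Ko = ((X - grand) ** 2).sum() / (n * J - 1)
    trace_Ku = ((X - subj[:, None, :]) ** 2).sum() / (n * (J - 1))
    return I2c2Components(trace_Ko=float(trace_Ko), trace_Ku=float(trace_Ku), J=J)


def i2c2(fcs: Mapping[tuple[str, int], FCMatrix], fisher_z: bool = False) -> float:
    """Image intraclass correlation: 1 - trace(Ku)/trace(Ko).

    Can be negative in noise-dominated data; equals 1 exactly when every
    subject's scans are identical.
    """
    X, _, _, _ = fc_data_array(fcs, fisher_z=fisher_z)
    comp = i2c2_components(X)
    if comp.trace_Ko == 0:
        raise ValidationError("degenerate data: total variability trace is zero")
    return 1.0 - comp.trace_Ku / comp.trace_Ko


def i2c2_from_squared_distances(D2: np.ndarray, groups: Sequence[int]) -> float:
    """I2C2 computed purely from pairwise squared distances.

    Uses the identity sum_a ||x_a - xbar||^2 = sum_{a<b} d_ab^2 / M, and
    its per-subject analogue, so the statistic can be permuted at the
    level of the distance matrix.  `groups[a]` is the subject index of
    scan a.
    """
    D2 = np.asarray(D2, dtype=float)
    groups = np.asarray(groups)
    M = D2.shape[0]
    total_ss = D2.sum() / (2.0 * M)
    within_ss = 0.0
    df_within = 0
    for g in np.unique(groups):
        rows = np.flatnonzero(groups == g)
        J = rows.size
        within_ss += D2[np.ix_(rows, rows)].sum() / (2.0 * J)
        df_within += J - 1
    trace_Ko = total_ss / (M - 1)
    trace_Ku = within_ss / df_within
    if trace_Ko == 0:
        raise ValidationError("degenerate data: total variability trace is zero")
    return 1.0 - trace_Ku / trace_Ko


# ---------------------------------------------------------------------------
# Distance-rank measures


def _subject_blocks(d: DistanceMatrix) -> tuple[np.ndarray, np.ndarray]:
    """(n_subjects, n_scans) row-index grid, plus the subject of each row."""
    order: dict[str, list[int]] = {s: [] for s in d.subjects}
    for i, (s, _) in enumerate(d.index):
        order[s].append(i)
    rows = np.array([order[s] for s in d.subjects])
    groups = np.empty(len(d.index), dtype=int)
    for gi, s in enumerate(d.subjects):
        groups[rows[gi]] = gi
    return rows, groups


def discriminability(d: DistanceMatrix, mode: str = "cross_scan") -> float:
    """Fraction of between > within distance comparisons (ties count 1/2).

    For each subject and each ordered pair of that subject's scans
    (anchor, repeat), the within-distance d(anchor, repeat) is compared
    against the anchor's distances to other subjects' scans:

    * ``cross_scan`` — only the other subjects' scans from the repeat's
      session are compared (requires exactly 2 scans per subject);
    * ``all`` — every scan of every other subject is compared.

    Perfectly reliable data (within-distances all smaller) scores 1;
    exchangeable data scores 0.5 in expectation.
    """
    if mode not in ("cross_scan", "all"):
        raise ValidationError(f"unknown discriminability mode {mode!r}")
    if len(d.subjects) < 2:
        raise ValidationError("discriminability requires at least 2 subjects")
    rows, _ = _subject_blocks(d)
    n, k = rows.shape
    if mode == "cross_scan" and k != 2:
        raise ValidationError("cross_scan mode requires exactly 2 scans per subject")
    D = d.values
    if k == 2:
        return _discr_two_scans(D, rows, mode)
    fracs = []
    for si in range(n):
        others = np.delete(np.arange(n), si)
        for a in range(k):
            anchor = rows[si, a]
            for b in range(k):
                if b == a:
                    continue
                w = D[anchor, rows[si, b]]
                if mode == "cross_scan":
                    comp = D[anchor, rows[others, b]]
                else:
                    comp = D[anchor, rows[others].ravel()]
                fracs.append(
                    ((comp > w).sum() + 0.5 * (comp == w).sum()) / comp.size
                )
    return float(np.mean(fracs))


def _discr_two_scans(D: np.ndarray, rows: np.ndarray, mode: str) -> float:
    """Vectorised two-scans-per-subject discriminability (both modes)."""
    n = rows.shape[0]
    a1, a2 = rows[:, 0], rows[:, 1]
    w12 = D[a1, a2]  # anchor scan1 -> own scan2 (same both directions)
    fracs = []
    for anchors, w, partner_col in ((a1, w12, a2), (a2, w12, a1)):
        if mode == "cross_scan":
            comp = D[np.ix_(anchors, partner_col)]
            gt = comp > w[:, None]
            eq = comp == w[:, None]
            # the diagonal is the within-distance itself; exclude it
            per_anchor = (
                gt.sum(axis=1) + 0.5 * (eq.sum(axis=1) - 1.0)
            ) / (n - 1)
        else:
            comp = D[anchors][:, rows.ravel()]  # n x 2n, own 2 cols excluded below
            gt = comp > w[:, None]
            eq = comp == w[:, None]
            own = np.zeros((n, 2 * n), dtype=bool)
            own[np.arange(n), 2 * np.arange(n)] = True
            own[np.arange(n), 2 * np.arange(n) + 1] = True
            gt &= ~own
            eq &= ~own
            per_anchor = (gt.sum(axis=1) + 0.5 * eq.sum(axis=1)) / (2 * (n - 1))
        fracs.append(per_anchor)
    # subject-major anchor order: (s0 scan1->2, s0 scan2->1, s1 scan1->2, ...)
    return float(np.mean(np.column_stack(fracs).ravel()))


def fingerprinting(d: DistanceMatrix, direction: str = "both") -> float:
    """Nearest-neighbour identification accuracy across the two scans.

    A subject is identified in the scan1->scan2 direction when the
    distance to their own scan 2 is strictly smaller than to every other
    subject's scan 2 (any tie counts as a failure).  ``both`` averages
    the two directions.
    """
    if direction not in ("both", "forward", "backward"):
        raise ValidationError(f"unknown fingerprinting direction {direction!r}")
    rows, _ = _subject_blocks(d)
    n, k = rows.shape
    if k != 2:
        raise ValidationError("fingerprinting requires exactly 2 scans per subject")
    if n < 2:
        raise ValidationError("fingerprinting requires at least 2 subjects")
    D = d.values

    def one_way(a: int, b: int) -> float:
        cross = D[np.ix_(rows[:, a], rows[:, b])]  # n x n, diag = within
        within = np.diag(cross)
        best_other = np.min(np.where(np.eye(n, dtype=bool), np.inf, cross), axis=1)
        return float(np.mean(within < best_other))

    fwd = one_way(0, 1)
    bwd = one_way(1, 0)
    if direction == "forward":
        return fwd
    if direction == "backward":
        return bwd
    return (fwd + bwd) / 2.0


# ---------------------------------------------------------------------------
# Convenience: all four measures for one condition's FC set


def reliability_suite(
    fcs: Mapping[tuple[str, int], FCMatrix],
    roi: str,
    condition: str,
    fisher_z: bool = False,
    discr_mode: str = "cross_scan",
    fingerprint_direction: str = "both",
    n_trs: int | None = None,
) -> list[ReliabilityEstimate]:
    """Compute mean ICC, I2C2, discriminability and fingerprinting."""
    n_subjects = len({s for s, _ in fcs})
    d = distance_matrix(fcs, fisher_z=fisher_z)
    _, roi_mean = mean_icc(edgewise_icc(fcs, fisher_z=fisher_z))
    values = {
        "mean_icc": roi_mean,
        "i2c2": i2c2(fcs, fisher_z=fisher_z),
        "discr": discriminability(d, mode=discr_mode),
        "fingerprint": fingerprinting(d, direction=fingerprint_direction),
    }
    return [
        ReliabilityEstimate(
            measure=m, value=v, roi=roi, condition=condition,
            n_subjects=n_subjects, n_trs=n_trs,
        )
        for m, v in values.items()
    ]


def estimates_to_frame(estimates: Sequence[ReliabilityEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "roi": e.roi,
                "condition": e.condition,
                "measure": e.measure,
                "n_trs": e.n_trs,
                "value": e.value,
                "n_subjects": e.n_subjects,
            }
            for e in estimates
        ]
    )
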