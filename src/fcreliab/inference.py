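"""Condition comparison by nested permutation, FDR control, and drivers.

The permutation scheme respects the nesting of the design: each subject
contributes two scans per condition, and a permutation swaps the WHOLE
pair of condition-A scans with the whole pair of condition-B scans with
probability 1/2, independently per subject.  Scan pairs are never split,
so a permuted "condition" is never a mixture of states within a subject
and reliability is never measured across conditions.

For the multivariate measures (I2C2, discriminability, fingerprinting)
labels are permuted at the level of the distance matrix, which is
computed once over all scans of both conditions; for mean ICC labels are
permuted at the level of the FC matrices.  The p-value is the proportion
of permuted |difference| values at least as large as the observed
|difference| (non-strict by default; a strict rule and a +1/(B+1)
smoothed rule are available).  Families of tests are corrected with
Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .metrics import (
    DistanceMatrix,
    discriminability,
    fc_data_array,
    fingerprinting,
    i2c2_from_squared_distances,
    icc_a1,
    mean_icc,
    reliability_suite,
    estimates_to_frame,
    VALID_MEASURES,
)
from .pipeline import FCMatrix, ParcelMap, ScanRecord, compute_fc, truncate_to_trs

logger = logging.getLogger(__name__)

MULTIVARIATE_MEASURES = ("i2c2", "discr", "fingerprint")


@dataclass
class PermutationComparison:
    """One measure's observed condition difference and its permutation null."""

    measure: str
    roi: str
    observed_diff: float
    observed_values: dict[str, float]
    null_sample: np.ndarray
    n_permutations: int
    p_raw: float
    seed: int | None = None
    p_adjusted: float | None = None


@dataclass
class DurationSweepResult:
    grid: list[int]
    table: pd.DataFrame


# ---------------------------------------------------------------------------
# Label permutation


def draw_swaps(n_subjects: int, rng: np.random.Generator) -> np.ndarray:
    """Per-subject Bernoulli(1/2) condition-swap indicators."""
    return rng.random(n_subjects) < 0.5


def permute_condition_labels(
    scans: Mapping[tuple[str, str, int], object],
    rng: np.random.Generator,
    conditions: tuple[str, str] | None = None,
) -> dict[tuple[str, str, int], object]:
    """Swap each subject's full condition scan-pairs with probability 1/2.

    The data objects are untouched; only their (subject, condition,
    scan_index) keys move, and a pair's internal scan order is preserved.
    """
    conds = conditions or _infer_conditions(scans)
    subjects = sorted({k[0] for k in scans})
    scan_idx = sorted({k[2] for k in scans})
    for sid in subjects:
        for c in conds:
            idx = sorted(i for (s, cc, i) in scans if s == sid and cc == c)
            if idx != scan_idx:
                raise ValidationError(
                    f"subject {sid} lacks a complete scan pair for condition {c!r}"
                )
    swaps = draw_swaps(len(subjects), rng)
    relabeled: dict[tuple[str, str, int], object] = {}
    flip = {conds[0]: conds[1], conds[1]: conds[0]}
    for (sid, cond, j), value in scans.items():
        new_cond = flip[cond] if swaps[subjects.index(sid)] else cond
        relabeled[(sid, new_cond, j)] = value
    return relabeled


def _infer_conditions(
    scans: Mapping[tuple[str, str, int], object]
) -> tuple[str, str]:
    conds = sorted({k[1] for k in scans})
    if len(conds) != 2:
        raise ValidationError(f"expected exactly 2 conditions, found {conds}")
    return (conds[0], conds[1])


# ---------------------------------------------------------------------------
# Permutation engine


class PermutationEngine:
    """Precomputes shared structures so one dataset can serve many tests.

    The full cross-condition distance matrix (for multivariate measures)
    and the stacked FC data array (for mean ICC) are built once;
    each permutation then only re-indexes them.
    """

    def __init__(
        self,
        scans: Mapping[tuple[str, str, int], FCMatrix],
        conditions: tuple[str, str] | None = None,
        fisher_z: bool = False,
        discr_mode: str = "cross_scan",
        fingerprint_direction: str = "both",
    ):
        self.conditions = conditions or _infer_conditions(scans)
        self.fisher_z = fisher_z
        self.discr_mode = discr_mode
        self.fingerprint_direction = fingerprint_direction

        self.subjects = sorted({k[0] for k in scans})
        self.scan_idx = sorted({k[2] for k in scans})
        self.k = len(self.scan_idx)
        if self.k != 2:
            raise ValidationError(
                "the nested permutation design requires exactly 2 scans per condition"
            )
        for sid in self.subjects:
            for c in self.conditions:
                for j in self.scan_idx:
                    if (sid, c, j) not in scans:
                        raise ValidationError(
                            f"incomplete crossing: missing scan ({sid}, {c}, {j})"
                        )

        # one joint (subject, condition, scan) stacking; shared NaN mask
        joint = {
            (f"{s}||{c}", j): scans[(s, c, j)]
            for s in self.subjects
            for c in self.conditions
            for j in self.scan_idx
        }
        X, joint_subjects, _, mask = fc_data_array(joint, fisher_z=self.fisher_z)
        # joint_subjects is sorted "sub||cond"; rebuild into (n, 2, k, E)
        n, E = len(self.subjects), X.shape[-1]
        self.X = np.empty((n, 2, self.k, E))
        for si, s in enumerate(self.subjects):
            for ci, c in enumerate(self.conditions):
                self.X[si, ci] = X[joint_subjects.index(f"{s}||{c}")]
        self.mask = mask
        self.fc_shape = next(iter(scans.values())).shape

        flat = self.X.reshape(n * 2 * self.k, E)
        diff = flat[:, None, :] - flat[None, :, :]
        self.D2 = np.einsum("abe,abe->ab", diff, diff)
        np.fill_diagonal(self.D2, 0.0)
        self.D = np.sqrt(self.D2)
        # row layout: subject-major, condition, scan
        self._rows = np.arange(n * 2 * self.k).reshape(n, 2, self.k)
        self._index = [(s, j) for s in self.subjects for j in self.scan_idx]
        self._groups = np.repeat(np.arange(n), self.k)

    # -- evaluation of one measure under a swap assignment ------------------

    def _condition_rows(self, swaps: np.ndarray, cond_pos: int) -> np.ndarray:
        eff = np.where(swaps, 1 - cond_pos, cond_pos)
        return self._rows[np.arange(len(self.subjects)), eff]  # (n, k)

    def _distance_value(self, measure: str, rows: np.ndarray) -> float:
        sel = rows.ravel()
        if measure == "i2c2":
            return i2c2_from_squared_distances(
                self.D2[np.ix_(sel, sel)], self._groups
            )
        d = DistanceMatrix(values=self.D[np.ix_(sel, sel)], index=self._index)
        if measure == "discr":
            return discriminability(d, mode=self.discr_mode)
        return fingerprinting(d, direction=self.fingerprint_direction)

    def _mean_icc_value(self, rows_data: np.ndarray) -> float:
        grid = np.full(self.fc_shape[0] * self.fc_shape[1], np.nan)
        grid[self.mask] = icc_a1(rows_data)
        _, roi_mean = mean_icc(grid.reshape(self.fc_shape))
        return roi_mean

    def measure_values(self, measure: str, swaps: np.ndarray) -> tuple[float, float]:
        """(condition_a, condition_b) values of one measure under `swaps`."""
        if measure not in VALID_MEASURES:
            raise ValidationError(
                f"unknown measure {measure!r}; expected one of {VALID_MEASURES}"
            )
        if measure == "mean_icc":
            Xp = np.where(swaps[:, None, None, None], self.X[:, ::-1], self.X)
            return (
                self._mean_icc_value(Xp[:, 0]),
                self._mean_icc_value(Xp[:, 1]),
            )
        return (
            self._distance_value(measure, self._condition_rows(swaps, 0)),
            self._distance_value(measure, self._condition_rows(swaps, 1)),
        )

    def test(
        self,
        measure: str,
        n_perm: int,
        seed: int | np.random.SeedSequence = 0,
        roi: str = "roi",
        strict: bool = False,
        add_one: bool = False,
    ) -> PermutationComparison:
        """Nested permutation test of the condition difference of one measure."""
        if n_perm < 1:
            raise ValidationError("n_perm must be >= 1")
        n = len(self.subjects)
        no_swap = np.zeros(n, dtype=bool)
        va, vb = self.measure_values(measure, no_swap)
        observed = va - vb
        rng = np.random.default_rng(seed)
        null = np.empty(n_perm)
        for b in range(n_perm):
            swaps = draw_swaps(n, rng)
            pa, pb = self.measure_values(measure, swaps)
            null[b] = pa - pb
        if strict:
            count = int((np.abs(null) > np.abs(observed)).sum())
        else:
            count = int((np.abs(null) >= np.abs(observed)).sum())
        p_raw = (count + 1) / (n_perm + 1) if add_one else count / n_perm
        return PermutationComparison(
            measure=measure,
            roi=roi,
            observed_diff=float(observed),
            observed_values={self.conditions[0]: va, self.conditions[1]: vb},
            null_sample=null,
            n_permutations=n_perm,
            p_raw=float(p_raw),
            seed=seed if isinstance(seed, int) else None,
        )


def permutation_test(
    scans: Mapping[tuple[str, str, int], FCMatrix],
    measure: str,
    n_perm: int,
    seed: int | np.random.SeedSequence = 0,
    *,
    conditions: tuple[str, str] | None = None,
    roi: str = "roi",
    fisher_z: bool = False,
    discr_mode: str = "cross_scan",
    fingerprint_direction: str = "both",
    strict: bool = False,
    add_one: bool = False,
) -> PermutationComparison:
    """One-shot nested permutation test (see :class:`PermutationEngine`)."""
    engine = PermutationEngine(
        scans,
        conditions=conditions,
        fisher_z=fisher_z,
        discr_mode=discr_mode,
        fingerprint_direction=fingerprint_direction,
    )
    return engine.test(
        measure, n_perm, seed=seed, roi=roi, strict=strict, add_one=add_one
    )


# ---------------------------------------------------------------------------
# Benjamini-Hochberg FDR


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Step-up BH adjusted p-values (monotone, capped at 1, order preserved)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValidationError("bh_fdr expects a non-empty 1-D vector")
    if np.any(~np.isfinite(p)) or p.min() < 0 or p.max() > 1:
        raise ValidationError("p-values must be finite and within [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(adj, 0.0, 1.0)
    return out


# ---------------------------------------------------------------------------
# Drivers


def roi_comparison_suite(
    roi_scans: Mapping[str, Mapping[tuple[str, str, int], FCMatrix]],
    n_perm_multi: int = 5000,
    n_perm_icc: int = 500,
    seed: int = 0,
    alpha: float = 0.05,
    conditions: tuple[str, str] | None = None,
    fisher_z: bool = False,
    discr_mode: str = "cross_scan",
    fingerprint_direction: str = "both",
    strict: bool = False,
    add_one: bool = False,
) -> pd.DataFrame:
    """All four measures for every ROI, one BH family across the crossing.

    With 3 ROIs this is the 12-test family (3 ROIs x 4 measures); the
    univariate mean ICC uses its own (smaller) permutation count.
    """
    ss = np.random.SeedSequence(seed)
    children = iter(ss.spawn(len(roi_scans) * len(VALID_MEASURES)))
    rows = []
    for roi, scans in roi_scans.items():
        engine = PermutationEngine(
            scans,
            conditions=conditions,
            fisher_z=fisher_z,
            discr_mode=discr_mode,
            fingerprint_direction=fingerprint_direction,
        )
        for measure in VALID_MEASURES:
            n_perm = n_perm_icc if measure == "mean_icc" else n_perm_multi
            res = engine.test(
                measure, n_perm, seed=next(children), roi=roi,
                strict=strict, add_one=add_one,
            )
            ca, cb = engine.conditions
            rows.append(
                {
                    "roi": roi,
                    "measure": measure,
                    f"value_{ca}": res.observed_values[ca],
                    f"value_{cb}": res.observed_values[cb],
                    "observed_diff": res.observed_diff,
                    "n_permutations": res.n_permutations,
                    "p_raw": res.p_raw,
                }
            )
    table = pd.DataFrame(rows)
    table["p_adjusted"] = bh_fdr(table["p_raw"].to_numpy())
    table["significant"] = table["p_adjusted"] < alpha
    return table


def parcelwise_driver(
    scans: Sequence[ScanRecord],
    pmap: ParcelMap,
    n_perm: int = 5000,
    seed: int = 0,
    alpha: float = 0.05,
    conditions: tuple[str, str] | None = None,
    fisher_z: bool = False,
    discr_mode: str = "cross_scan",
    fingerprint_direction: str = "both",
    strict: bool = False,
    add_one: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Whole-brain loop: every parcel as an ROI, multivariate measures only.

    Mean ICC is omitted at this level; the BH family spans
    n_parcels x 3 hypotheses (1,137 for a 379-parcel map).  Returns the
    per-test table and a per-measure count of parcels significantly
    better for each condition.
    """
    parcel_rois = pmap.parcel_rois()
    ss = np.random.SeedSequence(seed)
    children = iter(ss.spawn(len(parcel_rois) * len(MULTIVARIATE_MEASURES)))
    rows = []
    for roi_name, vertices in parcel_rois.items():
        roi_pmap = ParcelMap(
            assignment=pmap.assignment, roi_masks={roi_name: vertices}
        )
        fc_set = {
            (s.subject_id, s.condition, s.scan_index): compute_fc(
                s, roi_pmap, roi_name
            )
            for s in scans
        }
        engine = PermutationEngine(
            fc_set,
            conditions=conditions,
            fisher_z=fisher_z,
            discr_mode=discr_mode,
            fingerprint_direction=fingerprint_direction,
        )
        for measure in MULTIVARIATE_MEASURES:
            res = engine.test(
                measure, n_perm, seed=next(children), roi=roi_name,
                strict=strict, add_one=add_one,
            )
            ca, cb = engine.conditions
            rows.append(
                {
                    "parcel": roi_name,
                    "measure": measure,
                    f"value_{ca}": res.observed_values[ca],
                    f"value_{cb}": res.observed_values[cb],
                    "observed_diff": res.observed_diff,
                    "p_raw": res.p_raw,
                }
            )
    table = pd.DataFrame(rows)
    table["p_adjusted"] = bh_fdr(table["p_raw"].to_numpy())
    table["significant"] = table["p_adjusted"] < alpha
    ca, cb = conditions or _infer_conditions(
        {(s.subject_id, s.condition, s.scan_index): None for s in scans}
    )
    counts = (
        table.assign(
            better=np.where(table["observed_diff"] > 0, ca, cb)
        )
        .query("significant")
        .groupby(["measure", "better"])
        .size()
        .rename("n_parcels")
        .reset_index()
    )
    return table, counts


def family_size(n_rois: int, n_measures: int) -> int:
    """Bookkeeping helper: hypotheses in one BH family."""
    return n_rois * n_measures


def duration_sweep(
    scans: Sequence[ScanRecord],
    pmap: ParcelMap,
    roi: str,
    start: int = 20,
    step: int = 20,
    stop: int = 680,
    fisher_z: bool = False,
    discr_mode: str = "cross_scan",
    fingerprint_direction: str = "both",
) -> DurationSweepResult:
    """Recompute FC and all four measures on growing scan prefixes.

    The default grid is 20, 40, ..., 680 TRs (34 points).  If some scan
    is shorter than `stop` the grid is truncated to the common minimum
    with a warning; truncation operates on the cleaned (trimmed/cropped)
    series.
    """
    scans = list(scans)
    if not scans:
        raise ValidationError("no scans supplied")
    min_len = min(s.n_timepoints for s in scans)
    if start > min_len:
        raise ValidationError(
            f"sweep start {start} exceeds the shortest scan ({min_len} TRs)"
        )
    grid = list(range(start, stop + 1, step))
    if grid[-1] > min_len:
        grid = [g for g in grid if g <= min_len]
        warnings.warn(
            f"sweep grid truncated at {grid[-1]} TRs (shortest scan {min_len})",
            stacklevel=2,
        )
    conditions = sorted({s.condition for s in scans})
    estimates = []
    for g in grid:
        cut = [truncate_to_trs(s, g) for s in scans]
        for condition in conditions:
            fc_set = {
                (s.subject_id, s.scan_index): compute_fc(s, pmap, roi)
                for s in cut
                if s.condition == condition
            }
            estimates.extend(
                reliability_suite(
                    fc_set,
                    roi=roi,
                    condition=condition,
                    fisher_z=fisher_z,
                    discr_mode=discr_mode,
                    fingerprint_direction=fingerprint_direction,
                    n_trs=g,
                )
            )
    return DurationSweepResult(grid=grid, table=estimates_to_frame(estimates))
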