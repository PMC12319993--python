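"""From raw per-scan time series to analysis-ready vertex x parcel FC matrices.

The processing contract mirrors a standard naturalistic-fMRI workflow:
drop the initial settle-in TRs, excise stimulus-boundary epochs (plus a
post-epoch padding window to let the haemodynamic response decay), crop
runs to a common length within each session, average vertices into
parcel time courses, and correlate every ROI vertex against every parcel
(Pearson).  Subjects whose head motion (mean framewise displacement)
exceeds a threshold in any run are excluded up front.

All TR coordinates are 0-based, half-open intervals [start, start+length).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class ScanRecord:
    """One scan's vertex time series plus identifying metadata."""

    subject_id: str
    condition: str
    scan_index: int
    session: int
    data: np.ndarray  # time x vertices
    tr_seconds: float = 1.0
    mean_fd: float | None = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] < 1 or self.data.shape[1] < 1:
            raise ValidationError(
                "ScanRecord.data must be a time x vertices matrix with at "
                "least one timepoint and one vertex"
            )
        if self.mean_fd is not None and self.mean_fd < 0:
            raise ValidationError("mean_fd must be >= 0")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.data.shape[1]


@dataclass
class EpochTable:
    """Intervals of TRs to excise, each followed by `pad` extra TRs.

    Interval coordinates refer to the ORIGINAL (untrimmed) scan frame.
    """

    intervals: Sequence[tuple[int, int]] = field(default_factory=list)
    pad: int = 0

    def __post_init__(self) -> None:
        ints = [(int(s), int(l)) for s, l in self.intervals]
        if any(s < 0 or l < 1 for s, l in ints):
            raise ValidationError("epoch intervals need start >= 0 and length >= 1")
        if ints != sorted(ints):
            raise ValidationError("epoch intervals must be sorted by start")
        if self.pad < 0:
            raise ValidationError("epoch padding must be >= 0")
        for (s1, l1), (s2, _) in zip(ints, ints[1:]):
            if s1 + l1 + self.pad > s2:
                raise ValidationError(
                    "epoch+padding windows overlap or touch out of order"
                )
        self.intervals = ints

    def windows(self) -> list[tuple[int, int]]:
        """Half-open [start, stop) windows including padding."""
        return [(s, s + l + self.pad) for s, l in self.intervals]


@dataclass
class ParcelMap:
    """Vertex -> parcel assignment plus named ROI vertex masks."""

    assignment: np.ndarray  # 0-based parcel index per vertex
    roi_masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=int)
        if self.assignment.ndim != 1:
            raise ValidationError("parcel assignment must be a 1-D vertex vector")
        if self.assignment.min(initial=0) < 0:
            raise ValidationError("parcel indices must be >= 0")
        masks = {}
        n_vertices = self.assignment.size
        for name, idx in self.roi_masks.items():
            idx = np.asarray(idx, dtype=int)
            if idx.size == 0:
                raise ValidationError(f"ROI mask {name!r} is empty")
            if idx.min() < 0 or idx.max() >= n_vertices:
                raise ValidationError(
                    f"ROI mask {name!r} has vertices outside [0, {n_vertices})"
                )
            masks[name] = idx
        self.roi_masks = masks

    @property
    def n_parcels(self) -> int:
        return int(self.assignment.max()) + 1

    def parcel_rois(self) -> dict[str, np.ndarray]:
        """Every parcel as its own ROI (for whole-brain drivers)."""
        return {
            f"parcel-{p:03d}": np.flatnonzero(self.assignment == p)
            for p in range(self.n_parcels)
        }

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"vertex": np.arange(self.assignment.size), "parcel": self.assignment}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, roi_masks: dict | None = None) -> "ParcelMap":
        df = pd.read_csv(path, sep="\t").sort_values("vertex")
        return cls(assignment=df["parcel"].to_numpy(), roi_masks=roi_masks or {})


@dataclass
class FCMatrix:
    """Vertices x parcels connectivity for one (subject, condition, scan).

    ``scale`` is "r" for raw Pearson correlations (entries in [-1, 1] or
    NaN) or "z" for Fisher-transformed / unbounded connectivity values.
    """

    values: np.ndarray
    subject_id: str
    condition: str
    scan_index: int
    n_timepoints_used: int | None = None
    scale: str = "r"
    mean_fd: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("FCMatrix.values must be 2-D (vertices x parcels)")
        if self.scale not in ("r", "z"):
            raise ValidationError("FCMatrix.scale must be 'r' or 'z'")
        if self.scale == "r":
            finite = self.values[np.isfinite(self.values)]
            if finite.size and (finite.min() < -1 - 1e-9 or finite.max() > 1 + 1e-9):
                raise ValidationError(
                    "Pearson-scale FCMatrix entries must lie in [-1, 1]"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


# ---------------------------------------------------------------------------
# Operations


def trim_scan(
    scan: ScanRecord, n_initial: int, epochs: EpochTable | None = None
) -> ScanRecord:
    """Drop the first `n_initial` TRs, then excise each epoch + padding.

    Epoch coordinates are interpreted in the original scan's 0-based TR
    frame; the returned scan keeps the surviving timepoints in order.
    """
    if n_initial < 0:
        raise ValidationError("n_initial must be >= 0")
    T = scan.n_timepoints
    keep = np.ones(T, dtype=bool)
    keep[:n_initial] = False
    if epochs is not None:
        for start, stop in epochs.windows():
            if stop > T:
                raise ValidationError(
                    f"epoch window [{start}, {stop}) exceeds scan length {T}"
                )
            keep[start:stop] = False
    if not keep.any():
        raise ValidationError("trim removes every timepoint of the scan")
    return replace(scan, data=scan.data[keep])


def crop_to_common_length(scans: Iterable[ScanRecord]) -> list[ScanRecord]:
    """Truncate scans (from the end) to the minimum length within each session."""
    scans = list(scans)
    if not scans:
        raise ValidationError("no scans to crop")
    target: dict[int, int] = {}
    for s in scans:
        target[s.session] = min(target.get(s.session, s.n_timepoints), s.n_timepoints)
    return [
        replace(s, data=s.data[: target[s.session]])
        if s.n_timepoints > target[s.session]
        else s
        for s in scans
    ]


def qc_filter(
    scans: Iterable[ScanRecord], fd_threshold_mm: float
) -> tuple[set[str], set[str]]:
    """Split subjects into (kept, excluded) by head motion.

    A subject is excluded if ANY of its scans has mean framewise
    displacement above the threshold.
    """
    excluded: set[str] = set()
    all_subjects: set[str] = set()
    for scan in scans:
        all_subjects.add(scan.subject_id)
        if scan.mean_fd is None:
            raise ValidationError(
                f"scan ({scan.subject_id}, {scan.condition}, {scan.scan_index}) "
                "has no recorded mean_fd"
            )
        if scan.mean_fd > fd_threshold_mm:
            excluded.add(scan.subject_id)
    kept = all_subjects - excluded
    if excluded:
        logger.info("qc_filter excluded %d subject(s): %s",
                    len(excluded), sorted(excluded))
    return kept, excluded


def parcellate(scan: ScanRecord, pmap: ParcelMap) -> np.ndarray:
    """Unweighted mean time course of each parcel's member vertices."""
    if pmap.assignment.size != scan.n_vertices:
        raise ValidationError(
            f"parcel assignment covers {pmap.assignment.size} vertices but the "
            f"scan has {scan.n_vertices}"
        )
    P = pmap.n_parcels
    counts = np.bincount(pmap.assignment, minlength=P)
    empty = np.flatnonzero(counts == 0)
    if empty.size:
        raise ValidationError(f"parcel(s) {empty.tolist()} have zero member vertices")
    sums = np.zeros((scan.n_timepoints, P))
    np.add.at(sums.T, pmap.assignment, scan.data.T)
    return sums / counts


def _pearson_block(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Columnwise Pearson r between all columns of x and all columns of y."""
    T = x.shape[0]
    xc = x - x.mean(0)
    yc = y - y.mean(0)
    xs = np.sqrt((xc**2).sum(0))
    ys = np.sqrt((yc**2).sum(0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc.T @ yc) / np.outer(xs, ys)
    r[~np.isfinite(r)] = np.nan
    return np.clip(r, -1.0, 1.0)


def compute_fc(scan: ScanRecord, pmap: ParcelMap, roi: str) -> FCMatrix:
    """Pearson correlation of every ROI vertex with every parcel time course.

    Zero-variance series produce NaN entries (and a logged warning); ROI
    vertices still correlate against the parcel that contains them.
    """
    if scan.n_timepoints < 3:
        raise ValidationError("compute_fc requires at least 3 timepoints")
    if roi not in pmap.roi_masks:
        raise ValidationError(f"ROI {roi!r} not found in the parcel map")
    parcel_ts = parcellate(scan, pmap)
    roi_ts = scan.data[:, pmap.roi_masks[roi]]
    r = _pearson_block(roi_ts, parcel_ts)
    n_nan = int(np.isnan(r).sum())
    if n_nan:
        logger.warning(
            "compute_fc(%s, %s, scan %d, roi %s): %d degenerate (NaN) entries",
            scan.subject_id, scan.condition, scan.scan_index, roi, n_nan,
        )
    return FCMatrix(
        values=r,
        subject_id=scan.subject_id,
        condition=scan.condition,
        scan_index=scan.scan_index,
        n_timepoints_used=scan.n_timepoints,
        scale="r",
        mean_fd=scan.mean_fd,
    )


def shared_nan_mask(fcs: Iterable[FCMatrix]) -> np.ndarray:
    """Boolean keep-mask over edges: an edge NaN in ANY scan is dropped in all."""
    mask = None
    for fc in fcs:
        good = np.isfinite(fc.values).ravel()
        mask = good if mask is None else mask & good
    if mask is None:
        raise ValidationError("no FC matrices supplied")
    return mask


def vectorize_fc(
    fc: FCMatrix, fisher_z: bool = False, mask: np.ndarray | None = None
) -> np.ndarray:
    """Row-major flattening of an FC matrix, optionally Fisher-transformed.

    `mask` is the dataset-wide keep-mask from :func:`shared_nan_mask`;
    without one, NaN edges of this matrix alone are dropped.
    """
    flat = fc.values.ravel()
    if mask is None:
        mask = np.isfinite(flat)
    if not mask.any():
        raise ValidationError("FC matrix has no finite edges after masking")
    flat = flat[mask]
    if fisher_z and fc.scale == "r":
        flat = np.arctanh(np.clip(flat, -1 + 1e-7, 1 - 1e-7))
    return flat


def truncate_to_trs(scan: ScanRecord, n_trs: int) -> ScanRecord:
    """Keep only the first `n_trs` timepoints."""
    if n_trs < 1:
        raise ValidationError("n_trs must be >= 1")
    if n_trs > scan.n_timepoints:
        raise ValidationError(
            f"n_trs={n_trs} exceeds scan length {scan.n_timepoints}"
        )
    if n_trs == scan.n_timepoints:
        return scan
    return replace(scan, data=scan.data[:n_trs])


# ---------------------------------------------------------------------------
# Plain-text IO (dense TSV matrices + manifest), matching synthetic.write_dataset


def write_scans(scans: Iterable[ScanRecord], outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in scans:
        fname = f"{s.subject_id}_{s.condition}_scan{s.scan_index}.tsv"
        np.savetxt(outdir / fname, s.data, fmt="%.17g", delimiter="\t")
        rows.append(
            dataclasses.asdict(s)
            | {"path": fname, "n_timepoints": s.n_timepoints}
        )
    for r in rows:
        r.pop("data")
    manifest = outdir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def read_scans(manifest: str | Path) -> list[ScanRecord]:
    manifest = Path(manifest)
    df = pd.read_csv(manifest, sep="\t")
    out = []
    for row in df.itertuples():
        data = np.loadtxt(manifest.parent / row.path, delimiter="\t", ndmin=2)
        out.append(
            ScanRecord(
                subject_id=row.subject_id,
                condition=row.condition,
                scan_index=int(row.scan_index),
                session=int(row.session),
                data=data,
                tr_seconds=float(getattr(row, "tr_seconds", 1.0)),
                mean_fd=float(row.mean_fd) if pd.notna(row.mean_fd) else None,
            )
        )
    return out
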