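"""Synthetic multi-subject, two-condition, two-scan FC datasets.

The generator draws data from an explicit hierarchical variance model so
that every downstream reliability statistic has an analytic (direct-FC
mode) or brute-force (time-series mode) ground truth:

* ``direct_fc`` mode — each connectivity edge value for subject *i*,
  scan *j* is ``X_ij = mu_i + eps_ij`` with ``mu_i ~ N(0, sigma2_between)``
  and ``eps_ij ~ N(0, sigma2_within)``.  The edgewise intraclass
  correlation is then exactly ``sigma2_between / (sigma2_between +
  sigma2_within)``.  Values are unbounded Gaussians, i.e. they live on an
  (implicitly Fisher-transformed) connectivity scale rather than raw
  Pearson r; this keeps the variance components exact.

* ``timeseries`` mode — each subject owns a latent parcel-level mixing
  matrix; every scan draws fresh T-sample signals from it plus
  scan-specific noise, and vertex signals are their parcel's signal plus
  vertex noise.  Sample FC computed from these series has
  between/within-subject variance ordering controlled by the same two
  sigma parameters (no closed form; use Monte-Carlo).

A ``condition_effect`` can scale either variance component per condition,
which is the planted "acquisition state" effect downstream permutation
tests should detect.  With the identity effect the two conditions are
exchangeable by construction.

Randomness uses one root seed with per-subject child streams, so adding
subjects never perturbs already-generated ones.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError
from .pipeline import FCMatrix, ParcelMap, ScanRecord

DEFAULT_CONDITIONS = ("movie", "rest")


@dataclass(frozen=True)
class ConditionEffect:
    """Multiplicative scaling of the variance components for one condition."""

    between: float = 1.0
    within: float = 1.0


@dataclass
class VarianceSpec:
    """Parameters of the hierarchical generative model.

    sigma2_between is the variance of the subject-level latent edge value
    (trait connectivity); sigma2_within is the variance of scan-level
    noise (state + measurement).  Their ratio fixes the theoretical
    edgewise ICC in direct-FC mode.
    """

    n_subjects: int
    n_vertices: int
    n_parcels: int
    sigma2_between: float
    sigma2_within: float
    n_scans_per_condition: int = 2
    conditions: tuple[str, str] = DEFAULT_CONDITIONS
    condition_effect: Mapping[str, ConditionEffect] = field(default_factory=dict)
    mode: Literal["direct_fc", "timeseries"] = "direct_fc"
    n_timepoints: int | None = None
    shared_rank: int = 0
    shared_var: float = 0.0
    fd_lognormal: tuple[float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma2_between < 0 or self.sigma2_within < 0:
            raise ValidationError("sigma2_between and sigma2_within must be >= 0")
        if self.sigma2_between == 0 and self.sigma2_within == 0:
            raise ValidationError(
                "sigma2_between and sigma2_within must not both be zero"
            )
        if self.n_scans_per_condition < 2:
            raise ValidationError("n_scans_per_condition must be >= 2")
        if self.n_subjects < 3:
            raise ValidationError("n_subjects must be >= 3")
        if self.n_vertices < 1 or self.n_parcels < 1:
            raise ValidationError("n_vertices and n_parcels must be >= 1")
        if len(self.conditions) != 2 or self.conditions[0] == self.conditions[1]:
            raise ValidationError("conditions must be two distinct labels")
        if self.mode not in ("direct_fc", "timeseries"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.mode == "timeseries":
            if self.n_timepoints is None or self.n_timepoints < 20:
                raise ValidationError("timeseries mode requires n_timepoints >= 20")
        for label in self.condition_effect:
            if label not in self.conditions:
                raise ValidationError(
                    f"condition_effect key {label!r} not in conditions"
                )
        if self.shared_rank < 0 or self.shared_var < 0:
            raise ValidationError("shared_rank and shared_var must be >= 0")

    def effect(self, condition: str) -> ConditionEffect:
        return self.condition_effect.get(condition, ConditionEffect())


@dataclass
class DatasetTruth:
    """Model-implied values for the generated data (direct-FC mode only)."""

    icc: dict[str, float]
    icc_difference: float  # conditions[0] minus conditions[1]


@dataclass
class SyntheticDataset:
    """Complete subject x condition x scan crossing of generated scans."""

    scans: dict[tuple[str, str, int], object]
    spec: VarianceSpec
    truth: DatasetTruth | None = None
    parcel_map: ParcelMap | None = None

    def subjects(self) -> list[str]:
        return sorted({k[0] for k in self.scans})

    def condition_scans(self, condition: str) -> dict[tuple[str, int], object]:
        """Scans of one condition keyed by (subject, scan_index)."""
        return {
            (s, i): v for (s, c, i), v in self.scans.items() if c == condition
        }


def theoretical_icc(spec: VarianceSpec, condition: str) -> float:
    """Closed-form edgewise ICC implied by the variance components.

    Only defined in direct-FC mode, where the model is exactly the
    one-way random-effects decomposition the ICC estimates.
    """
    if spec.mode != "direct_fc":
        raise ValidationError(
            "theoretical_icc has no closed form in timeseries mode; "
            "estimate it by Monte-Carlo instead"
        )
    eff = spec.effect(condition)
    s2b = (spec.sigma2_between + spec.shared_var) * eff.between
    s2w = spec.sigma2_within * eff.within
    if s2b == 0 and s2w == 0:
        raise ValidationError("condition-adjusted variances are both zero")
    return s2b / (s2b + s2w)


def _subject_id(i: int) -> str:
    return f"sub-{i + 1:03d}"


def _streams(spec: VarianceSpec) -> tuple[np.random.Generator, list[np.random.SeedSequence]]:
    """One global stream plus one stable child stream per subject."""
    children = np.random.SeedSequence(spec.seed).spawn(spec.n_subjects + 1)
    return np.random.default_rng(children[0]), children[1:]


def _draw_fd(rng: np.random.Generator, spec: VarianceSpec) -> float:
    if spec.fd_lognormal is None:
        return 0.0
    mu, sigma = spec.fd_lognormal
    return float(rng.lognormal(mu, sigma))


def generate_fc_dataset(spec: VarianceSpec) -> SyntheticDataset:
    """Draw per-scan FC matrices directly from the hierarchical edge model."""
    if spec.mode != "direct_fc":
        raise ValidationError("generate_fc_dataset requires mode='direct_fc'")
    n_edges = spec.n_vertices * spec.n_parcels
    global_rng, child_seeds = _streams(spec)
    shared_basis = None
    if spec.shared_rank > 0 and spec.shared_var > 0:
        shared_basis = global_rng.normal(size=(n_edges, spec.shared_rank))

    scans: dict[tuple[str, str, int], FCMatrix] = {}
    for i, child in enumerate(child_seeds):
        rng = np.random.default_rng(child)
        sid = _subject_id(i)
        mu = rng.normal(0.0, 1.0, n_edges) * np.sqrt(spec.sigma2_between)
        if shared_basis is not None:
            loadings = rng.normal(size=spec.shared_rank)
            mu = mu + shared_basis @ loadings * np.sqrt(
                spec.shared_var / spec.shared_rank
            )
        for condition in spec.conditions:
            eff = spec.effect(condition)
            latent = mu * np.sqrt(eff.between)
            noise_sd = np.sqrt(spec.sigma2_within * eff.within)
            for j in range(1, spec.n_scans_per_condition + 1):
                values = latent + rng.normal(0.0, 1.0, n_edges) * noise_sd
                scans[(sid, condition, j)] = FCMatrix(
                    values=values.reshape(spec.n_vertices, spec.n_parcels),
                    subject_id=sid,
                    condition=condition,
                    scan_index=j,
                    scale="z",
                    mean_fd=_draw_fd(rng, spec),
                )

    truth = DatasetTruth(
        icc={c: theoretical_icc(spec, c) for c in spec.conditions},
        icc_difference=theoretical_icc(spec, spec.conditions[0])
        - theoretical_icc(spec, spec.conditions[1]),
    )
    return SyntheticDataset(scans=scans, spec=spec, truth=truth)


def default_parcel_map(n_vertices: int, n_parcels: int) -> ParcelMap:
    """Contiguous equal-size blocks of vertices, one block per parcel."""
    assignment = (np.arange(n_vertices) * n_parcels) // n_vertices
    return ParcelMap(assignment=assignment, roi_masks={})


def generate_timeseries_dataset(spec: VarianceSpec) -> SyntheticDataset:
    """Draw per-scan vertex time series with subject-specific latent structure.

    Each subject's parcel signals are a linear mix ``Z @ L_i.T`` of iid
    normals, where ``L_i = (A_shared + sqrt(sigma2_between * effect) B_i)
    / sqrt(P)``; ``A_shared`` is common to everyone, ``B_i`` is
    subject-specific.  Scan-level parcel noise and vertex noise both scale
    with ``sqrt(sigma2_within * effect)``.
    """
    if spec.mode != "timeseries":
        raise ValidationError("generate_timeseries_dataset requires mode='timeseries'")
    T, V, P = spec.n_timepoints, spec.n_vertices, spec.n_parcels
    pmap = default_parcel_map(V, P)
    global_rng, child_seeds = _streams(spec)
    a_shared = global_rng.normal(size=(P, P))

    scans: dict[tuple[str, str, int], ScanRecord] = {}
    for i, child in enumerate(child_seeds):
        rng = np.random.default_rng(child)
        sid = _subject_id(i)
        b_i = rng.normal(size=(P, P))
        for condition in spec.conditions:
            eff = spec.effect(condition)
            mixing = (
                a_shared + np.sqrt(spec.sigma2_between * eff.between) * b_i
            ) / np.sqrt(P)
            noise_sd = np.sqrt(spec.sigma2_within * eff.within)
            for j in range(1, spec.n_scans_per_condition + 1):
                z = rng.normal(size=(T, P))
                parcel_sig = z @ mixing.T + noise_sd * rng.normal(size=(T, P))
                data = parcel_sig[:, pmap.assignment] + noise_sd * rng.normal(
                    size=(T, V)
                )
                scans[(sid, condition, j)] = ScanRecord(
                    subject_id=sid,
                    condition=condition,
                    scan_index=j,
                    session=j,
                    data=data,
                    mean_fd=_draw_fd(rng, spec),
                )
    return SyntheticDataset(scans=scans, spec=spec, truth=None, parcel_map=pmap)


def generate_dataset(spec: VarianceSpec) -> SyntheticDataset:
    if spec.mode == "direct_fc":
        return generate_fc_dataset(spec)
    return generate_timeseries_dataset(spec)


# ---------------------------------------------------------------------------
# On-disk format: one dense TSV per scan + a manifest table + spec JSON.

def spec_to_dict(spec: VarianceSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["conditions"] = list(spec.conditions)
    d["condition_effect"] = {
        k: dataclasses.asdict(v) for k, v in spec.condition_effect.items()
    }
    if spec.fd_lognormal is not None:
        d["fd_lognormal"] = list(spec.fd_lognormal)
    return d


def spec_from_dict(d: Mapping) -> VarianceSpec:
    d = dict(d)
    d["conditions"] = tuple(d.get("conditions", DEFAULT_CONDITIONS))
    d["condition_effect"] = {
        k: ConditionEffect(**v) for k, v in d.get("condition_effect", {}).items()
    }
    if d.get("fd_lognormal") is not None:
        d["fd_lognormal"] = tuple(d["fd_lognormal"])
    return VarianceSpec(**d)


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> Path:
    """Write scans as TSV matrices plus a manifest; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for (sid, condition, j), scan in sorted(dataset.scans.items()):
        fname = f"{sid}_{condition}_scan{j}.tsv"
        if isinstance(scan, ScanRecord):
            matrix, session, fd = scan.data, scan.session, scan.mean_fd
        else:  # FCMatrix
            matrix, session, fd = scan.values, j, scan.mean_fd
        np.savetxt(outdir / fname, matrix, fmt="%.17g", delimiter="\t")
        rows.append(
            {
                "subject": sid,
                "condition": condition,
                "scan_index": j,
                "session": session,
                "path": fname,
                "mean_fd": fd,
            }
        )
    manifest = outdir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    (outdir / "spec.json").write_text(
        json.dumps(spec_to_dict(dataset.spec), indent=2, sort_keys=True) + "\n"
    )
    if dataset.parcel_map is not None:
        dataset.parcel_map.to_tsv(outdir / "parcel_map.tsv")
    return manifest


def read_dataset(indir: str | Path) -> SyntheticDataset:
    """Reload a dataset written by :func:`write_dataset`."""
    indir = Path(indir)
    spec = spec_from_dict(json.loads((indir / "spec.json").read_text()))
    manifest = pd.read_csv(indir / "manifest.tsv", sep="\t")
    scans: dict[tuple[str, str, int], object] = {}
    for row in manifest.itertuples():
        matrix = np.loadtxt(indir / row.path, delimiter="\t", ndmin=2)
        key = (row.subject, row.condition, int(row.scan_index))
        if spec.mode == "direct_fc":
            scans[key] = FCMatrix(
                values=matrix,
                subject_id=row.subject,
                condition=row.condition,
                scan_index=int(row.scan_index),
                scale="z",
                mean_fd=float(row.mean_fd),
            )
        else:
            scans[key] = ScanRecord(
                subject_id=row.subject,
                condition=row.condition,
                scan_index=int(row.scan_index),
                session=int(row.session),
                data=matrix,
                mean_fd=float(row.mean_fd),
            )
    pmap = None
    pmap_file = indir / "parcel_map.tsv"
    if pmap_file.exists():
        pmap = ParcelMap.from_tsv(pmap_file)
    truth = None
    if spec.mode == "direct_fc":
        truth = DatasetTruth(
            icc={c: theoretical_icc(spec, c) for c in spec.conditions},
            icc_difference=theoretical_icc(spec, spec.conditions[0])
            - theoretical_icc(spec, spec.conditions[1]),
        )
    return SyntheticDataset(scans=scans, spec=spec, truth=truth, parcel_map=pmap)
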