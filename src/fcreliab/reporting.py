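"""End-to-end runs from a config file, plus tabular/graphical summaries.

`run_pipeline` executes simulate/ingest -> QC -> FC -> reliability
metrics -> permutation inference -> optional duration sweep and
parcelwise driver, writing tidy TSVs and a JSON run-metadata sidecar.
Re-running an identical config reproduces byte-identical numeric tables.

`summarize` renders a human-readable report from a completed results
directory without recomputing anything: grouped bars of the four
measures per ROI with significance stars, measure-vs-TRs curves, and
parcelwise significant counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, ValidationError
from .inference import duration_sweep, parcelwise_driver, roi_comparison_suite
from .metrics import estimates_to_frame, reliability_suite
from .pipeline import (
    EpochTable,
    FCMatrix,
    ParcelMap,
    ScanRecord,
    compute_fc,
    crop_to_common_length,
    qc_filter,
    read_scans,
    trim_scan,
)
from .synthetic import (
    SyntheticDataset,
    VarianceSpec,
    generate_dataset,
    spec_from_dict,
)

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Validated description of one end-to-end run."""

    output_dir: Path
    seed: int = 0
    simulate: VarianceSpec | None = None
    manifest: Path | None = None
    parcel_map: Path | None = None
    rois: Mapping[str, list[int]] | int = 3
    fd_threshold_mm: float = 0.2
    fisher_z: bool = False
    discr_mode: str = "cross_scan"
    fingerprint_direction: str = "both"
    n_perm_multi: int = 5000
    n_perm_icc: int = 500
    alpha: float = 0.05
    p_rule: str = "geq"  # "geq" | "strict" | "add_one"
    trim_initial: int = 0
    epochs: EpochTable | None = None
    sweep: dict | None = None  # {start, step, stop, roi}
    parcelwise: dict | None = None  # {n_perm}

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ConfigError("alpha must lie in (0, 1)")
        if self.p_rule not in ("geq", "strict", "add_one"):
            raise ConfigError("p_rule must be 'geq', 'strict' or 'add_one'")
        if (self.simulate is None) == (self.manifest is None):
            raise ConfigError(
                "config needs exactly one of 'simulate' or 'input.manifest'"
            )
        if self.manifest is not None:
            if not Path(self.manifest).exists():
                raise ConfigError(f"input manifest {self.manifest} does not exist")
            if self.parcel_map is None or not Path(self.parcel_map).exists():
                raise ConfigError("manifest input requires an existing parcel_map")

    @property
    def p_flags(self) -> dict:
        return {
            "strict": self.p_rule == "strict",
            "add_one": self.p_rule == "add_one",
        }


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file {path} does not exist")
    raw = yaml.safe_load(path.read_text()) or {}
    return config_from_dict(raw, base_dir=path.parent)


def config_from_dict(raw: Mapping, base_dir: Path | None = None) -> RunConfig:
    base = Path(base_dir) if base_dir else Path.cwd()
    sim = raw.get("simulate")
    spec = None
    if sim is not None:
        try:
            spec = spec_from_dict({"seed": raw.get("seed", 0), **sim})
        except (TypeError, ValidationError) as exc:
            raise ConfigError(f"invalid simulate block: {exc}") from exc
    inp = raw.get("input", {}) or {}
    manifest = base / inp["manifest"] if "manifest" in inp else None
    pmap = base / inp["parcel_map"] if "parcel_map" in inp else None
    metrics = raw.get("metrics", {}) or {}
    inference = raw.get("inference", {}) or {}
    trim = raw.get("trim", {}) or {}
    epochs = None
    if trim.get("epochs"):
        epochs = EpochTable(
            intervals=[tuple(e) for e in trim["epochs"]],
            pad=trim.get("epoch_pad", 0),
        )
    return RunConfig(
        output_dir=base / raw.get("output_dir", "results"),
        seed=int(raw.get("seed", 0)),
        simulate=spec,
        manifest=manifest,
        parcel_map=pmap,
        rois=raw.get("rois", 3),
        fd_threshold_mm=float(raw.get("qc", {}).get("fd_threshold_mm", 0.2))
        if raw.get("qc")
        else float("inf"),
        fisher_z=bool(metrics.get("fisher_z", False)),
        discr_mode=metrics.get("discr_mode", "cross_scan"),
        fingerprint_direction=metrics.get("fingerprint_direction", "both"),
        n_perm_multi=int(inference.get("n_perm_multi", 5000)),
        n_perm_icc=int(inference.get("n_perm_icc", 500)),
        alpha=float(inference.get("alpha", 0.05)),
        p_rule=inference.get("p_rule", "geq"),
        trim_initial=int(trim.get("n_initial", 0)),
        epochs=epochs,
        sweep=raw.get("sweep"),
        parcelwise=raw.get("parcelwise"),
    )


def _auto_rois(n_vertices: int, n_rois: int) -> dict[str, np.ndarray]:
    """Contiguous equal blocks of vertices as ROIs."""
    bounds = np.linspace(0, n_vertices, n_rois + 1).astype(int)
    return {
        f"roi-{i + 1}": np.arange(bounds[i], bounds[i + 1])
        for i in range(n_rois)
    }


def _resolve_rois(config: RunConfig, n_vertices: int) -> dict[str, np.ndarray]:
    if isinstance(config.rois, int):
        return _auto_rois(n_vertices, config.rois)
    return {name: np.asarray(v, dtype=int) for name, v in config.rois.items()}


def _config_hash(config: RunConfig) -> str:
    def default(o):
        if isinstance(o, Path):
            return str(o)
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return repr(o)

    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def run_pipeline(config: RunConfig) -> Path:
    """Execute every configured stage; returns the results directory."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("fcreliab")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        return _run_pipeline(config, outdir)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run_pipeline(config: RunConfig, outdir: Path) -> Path:
    # --- stage: simulate or ingest
    if config.simulate is not None:
        dataset = generate_dataset(config.simulate)
        if config.simulate.mode == "direct_fc":
            scans = None
            fc_by_key = dict(dataset.scans)
            n_vertices = config.simulate.n_vertices
            pmap = None
        else:
            scans = list(dataset.scans.values())
            fc_by_key = None
            n_vertices = config.simulate.n_vertices
            pmap = dataset.parcel_map
    else:
        scans = read_scans(config.manifest)
        fc_by_key = None
        pmap = ParcelMap.from_tsv(config.parcel_map)
        n_vertices = scans[0].n_vertices

    conditions = None
    if config.simulate is not None:
        conditions = config.simulate.conditions

    # --- stage: QC + trimming (time-series route only)
    if scans is not None:
        kept, excluded = qc_filter(scans, config.fd_threshold_mm)
        if not kept:
            raise ValidationError("qc_filter excluded every subject")
        scans = [s for s in scans if s.subject_id in kept]
        if config.trim_initial or config.epochs:
            scans = [
                trim_scan(s, config.trim_initial, config.epochs) for s in scans
            ]
        scans = crop_to_common_length(scans)
    else:
        kept = {k[0] for k in fc_by_key}
        excluded = set()

    rois = _resolve_rois(config, n_vertices)

    # --- stage: FC construction per ROI
    roi_fc: dict[str, dict[tuple[str, str, int], FCMatrix]] = {}
    for roi_name, vertices in rois.items():
        if scans is not None:
            roi_pmap = ParcelMap(
                assignment=pmap.assignment, roi_masks={roi_name: vertices}
            )
            roi_fc[roi_name] = {
                (s.subject_id, s.condition, s.scan_index): compute_fc(
                    s, roi_pmap, roi_name
                )
                for s in scans
            }
        else:
            roi_fc[roi_name] = {
                key: FCMatrix(
                    values=fc.values[vertices],
                    subject_id=fc.subject_id,
                    condition=fc.condition,
                    scan_index=fc.scan_index,
                    scale=fc.scale,
                )
                for key, fc in fc_by_key.items()
            }

    # --- stage: reliability metrics per ROI x condition
    estimates = []
    cond_labels = conditions or tuple(sorted({k[1] for k in next(iter(roi_fc.values()))}))
    for roi_name, fc_set in roi_fc.items():
        for condition in cond_labels:
            one_cond = {
                (s, j): fc for (s, c, j), fc in fc_set.items() if c == condition
            }
            estimates.extend(
                reliability_suite(
                    one_cond,
                    roi=roi_name,
                    condition=condition,
                    fisher_z=config.fisher_z,
                    discr_mode=config.discr_mode,
                    fingerprint_direction=config.fingerprint_direction,
                )
            )
    _write_tsv(estimates_to_frame(estimates), outdir / "reliability.tsv")

    # --- stage: permutation inference across ROIs
    comparisons = roi_comparison_suite(
        roi_fc,
        n_perm_multi=config.n_perm_multi,
        n_perm_icc=config.n_perm_icc,
        seed=config.seed,
        alpha=config.alpha,
        conditions=conditions,
        fisher_z=config.fisher_z,
        discr_mode=config.discr_mode,
        fingerprint_direction=config.fingerprint_direction,
        **config.p_flags,
    )
    _write_tsv(comparisons, outdir / "comparisons.tsv")

    # --- stage: optional duration sweep (time-series route only)
    if config.sweep:
        if scans is None:
            raise ConfigError("duration sweep requires time-series input")
        sweep_roi = config.sweep.get("roi") or next(iter(rois))
        roi_pmap = ParcelMap(
            assignment=pmap.assignment, roi_masks={sweep_roi: rois[sweep_roi]}
        )
        result = duration_sweep(
            scans,
            roi_pmap,
            sweep_roi,
            start=int(config.sweep.get("start", 20)),
            step=int(config.sweep.get("step", 20)),
            stop=int(config.sweep.get("stop", 680)),
            fisher_z=config.fisher_z,
            discr_mode=config.discr_mode,
            fingerprint_direction=config.fingerprint_direction,
        )
        _write_tsv(result.table, outdir / "sweep.tsv")

    # --- stage: optional whole-brain parcelwise driver
    if config.parcelwise:
        if scans is None:
            raise ConfigError("parcelwise driver requires time-series input")
        table, counts = parcelwise_driver(
            scans,
            pmap,
            n_perm=int(config.parcelwise.get("n_perm", 5000)),
            seed=config.seed + 1,
            alpha=config.alpha,
            conditions=conditions,
            fisher_z=config.fisher_z,
            discr_mode=config.discr_mode,
            fingerprint_direction=config.fingerprint_direction,
            **config.p_flags,
        )
        _write_tsv(table, outdir / "parcelwise.tsv")
        _write_tsv(counts, outdir / "parcelwise_counts.tsv")

    metadata = {
        "package": "fcreliab",
        "version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "n_subjects_kept": len(kept),
        "n_subjects_excluded": len(excluded),
        "rois": {k: int(v.size) for k, v in rois.items()},
    }
    (outdir / "run_metadata.json").write_text(
        json.dumps(metadata, indent=2, sort_keys=True) + "\n"
    )
    return outdir


# ---------------------------------------------------------------------------
# Reporting


def summarize(results_dir: str | Path, make_plots: bool = True) -> Path:
    """Render report.md (+ SVG figures) from a completed run directory.

    Raises ConfigError listing any missing pieces; every number in the
    report is read from the output TSVs, never recomputed.
    """
    results_dir = Path(results_dir)
    required = ["reliability.tsv", "comparisons.tsv", "run_metadata.json"]
    missing = [f for f in required if not (results_dir / f).exists()]
    if missing:
        raise ConfigError(
            f"results directory {results_dir} is incomplete; missing: {missing}"
        )
    reliability = pd.read_csv(results_dir / "reliability.tsv", sep="\t")
    comparisons = pd.read_csv(results_dir / "comparisons.tsv", sep="\t")
    metadata = json.loads((results_dir / "run_metadata.json").read_text())

    lines = [
        "# FC reliability report",
        "",
        f"Package fcreliab {metadata['version']}, seed {metadata['seed']}, "
        f"config {metadata['config_hash']}.",
        f"Subjects kept: {metadata['n_subjects_kept']} "
        f"(excluded by QC: {metadata['n_subjects_excluded']}).",
        "",
        "## Reliability by ROI and condition",
        "",
    ]
    pivot = reliability.pivot_table(
        index=["roi", "measure"], columns="condition", values="value"
    ).round(4)
    lines.append(pivot.to_markdown())
    lines += ["", "## Condition comparisons (permutation test, BH-FDR)", ""]
    stars = comparisons.assign(
        star=np.where(comparisons["significant"], "*", "")
    )
    lines.append(
        stars[
            [c for c in stars.columns if c not in ("n_permutations",)]
        ].round(4).to_markdown(index=False)
    )

    sweep_path = results_dir / "sweep.tsv"
    sweep = pd.read_csv(sweep_path, sep="\t") if sweep_path.exists() else None
    if sweep is None:
        lines += ["", "_No duration sweep in this run._"]

    parcel_path = results_dir / "parcelwise_counts.tsv"
    if parcel_path.exists():
        counts = pd.read_csv(parcel_path, sep="\t")
        lines += ["", "## Parcelwise significant counts", ""]
        lines.append(
            counts.to_markdown(index=False)
            if not counts.empty
            else "_No parcel reached significance._"
        )

    if make_plots:
        figures = _make_figures(results_dir, reliability, comparisons, sweep)
        if figures:
            lines += ["", "## Figures", ""]
            lines += [f"- {f.name}" for f in figures]

    report = results_dir / "report.md"
    report.write_text("\n".join(lines) + "\n")
    return report


def _make_figures(results_dir, reliability, comparisons, sweep) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    made = []
    rois = sorted(reliability["roi"].unique())
    measures = ["mean_icc", "i2c2", "discr", "fingerprint"]
    conditions = sorted(reliability["condition"].unique())
    fig, axes = plt.subplots(
        1, len(rois), figsize=(4 * len(rois), 3.2), squeeze=False, sharey=True
    )
    width = 0.35
    for ax, roi in zip(axes[0], rois):
        sub = reliability[reliability["roi"] == roi]
        x = np.arange(len(measures))
        for ci, cond in enumerate(conditions):
            vals = [
                sub[(sub["measure"] == m) & (sub["condition"] == cond)]["value"].mean()
                for m in measures
            ]
            ax.bar(x + (ci - 0.5) * width, vals, width, label=cond)
        sig = comparisons[(comparisons["roi"] == roi) & comparisons["significant"]]
        for m in sig["measure"]:
            if m in measures:
                ax.text(measures.index(m), ax.get_ylim()[1] * 0.95, "*",
                        ha="center", fontsize=14)
        ax.set_xticks(x, measures, rotation=30)
        ax.set_title(roi)
    axes[0][0].set_ylabel("reliability value")
    axes[0][-1].legend()
    fig.tight_layout()
    bar_path = results_dir / "reliability_bars.svg"
    fig.savefig(bar_path, metadata={"Date": None})
    plt.close(fig)
    made.append(bar_path)

    if sweep is not None and not sweep.empty:
        fig, axes = plt.subplots(1, 4, figsize=(14, 3.2), squeeze=False)
        for ax, m in zip(axes[0], measures):
            for cond in sorted(sweep["condition"].unique()):
                sub = sweep[(sweep["measure"] == m) & (sweep["condition"] == cond)]
                ax.plot(sub["n_trs"], sub["value"], marker=".", label=cond)
            ax.set_title(m)
            ax.set_xlabel("TRs")
        axes[0][0].set_ylabel("value")
        axes[0][-1].legend()
        fig.tight_layout()
        sweep_path = results_dir / "sweep_curves.svg"
        fig.savefig(sweep_path, metadata={"Date": None})
        plt.close(fig)
        made.append(sweep_path)
    return made
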