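"""Standard-format I/O, run configuration and the end-to-end pipeline.

Volumes go through NIfTI-1 (nibabel); vascular curves are 2-column
plain-text (time s, HU); cohorts are CSV with the documented header; reports
are JSON.  The cohort CSV is the contract between the imaging stages and the
statistical evaluation, so the statistics are testable without any imaging.

Array convention: in memory volumes are ``(z, y, x)`` and series
``(t, z, y, x)``; on disk NIfTI stores ``(x, y, z[, t])``, so axes are
reversed (and the time axis moved last) on write and restored on read.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import yaml

from . import segment
from .evaluate import classify_prediction, evaluate_cohort
from .infarct import segment_infarct
from .maps import MapConfig, PerfusionMaps, compute_perfusion_maps, compute_relative_maps
from .segment import AlgorithmConfig, LesionResult, split_hemispheres
from .simulate import (
    BolusParams,
    CohortRecord,
    CTPSeries,
    GroundTruthPhantom,
    LesionSpec,
    VascularInput,
    make_phantom,
    simulate_followup_ct,
    simulate_series,
)

logger = logging.getLogger("ctperf")

COHORT_HEADER = [
    "id", "thr_hypo_ml", "thr_core_ml", "mir_hypo_ml", "mir_core_ml",
    "isp_hypo_ml", "isp_core_ml", "infarct_ml", "treatment",
]


# --------------------------------------------------------------------------
# volumes
# --------------------------------------------------------------------------


def write_volume(
    path: str | Path,
    data: np.ndarray,
    spacing: Sequence[float],
    affine: np.ndarray | None = None,
    dt: float | None = None,
) -> Path:
    """Write a 3D volume or 4D series as NIfTI-1.

    ``spacing`` is mm per (z, y, x) axis; for 4D data ``dt`` is stored as
    the temporal pixdim.
    """
    data = np.asarray(data)
    if data.ndim == 3:
        disk = np.transpose(data, (2, 1, 0))
        zooms = tuple(spacing[::-1])
    elif data.ndim == 4:
        disk = np.transpose(data, (3, 2, 1, 0))
        zooms = tuple(spacing[::-1]) + (float(dt) if dt else 1.0,)
    else:
        raise ValueError("only 3D volumes and 4D series are supported")
    if affine is None:
        affine = np.diag(list(spacing[::-1]) + [1.0])
    img = nib.Nifti1Image(disk.astype(np.float32), affine)
    img.header.set_zooms(zooms)
    path = Path(path)
    nib.save(img, str(path))
    return path


def read_volume(path: str | Path) -> tuple[np.ndarray, tuple[float, ...], np.ndarray]:
    """Read a NIfTI volume back into the (z, y, x[, t->front]) convention.

    Returns (data, spacing, affine); spacing is mm per (z, y, x).
    """
    img = nib.load(str(path))
    disk = np.asarray(img.dataobj)
    if disk.ndim == 3:
        data = np.transpose(disk, (2, 1, 0))
    elif disk.ndim == 4:
        data = np.transpose(disk, (3, 2, 1, 0))
    else:
        raise ValueError(f"unsupported NIfTI dimensionality {disk.ndim}")
    zooms = img.header.get_zooms()
    spacing = tuple(float(z) for z in zooms[:3][::-1])
    return data, spacing, img.affine


def write_curves(path: str | Path, vascular: VascularInput) -> Path:
    """Vascular curves as plain text: time_s, aif_hu, vof_hu."""
    path = Path(path)
    arr = np.column_stack([vascular.times, vascular.aif, vascular.vof])
    np.savetxt(path, arr, header="time_s aif_hu vof_hu", fmt="%.6g")
    return path


def read_curves(path: str | Path) -> VascularInput:
    arr = np.loadtxt(path)
    return VascularInput(times=arr[:, 0], aif=arr[:, 1], vof=arr[:, 2])


# --------------------------------------------------------------------------
# cohort CSV
# --------------------------------------------------------------------------


def write_cohort_csv(path: str | Path, records: Sequence[CohortRecord]) -> Path:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(COHORT_HEADER)
        for r in records:
            writer.writerow([
                r.dataset_id,
                f"{r.thr_hypo_ml:.6g}", f"{r.thr_core_ml:.6g}",
                f"{r.mir_hypo_ml:.6g}", f"{r.mir_core_ml:.6g}",
                f"{r.isp_hypo_ml:.6g}", f"{r.isp_core_ml:.6g}",
                f"{r.infarct_ml:.6g}", r.treatment,
            ])
    return path


def read_cohort_csv(path: str | Path) -> list[CohortRecord]:
    records = []
    with Path(path).open(newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(COHORT_HEADER) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"cohort CSV is missing columns: {sorted(missing)}")
        for row in reader:
            records.append(CohortRecord(
                dataset_id=row["id"],
                thr_hypo_ml=float(row["thr_hypo_ml"]),
                thr_core_ml=float(row["thr_core_ml"]),
                mir_hypo_ml=float(row["mir_hypo_ml"]),
                mir_core_ml=float(row["mir_core_ml"]),
                isp_hypo_ml=float(row["isp_hypo_ml"]),
                isp_core_ml=float(row["isp_core_ml"]),
                infarct_ml=float(row["infarct_ml"]),
                treatment=row["treatment"],  # type: ignore[arg-type]
            ))
    return records


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class RunConfig:
    """Resolved parameters of one pipeline run; round-trips through YAML."""

    seed: int = 0
    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    lesion_side: str = "right"
    lesion_radius_mm: float = 10.0
    dt_s: float = 4.0
    duration_s: float = 60.0
    noise_sd_hu: float = 2.0
    maps: MapConfig = field(default_factory=MapConfig)
    algorithms: AlgorithmConfig = field(default_factory=AlgorithmConfig)
    infarct_threshold_hu: float = 25.0
    infarct_min_component_ml: float = 0.5
    followup_brain_hu: float = 35.0
    followup_infarct_hu: float = 20.0
    epsilon_ml: float = 0.0
    write_series: bool = False
    verbosity: int = 0

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        kwargs = dict(raw)
        if "maps" in kwargs and isinstance(kwargs["maps"], dict):
            kwargs["maps"] = MapConfig(**kwargs["maps"])
        if "algorithms" in kwargs and isinstance(kwargs["algorithms"], dict):
            kwargs["algorithms"] = AlgorithmConfig(**kwargs["algorithms"])
        for name in ("shape", "spacing"):
            if name in kwargs:
                kwargs[name] = tuple(kwargs[name])
        return cls(**kwargs)


# --------------------------------------------------------------------------
# end-to-end pipeline
# --------------------------------------------------------------------------


def _lesion_csv_row(result: LesionResult) -> list:
    return [
        result.algorithm, result.side,
        f"{result.hypo_ml:.6g}", f"{result.core_ml:.6g}",
        "" if result.baseline_cbf is None else f"{result.baseline_cbf:.6g}",
        ";".join(result.flags),
    ]


def run_pipeline(config: RunConfig, outdir: str | Path) -> Path:
    """Simulate, map, segment (x3), segment the follow-up infarct, evaluate.

    Writes into ``outdir``: one NIfTI per perfusion map, the vascular
    curves, ``lesions.csv`` (one row per algorithm), ``infarct.csv``,
    ``report.json`` and the resolved ``config.yaml``.  Deterministic given
    the config seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")

    logger.info("simulating phantom %s, lesion %s r=%.1f mm",
                config.shape, config.lesion_side, config.lesion_radius_mm)
    phantom = make_phantom(
        shape=config.shape,
        spacing=config.spacing,
        lesion=LesionSpec(side=config.lesion_side, radius_mm=config.lesion_radius_mm),  # type: ignore[arg-type]
        seed=config.seed,
    )
    series, vascular = simulate_series(
        phantom,
        dt=config.dt_s,
        duration=config.duration_s,
        noise_sd=config.noise_sd_hu,
        k=config.maps.k,
        seed=config.seed,
    )
    write_curves(outdir / "vascular.txt", vascular)
    if config.write_series:
        write_volume(outdir / "series.nii.gz", series.data, config.spacing, dt=config.dt_s)

    maps = compute_perfusion_maps(series, vascular, config.maps)
    for name in ("cbf", "cbv", "mtt", "ttp", "tmax", "cth"):
        arr = getattr(maps, name)
        if arr is not None:
            write_volume(outdir / f"{name}.nii.gz", arr, config.spacing)

    cfg_alg = config.algorithms
    logger.info(
        "segmenting with Tmax > %.1f s, rCBF < %.2f, rMTT > %.2f, CBV cutoff %.1f "
        "mL/100 g, ISP dialect %s",
        cfg_alg.tmax_threshold_s, cfg_alg.rcbf_fraction, cfg_alg.rmtt_threshold,
        cfg_alg.cbv_cutoff, cfg_alg.isp_dialect,
    )
    labels = split_hemispheres(phantom.brain_mask)
    relative = compute_relative_maps(maps, labels)
    results = [
        segment.segment_cercare_threshold(maps, labels, config.algorithms),
        segment.segment_cercare_mirror(maps, labels, config.algorithms),
        segment.segment_isp(maps, relative, labels, config.algorithms),
    ]
    with (outdir / "lesions.csv").open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["algorithm", "side", "hypo_ml", "core_ml", "baseline_cbf", "flags"])
        for result in results:
            logger.info("%s: hypoperfused %.2f mL, core %.2f mL (flags: %s)",
                        result.algorithm, result.hypo_ml, result.core_ml,
                        ",".join(result.flags) or "-")
            writer.writerow(_lesion_csv_row(result))

    followup = simulate_followup_ct(
        phantom,
        brain_hu=config.followup_brain_hu,
        infarct_hu=config.followup_infarct_hu,
        noise_sd=0.0,
    )
    infarct = segment_infarct(
        followup, phantom.brain_mask, config.spacing,
        threshold_hu=config.infarct_threshold_hu,
        min_component_ml=config.infarct_min_component_ml,
    )
    logger.info("follow-up infarct: %.2f mL below %.0f HU", infarct.volume_ml, infarct.threshold_hu)
    with (outdir / "infarct.csv").open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["infarct_ml", "threshold_hu", "n_components"])
        writer.writerow([f"{infarct.volume_ml:.6g}", f"{infarct.threshold_hu:.6g}", infarct.n_components])

    report = {
        "seed": config.seed,
        "infarct_ml": infarct.volume_ml,
        "algorithms": {
            r.algorithm: {
                "side": r.side,
                "hypoperfused_ml": r.hypo_ml,
                "core_ml": r.core_ml,
                "baseline_cbf": r.baseline_cbf,
                "flags": list(r.flags),
                "category": {
                    "hypoperfused": classify_prediction(r.hypo_ml, infarct.volume_ml, config.epsilon_ml).value,
                    "core": classify_prediction(r.core_ml, infarct.volume_ml, config.epsilon_ml).value,
                },
            }
            for r in results
        },
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    return outdir


def evaluate_cohort_file(
    path: str | Path,
    outdir: str | Path,
    stratifications: Sequence[str] = ("overall",),
    epsilon: float = 0.0,
) -> Path:
    """Evaluate a cohort CSV; write a JSON report and a per-cell CSV."""
    records = read_cohort_csv(path)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reports = {s: evaluate_cohort(records, s, epsilon).to_dict() for s in stratifications}  # type: ignore[arg-type]
    (outdir / "evaluation.json").write_text(json.dumps(reports, indent=2))
    with (outdir / "evaluation.csv").open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["stratum", "algorithm", "compartment",
                         "no_abnormality", "underestimated", "reversible", "progressive",
                         "sensitivity_pct", "specificity_pct", "ppv_pct", "npv_pct"])
        for stratum, rep in reports.items():
            for algorithm, comps in rep["cells"].items():
                for compartment, cell in comps.items():
                    m = cell["metrics_percent"]
                    writer.writerow([stratum, algorithm, compartment, *cell["counts"],
                                     m["sensitivity"], m["specificity"], m["ppv"], m["npv"]])
    return outdir
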