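"""Single-frame, batch, and longitudinal wiring of the full pipeline.

Each run mirrors the clinical workflow: read the frame, segment the patient
(trained model, or a supplied mask for validation runs), isolate bare skin and
correct occlusions, compute the energy report, classify against the reference
table, and write artifacts.  Stages communicate only through the declared
types (ThermalFrame, LabelMask, HeatPartition, EnergyReport).
"""

from __future__ import annotations

import dataclasses
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import cohort, energetics, heat, segmentation
from .io import (
    EnergyReport,
    LabelMask,
    PatientRecord,
    ThermalFrame,
    read_frame,
    read_mask,
    reports_to_frame,
    write_mask,
    write_report,
)

__all__ = ["RunConfig", "run_single", "run_batch", "run_monitor", "grayscale_render"]

log = logging.getLogger("thermotee")


@dataclasses.dataclass
class RunConfig:
    """Everything a pipeline run needs; referenced paths must exist at launch."""

    mode: str = "single"  # single | batch | monitor
    frame_path: Path | None = None
    frames_dir: Path | None = None
    dialect: str = "csv_celsius"
    model_path: Path | None = None  # trained segmentation weights (.npz)
    mask_path: Path | None = None  # ground-truth mask bypassing the model
    out_dir: Path = Path("thermotee_out")
    k: int = 2
    material: heat.MaterialSpec = heat.MaterialSpec("fleece-blanket", 0.15)
    constants: energetics.PhysicsConstants = energetics.DEFAULT_CONSTANTS
    reference: energetics.ReferenceTable = dataclasses.field(
        default_factory=energetics.ReferenceTable
    )
    include_corrected: bool = False
    seed: int = 0

    def validate_paths(self) -> None:
        for p in (self.frame_path, self.frames_dir, self.model_path, self.mask_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured path does not exist: {p}")


def grayscale_render(frame: ThermalFrame) -> np.ndarray:
    """Min-max normalized 8-bit rendering for human inspection only.

    Never an input to computation: the pipeline always works on the
    temperature matrix itself.
    """
    t = frame.filled().temps
    lo, hi = float(t.min()), float(t.max())
    span = hi - lo if hi > lo else 1.0
    return np.round(255.0 * (t - lo) / span).astype(np.uint8)


def _segment(cfg: RunConfig, frame: ThermalFrame) -> LabelMask:
    if cfg.mask_path is not None:
        return read_mask(cfg.mask_path)
    if cfg.model_path is None:
        raise ValueError("either a trained model or a mask path is required")
    model = segmentation.SegModel.load(cfg.model_path)
    return segmentation.predict(model, frame)


def _analyse(
    cfg: RunConfig, frame: ThermalFrame, mask: LabelMask, patient: PatientRecord
) -> tuple[EnergyReport, heat.HeatPartition]:
    partition = heat.partition_and_correct(
        frame, mask, material=cfg.material, k=cfg.k, seed=cfg.seed,
        constants=cfg.constants,
    )
    report = energetics.full_energy_report(
        frame, partition, patient,
        constants=cfg.constants, reference=cfg.reference,
        include_corrected=cfg.include_corrected,
    )
    return report, partition


def run_single(
    cfg: RunConfig,
    patient: PatientRecord,
    frame: ThermalFrame | None = None,
    mask: LabelMask | None = None,
) -> EnergyReport:
    """Analyse one frame; writes rendering, masks and a one-row report.

    The patient record is mandatory — weight, age and sex are required to
    turn radiative power into TEE (the caller constructs :class:`PatientRecord`
    which enforces that).
    """
    cfg.validate_paths()
    t0 = time.perf_counter()
    if frame is None:
        frame = read_frame(cfg.frame_path, cfg.dialect)  # type: ignore[arg-type]
    if mask is None:
        mask = _segment(cfg, frame)
    report, partition = _analyse(cfg, frame, mask, patient)

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stem = report.frame_id or "frame"
    Image.fromarray(grayscale_render(frame), mode="L").save(out / f"{stem}_gray.png")
    write_mask(mask, out / f"{stem}_mask.png")
    bare = LabelMask(labels=partition.bare_mask.astype(np.uint8))
    write_mask(bare, out / f"{stem}_bare.png")
    write_report([(report, patient)], out / f"{stem}_report.csv", format="csv")
    log.info("frame=%s stage=single duration=%.3fs flags=%s",
             stem, time.perf_counter() - t0, ",".join(report.flags) or "-")
    return report


def run_batch(
    cfg: RunConfig,
    metadata: pd.DataFrame,
    report_path: Path | None = None,
    report_format: str = "csv",
    with_stats: bool = False,
    mu0: float = 1500.0,
) -> tuple[pd.DataFrame, "cohort.CohortSummary | None"]:
    """Analyse a directory of frames; one report row per frame.

    ``metadata`` needs columns ``frame_id, weight_kg, age_years, sex`` and
    optionally ``mask_path``.  Frames that fail to parse or analyse are
    logged and skipped; a summary count is emitted at the end.
    """
    cfg.validate_paths()
    frames_dir = Path(cfg.frames_dir)  # type: ignore[arg-type]
    suffix = ".csv" if cfg.dialect == "csv_celsius" else ".tiff"
    frame_files = sorted(p for p in frames_dir.iterdir()
                         if p.suffix == suffix and not p.name.endswith(".meta"))
    if not frame_files:
        raise FileNotFoundError(f"no {suffix} frames in {frames_dir}")
    meta = metadata.set_index("frame_id")

    rows: list[tuple[EnergyReport, PatientRecord]] = []
    failures = 0
    for path in frame_files:
        try:
            frame = read_frame(path, cfg.dialect)
            rec = meta.loc[frame.frame_id]
            patient = PatientRecord(
                weight_kg=float(rec["weight_kg"]),
                age_years=float(rec["age_years"]),
                sex=str(rec["sex"]),
            )
            if "mask_path" in rec and isinstance(rec["mask_path"], str) and rec["mask_path"]:
                mask = read_mask(rec["mask_path"])
            else:
                mask = _segment(cfg, frame)
            report, _ = _analyse(cfg, frame, mask, patient)
            rows.append((report, patient))
        except Exception as exc:  # noqa: BLE001 - batch mode logs and skips
            failures += 1
            log.warning("frame=%s stage=batch failed: %s", path.name, exc)
    log.info("batch done: %d analysed, %d failed", len(rows), failures)
    if not rows:
        raise RuntimeError("batch produced no successful analyses")

    if report_path is not None:
        write_report(rows, report_path, format=report_format)  # type: ignore[arg-type]
    table = reports_to_frame(rows)
    summary = cohort.cohort_run(table, mu0=mu0) if with_stats else None
    return table, summary


def run_monitor(
    cfg: RunConfig,
    patient: PatientRecord,
    frames: list[ThermalFrame] | None = None,
    masks: list[LabelMask] | None = None,
) -> pd.DataFrame:
    """Longitudinal mode: a time-ordered TEE series with per-interval deltas.

    Needs >= 2 timestamped frames of one patient; duplicate timestamps are an
    error, out-of-order input is sorted.
    """
    cfg.validate_paths()
    if frames is None:
        frames_dir = Path(cfg.frames_dir)  # type: ignore[arg-type]
        suffix = ".csv" if cfg.dialect == "csv_celsius" else ".tiff"
        frames = [read_frame(p, cfg.dialect) for p in sorted(frames_dir.iterdir())
                  if p.suffix == suffix]
    if len(frames) < 2:
        raise ValueError("longitudinal monitoring needs at least 2 frames")
    stamps = [f.acquired_at for f in frames]
    if any(s is None for s in stamps):
        raise ValueError("every frame needs an acquired_at timestamp")
    if len(set(stamps)) != len(stamps):
        raise ValueError("duplicate timestamps in the monitoring series")

    order = np.argsort(np.array(stamps, dtype="datetime64[s]"))
    rows = []
    for j, i in enumerate(order):
        frame = frames[i]
        mask = masks[i] if masks is not None else _segment(cfg, frame)
        report, _ = _analyse(cfg, frame, mask, patient)
        rows.append({
            "acquired_at": stamps[i],
            "frame_id": frame.frame_id,
            "mean_skin_c": report.mean_skin_c,
            "tee_area": report.tee_area,
            "tee_total": report.tee_total,
        })
    df = pd.DataFrame(rows)
    df["tee_area_delta"] = df["tee_area"].diff()
    return df
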