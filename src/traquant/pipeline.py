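"""End-to-end pipeline: dataset discovery, per-patient processing, outputs.

A dataset is a directory tree ``<root>/<patient>/field_XX/{dapi,cd45,tra}.tif``
with controls under ``<root>/<patient>/control/control_XX/``; an optional
``manifest.csv`` at the root supplies group labels.  The pipeline is fully
deterministic given the inputs and configuration: re-running it produces
byte-identical CSV/JSON outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .cohort import normalize_cd45, summarize_cohort
from .config import PipelineConfig
from .diagnostics import run_comparisons
from .quantify import Calibration, calibrate, process_field, segment_field
from .synthdata import CHANNELS, Field

__all__ = [
    "PatientData",
    "discover_dataset",
    "load_field",
    "process_patient",
    "run_pipeline",
    "save_overlay",
]

logger = logging.getLogger("traquant")


@dataclass
class PatientData:
    """Paths to one patient's stained and control fields."""

    patient_id: str
    group: str
    field_dirs: list[Path] = field(default_factory=list)
    control_dirs: list[Path] = field(default_factory=list)


def _channel_paths(directory: Path) -> dict[str, Path] | None:
    paths = {name: directory / f"{name}.tif" for name in CHANNELS}
    if all(p.exists() for p in paths.values()):
        return paths
    return None


def load_field(directory: Path) -> Field:
    """Read the three grayscale TIFF channels of one field."""
    paths = _channel_paths(Path(directory))
    if paths is None:
        raise FileNotFoundError(f"missing channel TIFF in {directory}")
    arrays = {}
    for name, p in paths.items():
        a = tifffile.imread(p)
        if a.ndim != 2:
            raise ValueError(f"{p} is not a single-plane grayscale image")
        arrays[name] = a
    return Field(dapi=arrays["dapi"], cd45=arrays["cd45"], tra=arrays["tra"])


def discover_dataset(root: str | Path) -> list[PatientData]:
    """Scan a cohort directory tree; group labels come from manifest.csv."""
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset directory {root} does not exist")
    groups: dict[str, str] = {}
    manifest = root / "manifest.csv"
    if manifest.exists():
        m = pd.read_csv(manifest)
        groups = dict(zip(m["patient_id"].astype(str), m["group"].astype(str)))
    patients = []
    for pdir in sorted(p for p in root.iterdir() if p.is_dir()):
        field_dirs = sorted(
            d for d in pdir.iterdir() if d.is_dir() and d.name != "control"
        )
        cdir = pdir / "control"
        control_dirs = (
            sorted(d for d in cdir.iterdir() if d.is_dir()) if cdir.is_dir() else []
        )
        if not field_dirs and not control_dirs:
            continue
        patients.append(
            PatientData(
                patient_id=pdir.name,
                group=groups.get(pdir.name, "unknown"),
                field_dirs=field_dirs,
                control_dirs=control_dirs,
            )
        )
    if not patients:
        raise FileNotFoundError(f"no patient directories under {root}")
    return patients


def process_patient(
    pdata: PatientData,
    cfg: PipelineConfig | None = None,
    overlay_dir: Path | None = None,
) -> tuple[pd.DataFrame, Calibration]:
    """Calibrate on the patient's controls, then measure every field.

    Fields with a missing channel are skipped with a logged warning; a
    patient without fields raises, one without usable controls raises
    (callers may catch and exclude the patient).
    """
    cfg = cfg or PipelineConfig()
    if not pdata.field_dirs:
        raise ValueError(f"patient {pdata.patient_id}: no stained fields")
    controls = []
    for d in pdata.control_dirs:
        if _channel_paths(d) is None:
            logger.warning("patient %s: skipping control %s (missing channel)",
                           pdata.patient_id, d.name)
            continue
        controls.append(load_field(d))
    if not controls:
        raise ValueError(f"patient {pdata.patient_id}: no usable control fields")
    cal = calibrate(controls, cfg, patient_id=pdata.patient_id)

    frames = []
    for i, d in enumerate(pdata.field_dirs, start=1):
        if _channel_paths(d) is None:
            logger.warning("patient %s: skipping field %s (missing channel)",
                           pdata.patient_id, d.name)
            continue
        fld = load_field(d)
        seg = segment_field(fld, cfg)
        frames.append(
            process_field(
                fld, cal, cfg, patient_id=pdata.patient_id, field_index=i,
                segmented=seg,
            )
        )
        if overlay_dir is not None:
            save_overlay(
                fld, seg, cal, cfg, overlay_dir / f"{pdata.patient_id}_{d.name}.png"
            )
    if not frames:
        raise ValueError(f"patient {pdata.patient_id}: no usable stained fields")
    records = pd.concat(frames, ignore_index=True)
    logger.info(
        "patient %s: %d cells, %d TRA+ (threshold %.1f)",
        pdata.patient_id, len(records), int(records["tra_positive"].sum()),
        cal.tra_threshold,
    )
    return records, cal


def run_pipeline(
    data_dir: str | Path,
    out_dir: str | Path,
    cfg: PipelineConfig | None = None,
    overlays: bool = False,
    plan: list[tuple[str, str, str]] | None = None,
) -> dict[str, Path]:
    """Run every stage over a dataset and write the standard outputs.

    Produces per-patient ``cells.csv`` and ``calibration.json``, plus
    cohort-level ``patients.csv``, ``roc.csv`` and ``run.log`` under
    ``out_dir``.  Patients without usable controls are excluded with a
    logged error; ROC comparisons that cannot be computed (e.g. too few
    included patients in a small dataset) become NaN rows with a note.
    """
    cfg = cfg or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        import scipy
        import skimage

        logger.info("config: %s", cfg)
        logger.info(
            "versions: numpy %s scipy %s skimage %s pandas %s",
            np.__version__, scipy.__version__, skimage.__version__, pd.__version__,
        )
        patients = discover_dataset(data_dir)
        records_by_patient: dict[str, pd.DataFrame] = {}
        groups: dict[str, str] = {}
        calibrations: dict[str, Calibration] = {}
        overlay_dir = out / "overlays" if overlays else None
        if overlay_dir is not None:
            overlay_dir.mkdir(exist_ok=True)
        for pdata in patients:
            try:
                records, cal = process_patient(pdata, cfg, overlay_dir)
            except ValueError as exc:
                if "control" in str(exc):
                    logger.error("excluding patient %s: %s", pdata.patient_id, exc)
                    continue
                raise
            records_by_patient[pdata.patient_id] = records
            groups[pdata.patient_id] = pdata.group
            calibrations[pdata.patient_id] = cal
            pout = out / pdata.patient_id
            pout.mkdir(exist_ok=True)
            normalize_cd45(records).to_csv(pout / "cells.csv", index=False)
            (pout / "calibration.json").write_text(
                json.dumps(
                    {
                        "patient_id": cal.patient_id,
                        "tra_threshold": cal.tra_threshold,
                        "cd45_background": cal.cd45_background,
                        "n_control_fields": cal.n_control_fields,
                    },
                    indent=2,
                )
            )

        if not records_by_patient:
            raise ValueError("no patient could be processed")
        summaries = summarize_cohort(records_by_patient, groups, cfg, calibrations)
        summaries.to_csv(out / "patients.csv", index=False)

        known_groups = set(groups.values())
        roc_path = None
        plan_groups = {g for row in (plan or []) for g in row[1:]} or {
            "healthy", "localized", "metastatic",
        }
        if plan_groups & known_groups:
            roc_table = run_comparisons(summaries, plan=plan, cfg=cfg, strict=False)
            for _, row in roc_table.iterrows():
                if row["note"]:
                    logger.warning("roc: %s", row["note"])
            roc_path = out / "roc.csv"
            roc_table.to_csv(roc_path, index=False)

        outputs = {
            "patients": out / "patients.csv",
            "log": log_path,
        }
        if roc_path is not None:
            outputs["roc"] = roc_path
        return outputs
    finally:
        logger.removeHandler(handler)
        handler.close()


def save_overlay(field: Field, seg, cal: Calibration, cfg: PipelineConfig, path: Path):
    """QC overlay: DAPI grayscale, nuclei outlines, TRA+ cells circled."""
    from skimage.draw import circle_perimeter
    from skimage.segmentation import find_boundaries
    import imageio.v3 as iio
    from scipy import ndimage as ndi

    from .quantify import call_tra

    dapi = np.asarray(field.dapi, dtype=float)
    lo, hi = dapi.min(), dapi.max()
    base = ((dapi - lo) / (hi - lo + 1e-12) * 255).astype(np.uint8)
    rgb = np.stack([base] * 3, axis=-1)
    rgb[find_boundaries(seg.seeds.labels)] = (0, 255, 0)
    calls = call_tra(field.tra, seg.cells, cal.tra_threshold, cfg)
    pos_labels = calls.loc[calls["tra_positive"], "cell_label"].to_numpy()
    if len(pos_labels):
        centroids = ndi.center_of_mass(
            seg.cells.labels > 0, seg.cells.labels, pos_labels
        )
        for (r, c), lab in zip(centroids, pos_labels):
            radius = int(np.sqrt(seg.cells.areas_px[lab - 1] / np.pi)) + 3
            rr, cc = circle_perimeter(
                int(r), int(c), radius, shape=rgb.shape[:2]
            )
            rgb[rr, cc] = (255, 255, 0)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, rgb)
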