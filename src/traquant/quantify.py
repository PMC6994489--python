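"""Per-cell marker quantification and negative-control calibration.

The TRA-1-60 detection threshold is set per patient from secondary-
antibody-only control fields: the smallest intensity at which the full
calling rule (strictly suprathreshold pixels, at least ``min_tra_pixels``
of them inside a cell mask) yields zero TRA+ detections on every control
field.  CD45 is measured as the mean raw intensity inside each dilated
cell mask; its staining background is quantified from the same control
fields and reported separately rather than subtracted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .config import PipelineConfig
from .segmentation import CellLabelMap, SeedLabelMap, dilated_cell_mask, preprocess_dapi, segment_nuclei
from .synthdata import Field

__all__ = [
    "Calibration",
    "SegmentedField",
    "segment_field",
    "calibrate_tra_threshold",
    "call_tra",
    "measure_cd45",
    "measure_cd45_background",
    "calibrate",
    "process_field",
]


@dataclass
class Calibration:
    """Per-patient calibration derived from negative controls."""

    tra_threshold: float
    cd45_background: float
    n_control_fields: int
    patient_id: str | None = None

    def __post_init__(self) -> None:
        if self.cd45_background < 0:
            raise ValueError("cd45_background must be >= 0")
        if self.n_control_fields < 1:
            raise ValueError("n_control_fields must be >= 1")


@dataclass
class SegmentedField:
    """A field together with its segmentation products."""

    field: Field
    seeds: SeedLabelMap
    cells: CellLabelMap


def segment_field(field: Field, cfg: PipelineConfig | None = None) -> SegmentedField:
    """Run the DAPI segmentation chain on one field."""
    cfg = cfg or PipelineConfig()
    prep = preprocess_dapi(field.dapi, cfg)
    seeds = segment_nuclei(prep, cfg)
    cells = dilated_cell_mask(prep, seeds, cfg)
    return SegmentedField(field=field, seeds=seeds, cells=cells)


def _per_cell_sorted_tra(
    tra: np.ndarray, cells: CellLabelMap
) -> tuple[np.ndarray, np.ndarray]:
    """TRA values inside cell masks, sorted within each label.

    Returns ``(boundaries, sorted_values)`` where cell ``i`` (label i+1)
    owns ``sorted_values[boundaries[i]:boundaries[i+1]]`` ascending.
    """
    flat_labels = cells.labels.ravel()
    sel = flat_labels > 0
    labs = flat_labels[sel]
    vals = np.asarray(tra).ravel()[sel]
    order = np.lexsort((vals, labs))
    labs, vals = labs[order], vals[order]
    counts = np.bincount(labs, minlength=cells.n_labels + 1)[1:]
    boundaries = np.concatenate([[0], np.cumsum(counts)])
    return boundaries, vals


def calibrate_tra_threshold(
    control_fields: list[Field],
    cfg: PipelineConfig | None = None,
    mode: str | None = None,
) -> float:
    """Smallest threshold with zero TRA+ detections on all controls.

    In ``"detection"`` mode (default) a cell triggers only when at least
    ``min_tra_pixels`` of its pixels are strictly above T, so T is the
    largest ``min_tra_pixels``-th-greatest TRA value over all control
    cells.  In ``"pixel"`` mode T is simply the maximum control TRA value
    inside any cell mask.  Either way, re-calling the controls at T gives
    exactly zero TRA+ cells.
    """
    cfg = cfg or PipelineConfig()
    mode = mode or cfg.calibration_mode
    if mode not in ("detection", "pixel"):
        raise ValueError("mode must be 'detection' or 'pixel'")
    if not control_fields:
        raise ValueError("at least one control field is required")

    k = cfg.min_tra_pixels
    threshold = 0.0
    any_cells = False
    saturation = None
    for fld in control_fields:
        if np.issubdtype(np.asarray(fld.tra).dtype, np.integer):
            saturation = np.iinfo(np.asarray(fld.tra).dtype).max
        seg = segment_field(fld, cfg)
        if seg.cells.n_labels == 0:
            continue
        any_cells = True
        boundaries, vals = _per_cell_sorted_tra(fld.tra, seg.cells)
        for i in range(seg.cells.n_labels):
            cell_vals = vals[boundaries[i] : boundaries[i + 1]]
            if mode == "pixel":
                cand = float(cell_vals[-1]) if len(cell_vals) else 0.0
            else:
                if len(cell_vals) < k:
                    continue  # can never reach min_tra_pixels detections
                cand = float(cell_vals[-k])
            threshold = max(threshold, cand)
    if not any_cells:
        raise ValueError("no segmentable nuclei in any control field")
    if saturation is not None and threshold >= saturation:
        raise ValueError(
            "control TRA channel saturated: no threshold can zero the controls"
        )
    return threshold


def call_tra(
    tra: np.ndarray,
    cells: CellLabelMap,
    threshold: float,
    cfg: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Count strictly suprathreshold TRA pixels per cell and call TRA+.

    Returns a frame with ``cell_label``, ``tra_pixel_count`` and
    ``tra_positive`` (count >= ``min_tra_pixels``).
    """
    cfg = cfg or PipelineConfig()
    tra = np.asarray(tra)
    if tra.shape != cells.labels.shape:
        raise ValueError("raster/label shape mismatch")
    above = tra > threshold
    counts = np.bincount(
        cells.labels[above].ravel(), minlength=cells.n_labels + 1
    )[1:]
    return pd.DataFrame(
        {
            "cell_label": np.arange(1, cells.n_labels + 1),
            "tra_pixel_count": counts.astype(int),
            "tra_positive": counts >= cfg.min_tra_pixels,
        }
    )


def measure_cd45(cd45: np.ndarray, cells: CellLabelMap) -> np.ndarray:
    """Mean raw CD45 intensity inside each dilated cell mask."""
    cd45 = np.asarray(cd45, dtype=float)
    if cd45.shape != cells.labels.shape:
        raise ValueError("raster/label shape mismatch")
    if cells.n_labels == 0:
        return np.zeros(0)
    if (cells.areas_px == 0).any():
        raise ValueError("zero-area cell label")
    return np.asarray(
        ndi.mean(cd45, labels=cells.labels, index=np.arange(1, cells.n_labels + 1))
    )


def measure_cd45_background(
    control_fields: list[Field], cfg: PipelineConfig | None = None
) -> float:
    """CD45 staining background: mean of per-cell CD45 means on controls."""
    cfg = cfg or PipelineConfig()
    if not control_fields:
        raise ValueError("at least one control field is required")
    per_cell: list[np.ndarray] = []
    for fld in control_fields:
        seg = segment_field(fld, cfg)
        if seg.cells.n_labels:
            per_cell.append(measure_cd45(fld.cd45, seg.cells))
    if not per_cell:
        raise ValueError("no segmentable nuclei in any control field")
    return float(np.concatenate(per_cell).mean())


def calibrate(
    control_fields: list[Field],
    cfg: PipelineConfig | None = None,
    patient_id: str | None = None,
) -> Calibration:
    """TRA threshold and CD45 background from one pass over the controls."""
    cfg = cfg or PipelineConfig()
    return Calibration(
        tra_threshold=calibrate_tra_threshold(control_fields, cfg),
        cd45_background=measure_cd45_background(control_fields, cfg),
        n_control_fields=len(control_fields),
        patient_id=patient_id,
    )


def process_field(
    field: Field,
    calibration: Calibration,
    cfg: PipelineConfig | None = None,
    patient_id: str | None = None,
    field_index: int | None = None,
    segmented: SegmentedField | None = None,
) -> pd.DataFrame:
    """Segment one stained field and measure every cell.

    Returns one row per cell with nucleus/cell areas, the TRA pixel count
    and call, and the raw CD45 mean (``cd45_norm`` is filled later at the
    patient level).
    """
    cfg = cfg or PipelineConfig()
    seg = segmented or segment_field(field, cfg)
    n = seg.cells.n_labels
    if n == 0:
        return pd.DataFrame(
            columns=[
                "patient_id",
                "field_index",
                "cell_label",
                "nucleus_area_px",
                "cell_area_px",
                "tra_pixel_count",
                "tra_positive",
                "cd45_mean",
            ]
        )
    calls = call_tra(field.tra, seg.cells, calibration.tra_threshold, cfg)
    records = pd.DataFrame(
        {
            "patient_id": patient_id,
            "field_index": field_index,
            "cell_label": calls["cell_label"],
            "nucleus_area_px": seg.seeds.areas_px.astype(int),
            "cell_area_px": seg.cells.areas_px.astype(int),
            "tra_pixel_count": calls["tra_pixel_count"],
            "tra_positive": calls["tra_positive"],
            "cd45_mean": measure_cd45(field.cd45, seg.cells),
        }
    )
    return records
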