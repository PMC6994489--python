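"""Shared fixtures.

The expensive fixture is a processed 57-patient desk-scale synthetic
cohort, built once per session and shared by the calibration-, recovery-
and ROC-level tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

import traquant as tq
from traquant.pipeline import discover_dataset, process_patient


@pytest.fixture()
def cfg() -> tq.PipelineConfig:
    return tq.PipelineConfig()


@pytest.fixture()
def small_field():
    """One 256-px field with a handful of cells of every class."""
    spec = tq.FieldSpec(height_px=256, width_px=256, n_cells=12, rng_seed=42)
    return tq.generate_field(spec, tra_fraction=0.4, cd45low_given_tra=0.5)


@dataclass
class ProcessedCohort:
    truth: tq.GroundTruth
    records: dict[str, pd.DataFrame]
    calibrations: dict[str, tq.Calibration]
    groups: dict[str, str]
    summaries: pd.DataFrame
    controls: dict[str, list]  # patient_id -> control Fields (reloaded)


@pytest.fixture(scope="session")
def desk_cohort(tmp_path_factory) -> ProcessedCohort:
    """Default 57-patient cohort at desk scale, generated and processed."""
    root = tmp_path_factory.mktemp("cohort")
    design = tq.default_cohort_design(preset="desk", master_seed=11)
    truth = tq.generate_cohort(design, root, master_seed=11)
    cfg = tq.PipelineConfig()
    records, cals, groups, controls = {}, {}, {}, {}
    for pdata in discover_dataset(root):
        rec, cal = process_patient(pdata, cfg)
        records[pdata.patient_id] = rec
        cals[pdata.patient_id] = cal
        groups[pdata.patient_id] = pdata.group
        controls[pdata.patient_id] = [tq.load_field(d) for d in pdata.control_dirs]
    summaries = tq.summarize_cohort(records, groups, cfg, cals)
    return ProcessedCohort(
        truth=truth,
        records=records,
        calibrations=cals,
        groups=groups,
        summaries=summaries,
        controls=controls,
    )


def make_records(
    tra_flags: list[bool],
    cd45_means: list[float],
    field_index: list[int] | None = None,
) -> pd.DataFrame:
    """Hand-built cell-record table for the cohort-measure unit tests."""
    n = len(tra_flags)
    return pd.DataFrame(
        {
            "patient_id": "T",
            "field_index": field_index if field_index is not None else [1] * n,
            "cell_label": np.arange(1, n + 1),
            "nucleus_area_px": 100,
            "cell_area_px": 200,
            "tra_pixel_count": [10 if t else 0 for t in tra_flags],
            "tra_positive": tra_flags,
            "cd45_mean": cd45_means,
        }
    )
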