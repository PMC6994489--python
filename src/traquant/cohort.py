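"""Patient-level measurements.

Three measurements summarise each patient:

1. the percentage of TRA+ cells per imaged field (mean and SD over
   fields);
2. the number of cells that are both TRA+ and CD45-low, normalised per
   1000 analysed cells, where "low" means a normalised CD45 level below a
   cutoff (0.3 by default) and normalisation divides each cell's mean CD45
   by the patient's mean over TRA- cells;
3. the difference between the mean normalised CD45 of TRA+ cells and that
   of TRA- cells (which is 1 by construction) — computed only for patients
   with at least ``min_tra_cells_for_diff`` TRA+ cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PipelineConfig

__all__ = [
    "PatientSummary",
    "percent_tra",
    "normalize_cd45",
    "cd45low_per_1000",
    "cd45_difference",
    "summarize_patient",
    "summarize_cohort",
]


@dataclass
class PatientSummary:
    """The per-patient measurements plus calibration context."""

    patient_id: str
    group: str
    n_fields: int
    n_cells: int
    n_tra_pos: int
    mean_pct_tra: float
    sd_pct_tra: float
    mean_cd45_tra_neg: float
    cd45low_count: int
    cd45low_per_1000: float
    cd45_diff: float | None  # None when too few TRA+ cells
    included_in_diff: bool
    tra_threshold: float | None = None
    cd45_background: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean_pct_tra <= 100.0:
            raise ValueError("mean_pct_tra must lie in [0, 100]")
        if not 0.0 <= self.cd45low_per_1000 <= 1000.0:
            raise ValueError("cd45low_per_1000 must lie in [0, 1000]")
        if self.cd45low_count > self.n_tra_pos:
            raise ValueError("cd45low_count cannot exceed n_tra_pos")
        if self.included_in_diff != (self.cd45_diff is not None):
            raise ValueError("cd45_diff must be present iff included_in_diff")


def percent_tra(
    records: pd.DataFrame, cfg: PipelineConfig | None = None
) -> tuple[pd.Series, float, float]:
    """Per-field TRA+ percentage, with mean and SD over fields.

    The SD is taken over the n imaged fields (population SD by default;
    ``cfg.pct_sd_ddof`` switches the estimator).
    """
    cfg = cfg or PipelineConfig()
    if len(records) == 0:
        raise ValueError("no cell records")
    grouped = records.groupby("field_index")
    sizes = grouped.size()
    if (sizes == 0).any():
        raise ValueError("every field must contain at least one cell")
    per_field = 100.0 * grouped["tra_positive"].sum() / sizes
    return per_field, float(per_field.mean()), float(per_field.std(ddof=cfg.pct_sd_ddof))


def normalize_cd45(records: pd.DataFrame) -> pd.DataFrame:
    """Fill ``cd45_norm``: CD45 means divided by the TRA- cell average.

    TRA- cells therefore average to exactly 1 on the normalised scale,
    putting all three measurements in one unit system.
    """
    neg = records.loc[~records["tra_positive"], "cd45_mean"]
    if len(neg) == 0:
        raise ValueError("no TRA-negative cells: cannot normalize CD45")
    denom = float(neg.mean())
    if denom <= 0:
        raise ValueError("TRA-negative CD45 mean is zero")
    out = records.copy()
    out["cd45_norm"] = out["cd45_mean"] / denom
    return out


def cd45low_per_1000(
    records: pd.DataFrame, cfg: PipelineConfig | None = None
) -> tuple[int, float]:
    """Count of TRA+/CD45-low cells and its rate per 1000 analysed cells.

    "Low" is strict: ``cd45_norm < cfg.cd45low_cutoff``.
    """
    cfg = cfg or PipelineConfig()
    if "cd45_norm" not in records:
        raise ValueError("run normalize_cd45 first")
    count = int(
        (records["tra_positive"] & (records["cd45_norm"] < cfg.cd45low_cutoff)).sum()
    )
    rate = 1000.0 * count / len(records) if len(records) else 0.0
    return count, rate


def cd45_difference(
    records: pd.DataFrame, cfg: PipelineConfig | None = None
) -> float | None:
    """Mean normalised CD45 of TRA+ cells minus that of TRA- cells.

    Positive when TRA+ cells carry more CD45 than the TRA- average (the
    healthy pattern), negative when less (the metastatic-like pattern).
    Returns ``None`` for patients with fewer than
    ``cfg.min_tra_cells_for_diff`` TRA+ cells.
    """
    cfg = cfg or PipelineConfig()
    if "cd45_norm" not in records:
        raise ValueError("run normalize_cd45 first")
    pos = records.loc[records["tra_positive"], "cd45_norm"]
    if len(pos) < cfg.min_tra_cells_for_diff:
        return None
    neg = records.loc[~records["tra_positive"], "cd45_norm"]
    return float(pos.mean() - neg.mean())


def summarize_patient(
    records: pd.DataFrame,
    cfg: PipelineConfig | None = None,
    patient_id: str = "",
    group: str = "",
    tra_threshold: float | None = None,
    cd45_background: float | None = None,
) -> PatientSummary:
    """Compute all three measurements for one patient's cell records."""
    cfg = cfg or PipelineConfig()
    if len(records) == 0:
        raise ValueError(f"patient {patient_id!r}: no cell records")
    records = normalize_cd45(records)
    _, mean_pct, sd_pct = percent_tra(records, cfg)
    count, rate = cd45low_per_1000(records, cfg)
    diff = cd45_difference(records, cfg)
    neg_mean = float(records.loc[~records["tra_positive"], "cd45_mean"].mean())
    return PatientSummary(
        patient_id=patient_id,
        group=group,
        n_fields=records["field_index"].nunique(),
        n_cells=len(records),
        n_tra_pos=int(records["tra_positive"].sum()),
        mean_pct_tra=mean_pct,
        sd_pct_tra=sd_pct,
        mean_cd45_tra_neg=neg_mean,
        cd45low_count=count,
        cd45low_per_1000=rate,
        cd45_diff=diff,
        included_in_diff=diff is not None,
        tra_threshold=tra_threshold,
        cd45_background=cd45_background,
    )


def summarize_cohort(
    records_by_patient: dict[str, pd.DataFrame],
    groups: dict[str, str],
    cfg: PipelineConfig | None = None,
    calibrations: dict[str, object] | None = None,
) -> pd.DataFrame:
    """One PatientSummary row per patient, as a DataFrame.

    ``cd45_diff`` is empty (NaN) for excluded patients, with the
    ``included_in_diff`` flag making the exclusion explicit.
    """
    cfg = cfg or PipelineConfig()
    rows = []
    for pid, records in records_by_patient.items():
        cal = (calibrations or {}).get(pid)
        s = summarize_patient(
            records,
            cfg,
            patient_id=pid,
            group=groups.get(pid, ""),
            tra_threshold=getattr(cal, "tra_threshold", None),
            cd45_background=getattr(cal, "cd45_background", None),
        )
        row = s.__dict__.copy()
        if row["cd45_diff"] is None:
            row["cd45_diff"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
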