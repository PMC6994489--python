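"""Synthetic multi-channel immunofluorescence fields with known ground truth.

The generator emulates epifluorescence images of blood mononuclear cells
stained for DAPI (nuclei), CD45 (pan-leukocyte surface marker) and TRA-1-60
(embryonic surface marker): dense round nuclei on a noisy background with a
gentle illumination gradient, a TRA+ subpopulation at a per-patient
frequency, and a rare TRA+/CD45-low subpopulation concentrated in the
metastatic-like group.  Every rendered cell is recorded in a ground-truth
table so that each downstream stage can be validated without external data.

Intensity model per channel::

    I(x, y) = (background + signal(x, y)) * shade(x) + noise,
    shade(x) = 1 + g * (x / (W - 1) - 1/2),  noise ~ N(0, noise_sd)

Nuclei are Gaussian-smoothed disks; surface markers (CD45, TRA-1-60) are
rendered on a disk 5 px larger than the nucleus to emulate membrane staining
captured by the dilated cell mask.  Images are quantised to 16-bit, the
format the analysis pipeline reads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi

__all__ = [
    "CellTruth",
    "Field",
    "FieldSpec",
    "IntensityModel",
    "PatientSpec",
    "GroundTruth",
    "PlacementError",
    "generate_field",
    "generate_negative_control",
    "generate_patient",
    "generate_cohort",
    "default_cohort_design",
    "COHORT_PRESETS",
]

CHANNELS = ("dapi", "cd45", "tra")


class PlacementError(RuntimeError):
    """Raised when the requested number of nuclei cannot be placed."""


@dataclass(frozen=True)
class CellTruth:
    """Ground truth for one rendered cell."""

    cell_id: int
    center: tuple[int, int]  # (row, col), pixel centres at integer coords
    nucleus_radius_px: float
    tra_positive: bool
    cd45_class: str  # "high" | "low"
    dapi_amp: float
    cd45_amp: float
    tra_amp: float

    def __post_init__(self) -> None:
        if self.nucleus_radius_px <= 0:
            raise ValueError("nucleus_radius_px must be > 0")
        if self.cd45_class not in ("high", "low"):
            raise ValueError("cd45_class must be 'high' or 'low'")
        if min(self.dapi_amp, self.cd45_amp, self.tra_amp) < 0:
            raise ValueError("intensity amplitudes must be >= 0")
        if not self.tra_positive and self.tra_amp != 0:
            raise ValueError("TRA-negative cells must have tra_amp == 0")


@dataclass
class Field:
    """One imaged area: three co-registered channel rasters."""

    dapi: np.ndarray
    cd45: np.ndarray
    tra: np.ndarray
    pixel_size_um: float = 0.65

    @property
    def shape(self) -> tuple[int, int]:
        return self.dapi.shape


@dataclass
class FieldSpec:
    """Geometry, density and noise parameters of one synthetic field.

    ``min_gap_px`` is the extra centre-to-centre gap beyond touching
    (``r_i + r_j``); the default of 14 px keeps each cell's surface stain on
    its own side of the nearest-neighbour bisector.  Set it to a small value
    to generate dense or touching layouts.
    """

    height_px: int = 512
    width_px: int = 512
    pixel_size_um: float = 0.65
    n_cells: int = 100
    background_level: float = 100.0
    noise_sd: float = 10.0
    illumination_gradient: float = 0.05
    rng_seed: int = 0
    min_gap_px: float = 14.0
    max_tries_per_cell: int = 500

    def __post_init__(self) -> None:
        if self.height_px < 8 or self.width_px < 8:
            raise ValueError("field must be at least 8x8 px")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.background_level < 0 or self.noise_sd < 0:
            raise ValueError("intensities must be >= 0")
        if not 0.0 <= self.illumination_gradient <= 1.0:
            raise ValueError("illumination_gradient must lie in [0, 1]")


@dataclass
class IntensityModel:
    """Per-class intensity distributions, in arbitrary units (AU).

    CD45 "low" defaults to an added amplitude of one default noise SD above
    background (cells with barely detectable CD45), "high" to ten times the
    (background + 1 SD) level of a normal leukocyte.  TRA+ cells drawn from
    the high-CD45 regime get a mild boost (``tra_pos_high_boost``) so that,
    as in healthy blood, TRA+ cells show somewhat higher CD45 than the
    TRA- average.
    """

    dapi_amp: float = 1000.0
    tra_amp: float = 500.0
    cd45_high_amp: float = 1100.0
    cd45_low_amp: float = 10.0
    amp_cv: float = 0.10
    tra_pos_high_boost: float = 1.3
    nucleus_radius_mean_px: float = 6.0
    nucleus_radius_sd_px: float = 0.7
    nucleus_radius_min_px: float = 5.0
    nucleus_radius_max_px: float = 7.5
    surface_margin_px: float = 5.0
    render_sigma_px: float = 1.0


@dataclass
class PatientSpec:
    """Design of one synthetic patient (a set of fields plus controls)."""

    patient_id: str
    group: str  # healthy | localized | metastatic | progressor
    tra_fraction: float
    cd45low_given_tra: float = 0.0
    n_fields: int = 20
    n_control_fields: int = 10
    cells_per_field_mean: float = 120.0
    cells_per_field_sd: float = 12.0
    field: FieldSpec = field(default_factory=FieldSpec)
    rng_seed: int | None = None

    GROUP_TRA_RANGES = {
        "healthy": (0.0, 0.023),
        "metastatic": (0.002, 0.136),
        "localized": (0.00002, 0.031),
        "progressor": (0.0, 0.136),
    }

    def __post_init__(self) -> None:
        if self.group not in self.GROUP_TRA_RANGES:
            raise ValueError(f"unknown group {self.group!r}")
        if not (1 <= self.n_fields <= 20):
            raise ValueError("n_fields must be in 1..20")
        if not (1 <= self.n_control_fields <= 10):
            raise ValueError("n_control_fields must be in 1..10")
        if not 0.0 <= self.tra_fraction <= 1.0:
            raise ValueError("tra_fraction must lie in [0, 1]")
        if not 0.0 <= self.cd45low_given_tra <= 1.0:
            raise ValueError("cd45low_given_tra must lie in [0, 1]")
        lo, hi = self.GROUP_TRA_RANGES[self.group]
        if not (lo <= self.tra_fraction <= hi):
            raise ValueError(
                f"tra_fraction {self.tra_fraction} outside the {self.group} "
                f"range [{lo}, {hi}]"
            )


@dataclass
class GroundTruth:
    """Per-cell and per-patient truth tables of a generated cohort."""

    cells: pd.DataFrame  # patient, field, cell_id, row, col, radius, ...
    patients: pd.DataFrame  # realized counts and designed parameters

    def __post_init__(self) -> None:
        # consistency: patient-level counts follow from the cell table
        counts = (
            self.cells.groupby("patient_id")
            .agg(n=("cell_id", "size"), n_tra=("tra_positive", "sum"))
            .reindex(self.patients["patient_id"])
            .fillna(0)
        )
        if not np.array_equal(
            counts["n"].to_numpy(int), self.patients["n_cells_true"].to_numpy(int)
        ):
            raise ValueError("patient-level cell counts inconsistent with cell table")


# --------------------------------------------------------------------------
# field generation
# --------------------------------------------------------------------------


def _place_centres(
    rng: np.random.Generator, spec: FieldSpec, radii: np.ndarray
) -> np.ndarray:
    """Dart-throwing placement honouring the pairwise separation rule."""
    h, w = spec.height_px, spec.width_px
    centres = np.empty((len(radii), 2), dtype=np.int64)
    placed = 0
    tries_left = spec.max_tries_per_cell * max(1, len(radii))
    while placed < len(radii):
        if tries_left <= 0:
            raise PlacementError(
                f"could not place {len(radii)} nuclei in a {h}x{w} field "
                f"with min_gap_px={spec.min_gap_px}; placed {placed}"
            )
        tries_left -= 1
        r = radii[placed]
        margin = int(math.ceil(r)) + 2
        if h - 2 * margin <= 0 or w - 2 * margin <= 0:
            raise PlacementError("field too small for the nucleus radius")
        row = rng.integers(margin, h - margin)
        col = rng.integers(margin, w - margin)
        if placed:
            d = np.hypot(
                centres[:placed, 0] - row, centres[:placed, 1] - col
            )
            min_d = radii[:placed] + r + spec.min_gap_px
            if np.any(d < min_d):
                continue
        centres[placed] = (row, col)
        placed += 1
    return centres


def _draw_cells(
    rng: np.random.Generator,
    spec: FieldSpec,
    model: IntensityModel,
    tra_fraction: float,
    cd45low_given_tra: float,
) -> list[CellTruth]:
    n = spec.n_cells
    radii = np.clip(
        rng.normal(model.nucleus_radius_mean_px, model.nucleus_radius_sd_px, n),
        model.nucleus_radius_min_px,
        model.nucleus_radius_max_px,
    )
    centres = _place_centres(rng, spec, radii)
    tra_pos = rng.random(n) < tra_fraction
    low = tra_pos & (rng.random(n) < cd45low_given_tra)

    def amp(mean: float, size: int) -> np.ndarray:
        return np.clip(rng.normal(mean, model.amp_cv * mean, size), 0.0, None)

    dapi = amp(model.dapi_amp, n)
    cd45 = np.where(
        low,
        amp(model.cd45_low_amp, n),
        amp(model.cd45_high_amp, n)
        * np.where(tra_pos, model.tra_pos_high_boost, 1.0),
    )
    tra = np.where(tra_pos, amp(model.tra_amp, n), 0.0)
    return [
        CellTruth(
            cell_id=i + 1,
            center=(int(centres[i, 0]), int(centres[i, 1])),
            nucleus_radius_px=float(radii[i]),
            tra_positive=bool(tra_pos[i]),
            cd45_class="low" if low[i] else "high",
            dapi_amp=float(dapi[i]),
            cd45_amp=float(cd45[i]),
            tra_amp=float(tra[i]),
        )
        for i in range(n)
    ]


def _paint_disk(
    canvas: np.ndarray, centre: tuple[int, int], radius: float, value: float
) -> None:
    h, w = canvas.shape
    r0 = max(0, int(math.floor(centre[0] - radius)))
    r1 = min(h, int(math.ceil(centre[0] + radius)) + 1)
    c0 = max(0, int(math.floor(centre[1] - radius)))
    c1 = min(w, int(math.ceil(centre[1] + radius)) + 1)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    inside = (rr - centre[0]) ** 2 + (cc - centre[1]) ** 2 <= radius**2
    canvas[r0:r1, c0:c1][inside] += value


def _finish_channel(
    signal: np.ndarray, spec: FieldSpec, rng: np.random.Generator, sigma: float
) -> np.ndarray:
    if sigma > 0:
        signal = ndi.gaussian_filter(signal, sigma)
    w = spec.width_px
    shade = 1.0 + spec.illumination_gradient * (
        np.arange(w) / max(w - 1, 1) - 0.5
    )
    img = (spec.background_level + signal) * shade[np.newaxis, :]
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    return np.round(np.clip(img, 0.0, 65535.0)).astype(np.uint16)


def generate_field(
    spec: FieldSpec,
    tra_fraction: float = 0.0,
    cd45low_given_tra: float = 0.0,
    model: IntensityModel | None = None,
    cells: Sequence[CellTruth] | None = None,
) -> tuple[Field, list[CellTruth]]:
    """Render one three-channel field plus its exact cell-level truth.

    ``cells`` may supply an explicit layout (positions, radii, marker
    classes), bypassing random placement — handy for hand-built
    segmentation tests with e.g. touching nucleus pairs.
    Identical ``spec.rng_seed`` gives bit-identical output.
    """
    model = model or IntensityModel()
    rng = np.random.default_rng(spec.rng_seed)
    if cells is None:
        truth = _draw_cells(rng, spec, model, tra_fraction, cd45low_given_tra)
    else:
        truth = list(cells)

    shape = (spec.height_px, spec.width_px)
    dapi_map = np.zeros(shape)
    cd45_map = np.zeros(shape)
    tra_map = np.zeros(shape)
    for c in truth:
        _paint_disk(dapi_map, c.center, c.nucleus_radius_px, c.dapi_amp)
        surface_r = c.nucleus_radius_px + model.surface_margin_px
        _paint_disk(cd45_map, c.center, surface_r, c.cd45_amp)
        if c.tra_positive:
            _paint_disk(tra_map, c.center, surface_r, c.tra_amp)

    s = model.render_sigma_px
    fld = Field(
        dapi=_finish_channel(dapi_map, spec, rng, s),
        cd45=_finish_channel(cd45_map, spec, rng, s),
        tra=_finish_channel(tra_map, spec, rng, s),
        pixel_size_um=spec.pixel_size_um,
    )
    return fld, truth


def generate_negative_control(
    spec: FieldSpec, model: IntensityModel | None = None
) -> Field:
    """A secondary-antibody-only field: nuclei in DAPI, background-only
    CD45 and TRA channels."""
    model = model or IntensityModel()
    rng = np.random.default_rng(spec.rng_seed)
    truth = _draw_cells(rng, spec, model, tra_fraction=0.0, cd45low_given_tra=0.0)
    shape = (spec.height_px, spec.width_px)
    dapi_map = np.zeros(shape)
    for c in truth:
        _paint_disk(dapi_map, c.center, c.nucleus_radius_px, c.dapi_amp)
    s = model.render_sigma_px
    return Field(
        dapi=_finish_channel(dapi_map, spec, rng, s),
        cd45=_finish_channel(np.zeros(shape), spec, rng, 0.0),
        tra=_finish_channel(np.zeros(shape), spec, rng, 0.0),
        pixel_size_um=spec.pixel_size_um,
    )


# --------------------------------------------------------------------------
# patients and cohorts
# --------------------------------------------------------------------------


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Deterministically derive n child seeds (< 2**31) from one seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n, dtype=np.uint64)]


def _truth_frame(patient_id: str, field_name: str, truth: Iterable[CellTruth]) -> pd.DataFrame:
    rows = [
        {
            "patient_id": patient_id,
            "field": field_name,
            "cell_id": c.cell_id,
            "row": c.center[0],
            "col": c.center[1],
            "radius": c.nucleus_radius_px,
            "tra_positive": c.tra_positive,
            "cd45_class": c.cd45_class,
        }
        for c in truth
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "field",
            "cell_id",
            "row",
            "col",
            "radius",
            "tra_positive",
            "cd45_class",
        ],
    )


def _write_field(directory: Path, fld: Field) -> None:
    directory.mkdir(parents=True, exist_ok=True)
    for name in CHANNELS:
        tifffile.imwrite(directory / f"{name}.tif", getattr(fld, name))


def generate_patient(
    spec: PatientSpec,
    out_dir: str | Path | None = None,
    model: IntensityModel | None = None,
) -> tuple[list[Field], list[Field], pd.DataFrame]:
    """Generate all stained fields and negative controls of one patient.

    Returns ``(fields, control_fields, truth_table)``; if ``out_dir`` is
    given the images are also written in the cohort directory layout
    (``<out>/<patient>/field_XX/{dapi,cd45,tra}.tif`` and
    ``<out>/<patient>/control/control_XX/...``).
    """
    if spec.rng_seed is None:
        raise ValueError(f"patient {spec.patient_id}: rng_seed not set")
    model = model or IntensityModel()
    rng = np.random.default_rng(spec.rng_seed)
    n_cells = np.maximum(
        1,
        np.round(
            rng.normal(
                spec.cells_per_field_mean,
                spec.cells_per_field_sd,
                spec.n_fields + spec.n_control_fields,
            )
        ).astype(int),
    )
    seeds = _spawn_seeds(spec.rng_seed, spec.n_fields + spec.n_control_fields)

    fields: list[Field] = []
    frames: list[pd.DataFrame] = []
    for i in range(spec.n_fields):
        fspec = replace(spec.field, n_cells=int(n_cells[i]), rng_seed=seeds[i])
        fld, truth = generate_field(
            fspec, spec.tra_fraction, spec.cd45low_given_tra, model
        )
        name = f"field_{i + 1:02d}"
        fields.append(fld)
        frames.append(_truth_frame(spec.patient_id, name, truth))
        if out_dir is not None:
            _write_field(Path(out_dir) / spec.patient_id / name, fld)

    controls: list[Field] = []
    for j in range(spec.n_control_fields):
        k = spec.n_fields + j
        fspec = replace(spec.field, n_cells=int(n_cells[k]), rng_seed=seeds[k])
        ctrl = generate_negative_control(fspec, model)
        controls.append(ctrl)
        if out_dir is not None:
            _write_field(
                Path(out_dir) / spec.patient_id / "control" / f"control_{j + 1:02d}",
                ctrl,
            )

    truth_table = (
        pd.concat(frames, ignore_index=True)
        if frames
        else _truth_frame(spec.patient_id, "", [])
    )
    return fields, controls, truth_table


def generate_cohort(
    design: Sequence[PatientSpec],
    out_dir: str | Path,
    model: IntensityModel | None = None,
    master_seed: int | None = None,
) -> GroundTruth:
    """Generate a whole cohort on disk, returning its ground truth.

    Patients whose ``rng_seed`` is unset receive one spawned
    deterministically from ``master_seed``.  Writes the per-patient image
    tree plus ``cells_truth.csv`` and ``manifest.csv`` at the cohort root.
    """
    if not design:
        raise ValueError("design must be non-empty")
    ids = [p.patient_id for p in design]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate patient identifiers: {dupes}")

    needs_seed = [p for p in design if p.rng_seed is None]
    if needs_seed and master_seed is None:
        raise ValueError("master_seed required when patient seeds are unset")
    if master_seed is not None:
        child = iter(_spawn_seeds(master_seed, len(design)))
        design = [
            replace(p, rng_seed=next(child)) if p.rng_seed is None else p
            for p in design
        ]

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cell_frames: list[pd.DataFrame] = []
    patient_rows: list[dict] = []
    for p in design:
        _, _, truth = generate_patient(p, out_dir=out, model=model)
        cell_frames.append(truth)
        n_tra = int(truth["tra_positive"].sum())
        patient_rows.append(
            {
                "patient_id": p.patient_id,
                "group": p.group,
                "n_fields": p.n_fields,
                "n_control_fields": p.n_control_fields,
                "n_cells_true": len(truth),
                "n_tra_true": n_tra,
                "true_tra_fraction": n_tra / len(truth) if len(truth) else 0.0,
                "n_cd45low_true": int(
                    (truth["tra_positive"] & (truth["cd45_class"] == "low")).sum()
                ),
                "designed_tra_fraction": p.tra_fraction,
                "designed_cd45low_given_tra": p.cd45low_given_tra,
                "rng_seed": p.rng_seed,
            }
        )

    cells = pd.concat(cell_frames, ignore_index=True)
    patients = pd.DataFrame(patient_rows)
    cells.to_csv(out / "cells_truth.csv", index=False)
    patients.to_csv(out / "manifest.csv", index=False)
    return GroundTruth(cells=cells, patients=patients)


# --------------------------------------------------------------------------
# default cohort design
# --------------------------------------------------------------------------

#: Cohort-scale presets.  "full" mirrors the study geometry defaults
#: (512 px fields, 20 stained + 10 control fields per patient); "desk" and
#: "mini" trade field size and count for runtime.
COHORT_PRESETS = {
    "full": dict(field_px=512, n_fields=20, n_controls=10, cells_mean=120.0),
    "desk": dict(field_px=384, n_fields=10, n_controls=4, cells_mean=90.0),
    "mini": dict(field_px=224, n_fields=4, n_controls=2, cells_mean=30.0),
}

#: Cohort group sizes: 17 healthy, 26 metastatic, 13 localized, 1 progressor.
GROUP_SIZES = {"healthy": 17, "metastatic": 26, "localized": 13, "progressor": 1}


def _log_grid(lo: float, hi: float, n: int) -> np.ndarray:
    return np.exp(np.linspace(math.log(lo), math.log(hi), n))


def default_cohort_design(
    preset: str = "desk", master_seed: int = 0
) -> list[PatientSpec]:
    """The default 57-patient design.

    Per-group TRA+ fraction ranges follow the cohort's reported spread:
    healthy 0-2.3% (five patients with none at all), metastatic 0.2-13.6%,
    localized 0.002-3.1%.  TRA+/CD45-low cells occur in every
    metastatic-like patient and in exactly two localized patients; healthy
    controls never carry them.  Fractions sit on jittered log-spaced grids
    so each generated cohort spans its printed range regardless of seed.
    """
    if preset not in COHORT_PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(COHORT_PRESETS)}")
    cfg = COHORT_PRESETS[preset]
    fld = FieldSpec(height_px=cfg["field_px"], width_px=cfg["field_px"])
    rng = np.random.default_rng(np.random.SeedSequence([master_seed, 12345]))

    def jitter(values: np.ndarray, rel: float = 0.15) -> np.ndarray:
        return values * np.exp(rng.uniform(-rel, rel, len(values)))

    def mk(pid: str, group: str, fraction: float, q: float) -> PatientSpec:
        return PatientSpec(
            patient_id=pid,
            group=group,
            tra_fraction=float(fraction),
            cd45low_given_tra=float(q),
            n_fields=cfg["n_fields"],
            n_control_fields=cfg["n_controls"],
            cells_per_field_mean=cfg["cells_mean"],
            cells_per_field_sd=0.1 * cfg["cells_mean"],
            field=fld,
        )

    design: list[PatientSpec] = []

    # healthy: 5 with no TRA+ cells at all, 12 spanning 0..2.3%
    h_fracs = np.concatenate(
        [np.zeros(5), np.clip(jitter(_log_grid(1e-4, 0.023, 12)), 0.0, 0.023)]
    )
    for i, f in enumerate(h_fracs):
        design.append(mk(f"H{i + 1:02d}", "healthy", f, 0.0))

    # metastatic: fractions 0.2..13.6%; CD45-low propensity pairs inversely
    # with the fraction so the phenotype is expected in every patient at
    # desk-scale cell counts
    m_fracs = np.clip(jitter(_log_grid(0.002, 0.136, 26)), 0.002, 0.136)
    m_q = np.clip(
        np.linspace(0.7, 0.25, 26) + rng.uniform(-0.03, 0.03, 26), 0.2, 0.75
    )
    for i, (f, q) in enumerate(zip(m_fracs, m_q)):
        design.append(mk(f"M{i + 1:02d}", "metastatic", f, q))

    # localized: 0.002..3.1%; exactly two patients (the two highest
    # fractions) carry a small CD45-low propensity
    l_fracs = np.clip(jitter(_log_grid(2e-5, 0.031, 13)), 2e-5, 0.031)
    for i, f in enumerate(l_fracs):
        q = 0.03 if i >= 11 else 0.0
        design.append(mk(f"L{i + 1:02d}", "localized", f, q))

    design.append(mk("P01", "progressor", 0.008, 0.2))
    return design
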