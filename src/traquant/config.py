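"""Pipeline configuration.

All tunable constants of the image-analysis pipeline live in a single
:class:`PipelineConfig` dataclass so that a run is fully described by one
object (serialisable to/from YAML for the CLI).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Constants of the detection pipeline.

    Parameters
    ----------
    gaussian_sigma_px:
        Sigma of the Gaussian pre-smoothing of the DAPI channel, in pixels.
    bg_subtract_radius_px:
        Radius of the structuring element used for morphological (top-hat)
        background subtraction.  Must be much larger than a nucleus radius;
        50 px at 0.65 um/px comfortably is.
    dilation_px:
        Radius by which the cell mask is dilated beyond the thresholded
        region so that surface staining around the nucleus is captured.
    min_tra_pixels:
        Minimal number of suprathreshold TRA-1-60 pixels inside a cell mask
        for the cell to be called TRA-positive.
    cd45low_cutoff:
        Normalised CD45 level below which a TRA+ cell is classed CD45-low.
    min_tra_cells_for_diff:
        Minimal number of TRA+ cells a patient needs to enter the CD45
        intensity-difference measurement.
    connectivity:
        Pixel connectivity for connected components: 4 or 8.
    calibration_mode:
        ``"pixel"`` (default): the TRA threshold is the maximum control
        pixel value inside any cell mask, so no control pixel — let alone a
        detection — survives it.  ``"detection"``: the smallest value at
        which the full calling rule (>= min_tra_pixels suprathreshold
        pixels in a cell) yields zero detections on the controls; this is
        the weakest admissible threshold but lets a few patient cells beat
        it by pure order statistics when patients have more cells than the
        controls.
    roc_method:
        ``"hanley"`` (Hanley-McNeil SE, default) or ``"delong"`` for the ROC
        confidence interval / p-value.
    pct_sd_ddof:
        Delta degrees of freedom for the SD of per-field TRA+ percentages
        (0 = population SD over the imaged fields).
    """

    gaussian_sigma_px: float = 1.0
    bg_subtract_radius_px: int = 50
    dilation_px: int = 5
    min_tra_pixels: int = 5
    cd45low_cutoff: float = 0.3
    min_tra_cells_for_diff: int = 3
    connectivity: int = 8
    calibration_mode: str = "pixel"
    roc_method: str = "hanley"
    pct_sd_ddof: int = 0

    def __post_init__(self) -> None:
        if self.gaussian_sigma_px <= 0:
            raise ValueError("gaussian_sigma_px must be > 0")
        if self.bg_subtract_radius_px <= 0:
            raise ValueError("bg_subtract_radius_px must be > 0")
        if self.dilation_px < 0:
            raise ValueError("dilation_px must be >= 0")
        if self.min_tra_pixels < 1:
            raise ValueError("min_tra_pixels must be >= 1")
        if not 0.0 < self.cd45low_cutoff < 1.0:
            raise ValueError("cd45low_cutoff must lie in (0, 1)")
        if self.min_tra_cells_for_diff < 1:
            raise ValueError("min_tra_cells_for_diff must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.calibration_mode not in ("detection", "pixel"):
            raise ValueError("calibration_mode must be 'detection' or 'pixel'")
        if self.roc_method not in ("hanley", "delong"):
            raise ValueError("roc_method must be 'hanley' or 'delong'")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}  # noqa: C401
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
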