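"""Pipeline configuration.

All thresholds the segmentation relies on live here, grouped per stage.
The defaults encode the published protocol constants (blood-pool rule
AUC > 2/3 with t_mid < 1.5 min, fixed water distribution volume
V_T = 0.91 mL/g, 1.3 cm cavity margin, 6 TAC clusters, two-heartbeat
atrial timing gate) next to the implementation choices that the original
method leaves open (peak-segment stopping rules, basis-grid density,
LVOT cylinder growth, SVC tube criteria).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from pydantic import BaseModel, Field, model_validator

from .errors import ParameterError


class FirstPassConfig(BaseModel):
    """Voxel-wise first-pass peak extraction and blood-pool rule."""

    search_window_s: float = Field(120.0, gt=0)
    peak_tail_frac: float = Field(0.10, gt=0, lt=1)
    recirc_min_frac: float = Field(0.5, gt=0, lt=1)
    min_peak_snr: float = Field(5.0, ge=0)      # peak must exceed snr x late background
    min_peak_abs: float = Field(1e-3, ge=0)     # kBq/mL floor for "there is a signal"
    background_window_s: float = Field(90.0, gt=0)
    auc_blood_frac: float = Field(2.0 / 3.0, gt=0, lt=1)
    tmid_blood_max_s: float = Field(90.0, gt=0)


class ClusterConfig(BaseModel):
    """Cluster analysis of voxel TACs for the input functions."""

    k: int = Field(6, ge=3)
    auc_percentile: float = Field(75.0, ge=0, lt=100)
    min_av_lag_s: float = Field(4.0, ge=0)
    venous_auc_frac: float = Field(0.5, gt=0, le=1)
    arterial_auc_tol: float = Field(0.10, ge=0, lt=1)
    lung_auc_min: float = Field(0.15, gt=0)
    lung_auc_max: float = Field(0.5, gt=0)
    core_percentile: float = Field(75.0, ge=0, lt=100)  # hottest members -> input TAC
    max_iter: int = Field(100, ge=1)


class KineticModelConfig(BaseModel):
    """Basis-function single-tissue compartment model for O-15 water."""

    v_t: float = Field(0.91, gt=0)              # mL/g, fixed distribution volume
    mbf_min: float = Field(0.1, gt=0)           # mL/g/min
    mbf_max: float = Field(5.0, gt=0)
    mbf_n: int = Field(200, ge=2)
    fine_dt: float = Field(1.0, gt=0)           # s, convolution grid
    nonneg: bool = True

    @model_validator(mode="after")
    def _check_grid(self):
        if self.mbf_max <= self.mbf_min:
            raise ParameterError("mbf_max must exceed mbf_min")
        return self


class ChamberConfig(BaseModel):
    """Short-axis reorientation, myocardial profiling, cavity rule."""

    v_a_threshold: float = Field(0.6, gt=0, lt=1)
    v_rv_threshold: float = Field(0.5, gt=0, lt=1)
    n_angles: int = Field(36, ge=8)
    profile_r_max_mm: float = Field(45.0, gt=0)
    profile_step_mm: float = Field(1.0, gt=0)
    ptf_ridge_min: float = Field(0.15, ge=0)    # g/mL, minimum ridge to accept a wall
    edge_frac: float = Field(0.5, gt=0, lt=1)   # half-maximum wall edges
    max_half_wall_mm: float = Field(8.0, gt=0)
    min_slice_pixels: int = Field(10, ge=1)
    min_slices: int = Field(3, ge=1)
    cavity_margin_mm: float = Field(13.0, gt=0)  # 2 x assumed 6.5 mm FWHM resolution
    min_component_ml: float = Field(2.0, gt=0)


class AtriaConfig(BaseModel):
    """Atrial candidate gates, aorta split and SVC removal."""

    heart_rate_bpm: float = Field(60.0, gt=0)
    min_component_ml: float = Field(5.0, gt=0)
    lvot_radius_start_mm: float = Field(5.0, gt=0)
    lvot_radius_step_mm: float = Field(1.0, gt=0)
    lvot_radius_max_mm: float = Field(30.0, gt=0)
    tube_area_max_cm2: float = Field(4.0, gt=0)
    tube_circularity_min: float = Field(0.6, gt=0, le=1)
    tube_min_slices: int = Field(3, ge=1)


class PipelineConfig(BaseModel):
    """Aggregate configuration for a full pipeline run."""

    firstpass: FirstPassConfig = Field(default_factory=FirstPassConfig)
    clustering: ClusterConfig = Field(default_factory=ClusterConfig)
    kinetics: KineticModelConfig = Field(default_factory=KineticModelConfig)
    chambers: ChamberConfig = Field(default_factory=ChamberConfig)
    atria: AtriaConfig = Field(default_factory=AtriaConfig)
    seed: int = 0
    height_cm: float | None = 170.0
    weight_kg: float | None = 70.0

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.model_validate(json.load(fh))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2) + "\n")

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
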