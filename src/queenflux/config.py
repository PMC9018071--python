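"""Validated configuration objects for the simulator and the pipeline."""

from __future__ import annotations

import hashlib
import json
from pydantic import BaseModel, Field, model_validator

__all__ = ["SyntheticConfig", "CohortMix", "ClassifierThresholds", "PipelineConfig"]


class CohortMix(BaseModel):
    """Per-class proportions of cells in a simulated cohort.

    The default mix emulates the *snf1∆ adk1∆*-like regime in which roughly a
    third of cells show an ATP dip or shift during the observation window,
    with a small admixture of shallow-dip cells.
    """

    model_config = {"frozen": True}

    stable: float = 0.65
    dip: float = 0.20
    shallow_dip: float = 0.05
    shift: float = 0.10
    oscillating: float = 0.0

    @model_validator(mode="after")
    def _check(self) -> "CohortMix":
        vals = [self.stable, self.dip, self.shallow_dip, self.shift, self.oscillating]
        if any(v < 0 for v in vals):
            raise ValueError("cohort proportions must be non-negative")
        if abs(sum(vals) - 1.0) > 1e-9:
            raise ValueError(f"cohort proportions must sum to 1, got {sum(vals)}")
        return self

    def as_tuple(self) -> tuple[float, ...]:
        return (self.stable, self.dip, self.shallow_dip, self.shift, self.oscillating)


class SyntheticConfig(BaseModel):
    """Parameters of the synthetic time-lapse generator.

    Defaults encode the imaging regime the analysis is built for: 4-min frame
    interval, ~10 h observation, resting ATP ~4 mM at sensor ratio 1.0, deep
    dips (> 0.5 ratio units) lasting ~15 min, irreversible shifts, ~35-min
    unsynchronized oscillations, single-frame acquisition errors about once
    per 70 frames, and reporter intensity rising linearly (r ~ 0.99) with an
    optional ~5.6-fold post-dip acceleration of the residual RMSD within 3 h.
    """

    model_config = {"frozen": True}

    n_cells: int = Field(200, ge=1)
    n_frames: int = Field(150, ge=3)
    frame_interval: float = Field(4.0, gt=0)  # minutes
    baseline_atp: float = Field(4.0, gt=0)  # mM
    baseline_ratio: float = Field(1.0, gt=0)  # sensor ratio units
    ratio_noise_sd: float = Field(0.05, ge=0)  # ratio units
    dip_rate: float = Field(0.1, gt=0)  # events / hour / cell (dip-class cells)
    dip_depth_range: tuple[float, float] = (0.56, 0.85)  # ratio units
    shallow_depth_range: tuple[float, float] = (0.36, 0.44)  # ratio units
    dip_duration: float = Field(15.0, gt=0)  # minutes at reduced level
    shift_prob: float = Field(0.1, ge=0, le=1)  # P(depletion is irreversible)
    osc_period: float = Field(35.0, gt=0)  # minutes
    osc_amplitude: float = Field(0.15, ge=0)  # ratio units
    frame_error_rate: float = Field(1.0 / 70.0, ge=0, le=1)  # per frame
    frame_error_magnitude: float = Field(8.0, ge=0)  # channel noise SDs
    agg_intercept: float = Field(500.0, ge=0)  # reporter units
    agg_slope: float = Field(2.0, gt=0)  # reporter units / minute
    agg_corr_target: float = Field(0.99, gt=0, lt=1)  # Pearson r of linear rise
    post_dip_fold: float = Field(5.6, ge=1)  # target mean max RMSD fold
    post_dip_fold_spread: float = Field(0.25, ge=0)  # lognormal sigma of cell factor
    post_dip_horizon: float = Field(180.0, gt=0)  # minutes
    channel_base_490: float = Field(2000.0, gt=0)  # camera units
    image_size: int = Field(128, ge=16)
    cell_radius: int = Field(8, ge=2)
    cell_background: float = Field(500.0, ge=0)  # reporter cytoplasm level
    image_background: float = Field(100.0, ge=0)
    focus_amplitude: float = Field(10000.0, gt=0)
    psf_sigma: float = Field(1.5, gt=0)  # pixels
    pixel_noise_sd: float = Field(0.0, ge=0)  # Gaussian read noise, camera units
    pixel_poisson: bool = False
    mix: CohortMix = CohortMix()
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SyntheticConfig":
        for name in ("dip_depth_range", "shallow_depth_range"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi <= lo:
                raise ValueError(f"{name} must satisfy 0 <= min < max, got ({lo}, {hi})")
        if self.dip_depth_range[1] <= 0.5:
            raise ValueError("dip_depth_range max must exceed 0.5 to generate deep dips")
        if self.osc_amplitude > 0 and self.osc_period <= 2 * self.frame_interval:
            raise ValueError(
                "osc_period must exceed 2 x frame_interval (Nyquist); "
                f"got osc_period={self.osc_period}, frame_interval={self.frame_interval}"
            )
        if self.image_size < 4 * self.cell_radius:
            raise ValueError("image_size must be at least 4 x cell_radius")
        return self

    @property
    def dip_duration_frames(self) -> int:
        return max(1, int(round(self.dip_duration / self.frame_interval)))


class ClassifierThresholds(BaseModel):
    """Fixed thresholds of the ATP-dynamics classifier, in ratio units.

    A transient decrease deeper than ``deep`` spanning more than ``min_frames``
    frames is an ATP dip; 0.33-0.5 is a shallow dip; a > ``shallow`` decrease
    that never recovers is an ATP shift.
    """

    model_config = {"frozen": True}

    deep: float = 0.5
    shallow: float = 0.33
    min_frames: int = 2  # dip must span MORE than this many frames
    baseline_window: int = 5
    enter_delta: float = 0.2
    exit_frac: float = 0.1

    @model_validator(mode="after")
    def _check(self) -> "ClassifierThresholds":
        if not (0 < self.shallow < self.deep):
            raise ValueError(
                f"thresholds must satisfy 0 < shallow < deep, got shallow={self.shallow}, deep={self.deep}"
            )
        if self.min_frames < 1:
            raise ValueError("min_frames must be >= 1")
        if self.baseline_window < 3:
            raise ValueError("baseline_window must be >= 3 frames")
        if not (0 <= self.exit_frac < 1):
            raise ValueError("exit_frac must be in [0, 1)")
        if self.enter_delta <= 0:
            raise ValueError("enter_delta must be > 0")
        return self


class PipelineConfig(BaseModel):
    """End-to-end run configuration (simulate -> ratio -> classify -> rmsd -> period)."""

    model_config = {"frozen": True}

    synthetic: SyntheticConfig = SyntheticConfig()
    thresholds: ClassifierThresholds = ClassifierThresholds()
    doubling_time_min: float = Field(288.0, gt=0)  # 4.8 h, the ATP-mutant default
    doubling_times: dict[str, float] = {"wild_type": 216.0, "snf1_adk1": 288.0}
    calibration: dict = {"model": "linear", "slope": 4.0, "intercept": 0.0}
    foci_tolerance: float = Field(4000.0, gt=0)
    rmsd_step: float = Field(30.0, gt=0)  # minutes
    rmsd_horizon: float = Field(180.0, gt=0)  # minutes
    error_threshold_sd: float = Field(5.0, gt=0)
    error_window: int = Field(7, ge=3)
    min_predip_span: float = Field(92.0, gt=0)  # minutes
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "PipelineConfig":
        k = self.rmsd_horizon / self.rmsd_step
        if abs(k - round(k)) > 1e-9:
            raise ValueError(
                f"rmsd_horizon ({self.rmsd_horizon}) must be a multiple of rmsd_step ({self.rmsd_step})"
            )
        return self

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_json_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.model_validate(json.load(fh))
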