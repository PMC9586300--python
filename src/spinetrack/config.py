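"""Run configuration: a schema-validated JSON document driving the pipeline.

Unknown keys are rejected; the seed is mandatory and feeds every stochastic
step through per-unit child RNG streams.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field, field_validator

from .detection import DetectionParams
from .synthetic import ImagingParams, SimConfig
from .tracking import MatchingParams


class GroupSpec(BaseModel):
    """Per-group generative parameters (rates per spine per day)."""

    model_config = ConfigDict(extra="forbid")

    formation_rate_per_spine_per_day: float = 0.1
    formation_rate_post_switch: float | None = None
    newborn_daily_survival_prob: float = 0.94868
    newborn_survival_post_switch: float | None = None
    preexisting_daily_survival_prob: float = 0.998
    reappearance_prob: float = 0.05


class RunConfig(BaseModel):
    """Top-level configuration for a full pipeline run."""

    model_config = ConfigDict(extra="forbid")

    out_dir: str = "runs/out"
    seed: int
    session_days: list[int] = Field(default=[11, 13, 15, 18, 25])
    n_mice_per_group: int = 2
    dendrites_per_mouse: int = 4
    segment_length_um: tuple[float, float] = (50.0, 100.0)
    baseline_density_per_um: float = 0.4
    groups: dict[str, GroupSpec] = Field(
        default_factory=lambda: {"sham": GroupSpec(), "chi": GroupSpec(
            formation_rate_per_spine_per_day=0.25, newborn_daily_survival_prob=0.63246
        )}
    )
    rate_switch_day: int = 14
    pixel_size_xy_um: float = 0.1513
    z_step_um: float = 1.0
    gain: float = 150.0
    jitter_amplitude_um: tuple[float, float, float] = (1.0, 1.0, 1.0)
    noise: bool = True
    tube_exclusion_radius_um: float | None = None
    min_spine_length_um: float = 0.55
    matching_tolerance_um: float = 1.0
    registration_max_shift_um: float = 5.0
    alpha: float = 0.05
    behavior_csv: str | None = None

    @field_validator("session_days")
    @classmethod
    def _increasing(cls, v: list[int]) -> list[int]:
        if len(v) < 2 or any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("session_days must be strictly increasing")
        return v

    # ---- derived parameter bundles -------------------------------------
    def sim_config(self, group: str) -> SimConfig:
        g = self.groups[group]
        return SimConfig(
            session_days=tuple(self.session_days),
            n_mice_per_group=self.n_mice_per_group,
            dendrites_per_mouse=self.dendrites_per_mouse,
            group=group,
            segment_length_um=tuple(self.segment_length_um),
            baseline_density_per_um=self.baseline_density_per_um,
            formation_rate_per_spine_per_day=g.formation_rate_per_spine_per_day,
            formation_rate_post_switch=g.formation_rate_post_switch,
            newborn_daily_survival_prob=g.newborn_daily_survival_prob,
            newborn_survival_post_switch=g.newborn_survival_post_switch,
            rate_switch_day=self.rate_switch_day,
            preexisting_daily_survival_prob=g.preexisting_daily_survival_prob,
            reappearance_prob=g.reappearance_prob,
            seed=self.seed,
        )

    def imaging_params(self) -> ImagingParams:
        return ImagingParams(
            pixel_size_xy_um=self.pixel_size_xy_um,
            z_step_um=self.z_step_um,
            gain=self.gain,
            jitter_amplitude_um=tuple(self.jitter_amplitude_um),
            noise=self.noise,
        )

    def detection_params(self) -> DetectionParams:
        return DetectionParams(
            tube_exclusion_radius_um=self.tube_exclusion_radius_um,
            min_length_um=self.min_spine_length_um,
        )

    def matching_params(self) -> MatchingParams:
        return MatchingParams(tolerance_um=self.matching_tolerance_um)

    # ---- serialization --------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate_json(Path(path).read_text())

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
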