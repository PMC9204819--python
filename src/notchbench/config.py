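"""Structured run configuration (pydantic models, YAML round-trip)."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator

from .exceptions import ConfigurationError
from .notch import NotchRegion
from .psm_table import ChannelSet, DEFAULT_GROUPS, DEFAULT_LABELS
from .synthetic import DEFAULT_CONTRASTS, MixDesign, SimParams, build_mix_design


class DesignConfig(BaseModel):
    labels: list[str] = Field(default_factory=lambda: list(DEFAULT_LABELS))
    groups: list[str] = Field(default_factory=lambda: list(DEFAULT_GROUPS))
    yeast_masses_by_group: dict[str, float] = Field(
        default_factory=lambda: {"1x": 5.0, "2x": 10.0, "6x": 30.0}
    )
    total_mass: float = 100.0

    def channel_set(self) -> ChannelSet:
        return ChannelSet(labels=tuple(self.labels), groups=tuple(self.groups))

    def mix_design(self) -> MixDesign:
        return build_mix_design(self.yeast_masses_by_group, self.channel_set(), self.total_mass)


class NotchConfig(BaseModel):
    lower: float = 4.25
    upper: float = 5.75
    slope: float = 1.5
    enabled: bool = True

    def region(self) -> NotchRegion:
        return NotchRegion(lower=self.lower, upper=self.upper)


class SimConfig(BaseModel):
    n_yeast_proteins: int = 300
    n_human_proteins: int = 900
    psm_per_protein: tuple[float, float] = (6.0, 0.5)
    psm_redundancy: float = 2.0
    base_mean_log2: float = 10.0
    base_abundance_sd: float = 1.5
    psm_scale_sd: float = 1.5
    reporter_noise_sd: float = 0.4
    interference_dist: tuple[float, float] = (0.5, 12.0)
    missing_rate: float = 0.3
    detection_floor_log2: float = 4.0

    def sim_params(self, notch: NotchConfig, seed: int) -> SimParams:
        return SimParams(
            **self.model_dump(),
            notch=notch.region() if notch.enabled else None,
            notch_slope=notch.slope,
            seed=seed,
        )


class FilterConfig(BaseModel):
    grid: bool = True  # run the full 36-schema grid
    min_delta_cn: float = 0.5
    max_coisolation: float = 10.0
    min_avg_sn: float = 10.0
    remove_notch: bool = False


class RunConfig(BaseModel):
    """Validated configuration for the end-to-end pipeline."""

    design: DesignConfig = Field(default_factory=DesignConfig)
    sim: SimConfig = Field(default_factory=SimConfig)
    notch: NotchConfig = Field(default_factory=NotchConfig)
    filters: FilterConfig = Field(default_factory=FilterConfig)
    contrasts: list[str] = Field(default_factory=lambda: list(DEFAULT_CONTRASTS))
    fdr_threshold: float = 0.01
    level: str = "protein"
    out_dir: str = "notchbench_out"
    seed: int = 0

    @field_validator("level")
    @classmethod
    def _level_known(cls, v: str) -> str:
        if v not in ("protein", "peptide"):
            raise ValueError("level must be 'protein' or 'peptide'")
        return v

    @field_validator("fdr_threshold")
    @classmethod
    def _fdr_in_range(cls, v: float) -> float:
        if not 0 < v < 1:
            raise ValueError("fdr_threshold must be in (0, 1)")
        return v

    def validate_stages(self) -> None:
        """Cross-field preconditions checked before any stage runs."""
        if self.filters.remove_notch and not self.notch.enabled and self.notch.upper is None:
            raise ConfigurationError("remove_notch requires notch boundaries")
        self.design.mix_design()  # raises DesignError on bad masses
        self.sim.sim_params(self.notch, self.seed)  # raises ParameterError

    def fingerprint(self) -> str:
        """Stable hash of the configuration (excluding the output directory)."""
        payload = self.model_dump()
        payload.pop("out_dir", None)
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(payload)


def dump_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(mode="json"), fh, sort_keys=False)
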