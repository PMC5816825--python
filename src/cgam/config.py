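"""Validated analysis configuration (YAML in, resolved YAML out).

Every ``cgam analyze`` run validates its configuration against this schema
before touching data and writes the resolved copy next to its outputs, so a
result can always be traced back to the exact settings that produced it.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Dict, List, Literal, Optional

import yaml
from pydantic import BaseModel, Field, field_validator

from .errors import UsageError
from .parameters import CANONICAL_PARAMS


class SubjectConfig(BaseModel):
    mass_kg: float = Field(gt=0)
    leg_length_m: float = Field(gt=0)
    belt_speed_mps: float = Field(ge=0)


class DialectConfig(BaseModel):
    kind: Literal["csv_wide", "csv_long", "c3d"] = "csv_wide"
    units: Literal["m", "mm"] = "m"
    axes: List[str] = ["X", "Y", "Z"]
    label_map: Dict[str, str] = {}


class FilterConfig(BaseModel):
    marker_cutoff_hz: float = Field(default=6.0, gt=0)
    force_cutoff_hz: float = Field(default=15.0, gt=0)
    order: int = Field(default=4, ge=1)


class EventConfig(BaseModel):
    threshold_n: float = Field(default=20.0, gt=0)
    min_phase_s: float = Field(default=0.05, gt=0)


class AnalysisConfig(BaseModel):
    """Full configuration of one analysis run."""

    markers: str
    forces_left: str
    forces_right: str
    subject: SubjectConfig
    marker_rate_hz: Optional[float] = Field(default=None, gt=0)
    force_rate_hz: Optional[float] = Field(default=None, gt=0)
    dialect: DialectConfig = DialectConfig()
    filters: FilterConfig = FilterConfig()
    events: EventConfig = EventConfig()
    params: List[str] = list(CANONICAL_PARAMS)
    side_convention: Literal["left-minus-right", "right-minus-left"] = (
        "left-minus-right")
    covariance: Literal["per-trial", "pooled"] = "per-trial"
    ridge: str = "auto"  # auto | none | a fixed float as string
    out_dir: str = "cgam_out"
    seed: int = 0
    log_level: str = "INFO"

    @field_validator("params")
    @classmethod
    def _check_params(cls, v):
        bad = set(v) - set(CANONICAL_PARAMS)
        if bad:
            raise ValueError(f"unknown parameters {sorted(bad)}")
        if not v:
            raise ValueError("active parameter set must not be empty")
        return v

    @field_validator("ridge")
    @classmethod
    def _check_ridge(cls, v):
        if v in ("auto", "none"):
            return v
        try:
            float(v)
        except ValueError:
            raise ValueError("ridge must be 'auto', 'none', or a number")
        return v

    def ridge_policy(self):
        return self.ridge if self.ridge in ("auto", "none") else float(self.ridge)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text())
        except yaml.YAMLError as exc:
            raise UsageError(f"could not parse config YAML {path}: {exc}") from exc
        try:
            return cls.model_validate(raw)
        except Exception as exc:
            raise UsageError(f"invalid configuration in {path}: {exc}") from exc

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=True))

    def digest(self) -> str:
        """Hash of the scientific configuration (excludes out_dir/log_level,
        which cannot affect the numbers)."""
        payload = self.model_dump(exclude={"out_dir", "log_level"})
        blob = yaml.safe_dump(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()
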