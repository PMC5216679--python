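"""Validated run configuration for the end-to-end pipeline."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator

KNOWN_MODELS = ("glm", "maxent", "maxent-tgb", "papo", "occupancy", "colext")


class GridConfig(BaseModel):
    n_rows: int = Field(30, ge=1)
    n_cols: int = Field(30, ge=1)
    spatial_range: float = Field(3.0, ge=0)


class MCMCSettings(BaseModel):
    n_chains: int = Field(2, ge=1)
    n_iter: int = Field(8000, ge=100)
    burn_in: int = Field(2000, ge=0)
    thin: int = Field(2, ge=1)


class RunConfig(BaseModel):
    """Everything a pipeline run needs; validated before any stage runs."""

    seed: int = 0
    grid: GridConfig = GridConfig()
    models: list[str]
    env_terms: list[str] = ["spruce_volume", "connectivity", "temperature",
                            "precipitation", "temperature:precipitation"]
    bias_terms: list[str] = ["log_population_density", "dist_small_roads"]
    dispersal_km: float = Field(1.0, gt=0)
    n_background: int = Field(2000, ge=10)
    effort: float = Field(3.0, gt=0)
    n_recorders: int = Field(30, ge=1)
    n_plots: int = Field(300, ge=10)
    n_colext_plots: int = Field(400, ge=10)
    set_aside_fraction: float = Field(0.16, ge=0, le=1)
    forecast_variant: str = "both"
    mcmc: MCMCSettings = MCMCSettings()
    n_forward_reps: int = Field(2000, ge=100)

    @field_validator("models")
    @classmethod
    def _check_models(cls, v):
        if not v:
            raise ValueError("model list must not be empty")
        unknown = [m for m in v if m not in KNOWN_MODELS]
        if unknown:
            raise ValueError(f"unknown models {unknown}; choose from {KNOWN_MODELS}")
        return v

    @field_validator("forecast_variant")
    @classmethod
    def _check_variant(cls, v):
        if v not in ("none", "age", "deadwood", "both"):
            raise ValueError(f"unknown forecast variant {v!r}")
        return v

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]
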