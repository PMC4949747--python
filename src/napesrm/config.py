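"""Run configuration with strict schema validation.

One YAML block describes an entire run: acquisition parameters (adduct,
collision energy, scheduling windows), the internal standard and tissue
mass, confirmation tolerances, and the simulator settings.  Unknown keys
are rejected by name so a typo never silently falls back to a default.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .simulate import DEFAULT_IS_NAME

__all__ = ["RunConfig", "SimulatorConfig", "load_config"]


class SimulatorConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    peak_sigma_s: float = Field(4.0, gt=0)
    noise_sd: float = Field(5.0, ge=0)
    baseline_level: float | None = Field(None, ge=0)
    rt_jitter_sd_s: float = Field(1.0, ge=0)
    prep_cv: float = Field(0.05, ge=0)
    ion_ratio: float = Field(0.35, gt=0, le=1)
    sampling_interval_s: float = Field(0.5, gt=0)
    seed: int = 0


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    adduct: str = "M+H"
    collision_energy: float = Field(20.0, gt=0)
    rt_window_min: float = Field(3.0, gt=0)
    q1_window: float = Field(2.0, gt=0)
    q3_window: float = Field(2.0, gt=0)
    cycle_time_s: float = Field(1.0, gt=0)
    f2_neutral_loss: str = "H3PO4"
    is_species: str = DEFAULT_IS_NAME
    is_amount_pmol: float = Field(50.0, gt=0)
    tissue_mass_g: float = Field(0.1, gt=0)
    run_length_min: float = Field(18.0, gt=0)
    rt_delta_min: float = Field(0.05, gt=0)
    ratio_rel_tol: float = Field(0.30, gt=0)
    snr_threshold: float = Field(10.0, gt=0)
    simulator: SimulatorConfig = Field(default_factory=SimulatorConfig)

    @field_validator("adduct")
    @classmethod
    def _known_adduct(cls, v: str) -> str:
        from .lipid_model import get_adduct

        get_adduct(v)
        return v

    @field_validator("f2_neutral_loss")
    @classmethod
    def _known_loss(cls, v: str) -> str:
        if v not in ("H3PO4", "HPO3"):
            raise ValueError("f2_neutral_loss must be 'H3PO4' or 'HPO3'")
        return v


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML run configuration; defaults when ``path`` is None."""
    if path is None:
        return RunConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(data)
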