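"""Declarative run configuration: YAML in, validated + fully resolved out.

Unknown keys are rejected; every run writes a manifest echoing the resolved
configuration plus the provenance (user-supplied vs default) of each section,
so any artifact on disk is reproducible from its manifest alone.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class CommunitySection(_Section):
    m: int = Field(10, ge=1)
    p: int = Field(3, ge=1)
    mean_ctr: float = Field(2.0, gt=0)
    std_ctr: float = Field(0.0, ge=0)
    common_ctr: bool = True
    death_rate_min: float = Field(0.05, gt=0)
    death_rate_max: float = Field(0.5, gt=0)
    adaptation_velocity: float = Field(2.0, ge=0)
    value_min: float = Field(1.0, gt=0)
    value_max: float = Field(2.0, gt=0)
    half_sat_min: float = Field(0.5, gt=0)
    half_sat_max: float = Field(1.5, gt=0)
    supply_total: float = Field(6000.0, gt=0)
    n0: float = Field(1e4, gt=0)
    adaptive: bool = True

    @model_validator(mode="after")
    def _ranges(self) -> "CommunitySection":
        if self.death_rate_max < self.death_rate_min:
            raise ValueError("death_rate_max must be >= death_rate_min")
        if self.value_max < self.value_min:
            raise ValueError("value_max must be >= value_min")
        if self.half_sat_max < self.half_sat_min:
            raise ValueError("half_sat_max must be >= half_sat_min")
        return self


class SupplySection(_Section):
    mode: Literal["constant", "periodic"] = "constant"
    s: Optional[list[float]] = None          # constant supply vector
    s_in: Optional[list[float]] = None
    s_out: Optional[list[float]] = None
    tau_in: float = Field(12.0, gt=0)
    tau_out: float = Field(48.0, gt=0)

    @model_validator(mode="after")
    def _nonneg(self) -> "SupplySection":
        for name in ("s", "s_in", "s_out"):
            vec = getattr(self, name)
            if vec is not None and any(x < 0 for x in vec):
                raise ValueError(f"{name} entries must be non-negative")
        return self


class SimulateSection(_Section):
    t_end: float = Field(1000.0, gt=0)
    n_points: int = Field(200, ge=2)
    extinction_threshold: float = Field(1.0, gt=0)


class ExtinctionScalingSection(_Section):
    cv_grid: list[float] = Field(default_factory=lambda: [0.04, 0.07, 0.125, 0.22, 0.4])
    replicates: int = Field(10, ge=1)
    extinction_order: int = Field(1, ge=1)
    t_max: float = Field(1e5, gt=0)


class SelfOrganizationSection(_Section):
    hull_placement: Literal["inside", "outside"] = "outside"
    stationary_tol: float = Field(1e-7, gt=0)
    t_max: float = Field(5e4, gt=0)


class VariableEnvSection(_Section):
    n_cycles: int = Field(6, ge=1)


class AdaptationVelocitySection(_Section):
    d_values: list[float] = Field(default_factory=lambda: [0.0, 0.05, 0.5, 5.0])
    replicates: int = Field(10, ge=1)


class DecouplingSection(_Section):
    regime: Literal["low_value", "high_degradation"] = "low_value"
    unfavorable_index: int = Field(0, ge=0)


class DiauxicSection(_Section):
    """Parameters of the diauxic simulation / synthetic-curve generation;
    defaults are the synthetic yeast-like exemplar."""

    v_gal: float = Field(2.0e10, gt=0)
    v_eth: float = Field(1.7e10, gt=0)
    K_gal: float = Field(5.0e-4, gt=0)
    K_eth: float = Field(1.0e-3, gt=0)
    delta: float = Field(0.01, gt=0)
    Q: float = Field(4.5e-9, gt=0)
    d: float = Field(1.0e-8, gt=0)
    Y: float = Field(0.5, gt=0)
    n0: float = Field(1.6e5, gt=0)
    c_gal0: float = Field(5.0e-3, gt=0)
    c_eth0: float = Field(0.0, ge=0)
    alpha_gal0: float = Field(2.0e-11, gt=0)
    alpha_eth0: float = Field(1.0e-12, gt=0)
    duration_h: float = Field(70.0, gt=0)
    sampling_interval_h: float = Field(1.0 / 6.0, gt=0)
    noise_sigma: float = Field(0.021189299069938092, ge=0)  # 5% multiplicative
    variant: Literal["adaptive", "fixed"] = "adaptive"


class FitSection(_Section):
    variant: Literal["adaptive", "fixed", "both"] = "both"
    nwalkers: int = Field(32, ge=4)
    nsteps: int = Field(1000, ge=10)
    nburn: Optional[int] = Field(None, ge=0)
    prior_decades: float = Field(3.0, gt=0)


class RunConfig(_Section):
    """Top-level declarative document for one run."""

    experiment: str = "simulate"
    seed: int = Field(0, ge=0)
    outdir: str = "runs"
    community: CommunitySection = Field(default_factory=CommunitySection)
    supply: SupplySection = Field(default_factory=SupplySection)
    simulate: SimulateSection = Field(default_factory=SimulateSection)
    extinction_scaling: ExtinctionScalingSection = Field(
        default_factory=ExtinctionScalingSection
    )
    self_organization: SelfOrganizationSection = Field(
        default_factory=SelfOrganizationSection
    )
    variable_environment: VariableEnvSection = Field(default_factory=VariableEnvSection)
    adaptation_velocity: AdaptationVelocitySection = Field(
        default_factory=AdaptationVelocitySection
    )
    resource_decoupling: DecouplingSection = Field(default_factory=DecouplingSection)
    diauxic: DiauxicSection = Field(default_factory=DiauxicSection)
    fit: FitSection = Field(default_factory=FitSection)

    def provenance(self) -> dict:
        """Which keys were user-supplied vs filled from defaults."""

        def walk(model: BaseModel) -> dict:
            out = {}
            for name in type(model).model_fields:
                value = getattr(model, name)
                source = "user" if name in model.model_fields_set else "default"
                if isinstance(value, BaseModel):
                    out[name] = walk(value)
                else:
                    out[name] = source
            return out

        return walk(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(mode="json"), sort_keys=True)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration; an empty file yields all
    defaults.  Schema violations name the offending key."""
    text = Path(path).read_text()
    doc = yaml.safe_load(text)
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ValueError("configuration document must be a mapping")
    return RunConfig.model_validate(doc)


def dump_config(config: RunConfig, path) -> None:
    Path(path).write_text(config.to_yaml())
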