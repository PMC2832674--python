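"""Run configuration: schema-validated, unknown keys rejected.

A run config (YAML) describes the box, the composition (template
archives + copy numbers), the energy model, and the run length; every
simulation log records the fully resolved config and seed so any run is
reproducible from its artifacts.
"""

from __future__ import annotations

from pydantic import BaseModel, ConfigDict, Field

from .energy import EnergyModelParams

__all__ = ["RunConfig", "EnergyConfig", "CompositionEntry", "load_config"]


class EnergyConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    mode: str = "full"
    eps_lj: float = 0.285
    eps_rep: float = 0.39
    lj_contact: float = 5.0
    cutoff: float = 12.0
    hard_core: float = 4.5
    pairlist_skin: float = 0.0
    pairlist_refresh: int = 40
    temperature: float = 298.15

    def to_params(self) -> EnergyModelParams:
        return EnergyModelParams(**self.model_dump())


class CompositionEntry(BaseModel):
    model_config = ConfigDict(extra="forbid")

    template: str  # path to a crowdbd template archive
    copies: int = Field(ge=0)


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    box_edge: float = Field(gt=0)
    composition: list[CompositionEntry] = []
    energy: EnergyConfig = EnergyConfig()
    timestep: float = Field(default=2.5, gt=0)
    n_steps: int = Field(default=0, ge=0)
    record_every: int = Field(default=40, ge=1)
    seed: int = 0
    min_surface_sep: float = 10.0


def load_config(path) -> RunConfig:
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return RunConfig.model_validate(doc or {})
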