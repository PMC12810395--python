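"""Run configuration: a single declarative, schema-validated document.

The configuration names the objectives and their directions, the oracle,
the featurizer, the budget (batch size q, iterations T, MC samples L,
pool size N) and the generator/filter settings.  Unknown keys are
rejected so that typos fail before any computation starts.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = ["RunConfig", "ObjectiveSpec", "GASettings", "FilterSettings", "load_config"]


class ObjectiveSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    direction: Literal["maximize", "minimize"] = "maximize"


class GASettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    population_size: int = Field(60, ge=2)
    generations: int = Field(25, ge=1)
    mutation_rate: float = Field(0.9, ge=0.0, le=1.0)
    crossover_rate: float = Field(0.4, ge=0.0, le=1.0)
    elite_fraction: float = Field(0.2, ge=0.0, le=1.0)
    beta: float = Field(1.0, ge=0.0)


class FilterSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    max_smiles_length: int = Field(108, ge=1)
    max_sa_score: float = 8.0
    substructure_required: Optional[str] = None
    sa_method: Literal["auto", "ertl", "heuristic"] = "auto"


class RunConfig(BaseModel):
    """Full declarative run configuration (Algorithm-style loop settings)."""

    model_config = ConfigDict(extra="forbid")

    objectives: list[ObjectiveSpec]
    oracle: str = "logp_tpsa"
    featurizer: Literal["descriptors", "hash"] = "descriptors"
    init_data: Optional[str] = None  # labeled-table path (CLI runs)
    q: int = Field(50, ge=1)
    T: int = Field(20, ge=0)
    L: int = Field(256, ge=1)
    N: int = Field(5000, ge=1)
    seed: int = 0
    eps_ref: float = Field(0.0, ge=0.0)  # slack below the initial nadir
    patience: Optional[int] = Field(None, ge=1)  # HV-stall early stopping
    ga: GASettings = GASettings()
    filters: FilterSettings = FilterSettings()

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if not self.objectives:
            raise ValueError("at least one objective required")
        if self.N < self.q:
            raise ValueError("pool size N must be >= batch size q")
        names = [o.name for o in self.objectives]
        if len(set(names)) != len(names):
            raise ValueError("objective names must be unique")
        return self

    @property
    def objective_names(self) -> list[str]:
        return [o.name for o in self.objectives]

    @property
    def directions(self) -> tuple[str, ...]:
        return tuple(o.direction for o in self.objectives)


def load_config(path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return RunConfig.model_validate(raw)


def dump_config(cfg: RunConfig, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg.model_dump(), fh, sort_keys=False)
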