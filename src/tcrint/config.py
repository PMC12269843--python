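"""Validated run configurations (pydantic models, unknown keys rejected)."""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator


class SasaConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    probe_radius: float = Field(1.4, ge=0.0)
    n_points: int = Field(960, ge=100)
    radii_table: str = "default"


class ContactConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    hbond: float = Field(3.5, gt=0)
    vdw: float = Field(4.0, gt=0)
    disulfide: float = Field(4.5, gt=0)
    salt_bridge: float = Field(4.0, gt=0)


class InterfaceConfig(BaseModel):
    """Configuration of a structure-analysis run."""

    model_config = ConfigDict(extra="forbid")

    structure: Path
    mode: Literal["ternary", "apo"] = "ternary"
    reference: Path | None = None  # holo reference for apo superposition
    chain_roles: dict[str, str] = Field(default_factory=dict)
    imgt_ranges: dict[str, tuple[int, int]] | None = None
    p1_seq_id: int | None = None
    contacts: ContactConfig = Field(default_factory=ContactConfig)
    sasa: SasaConfig = Field(default_factory=SasaConfig)
    out_dir: Path = Path("results/interface")
    verbosity: int = 1

    @field_validator("chain_roles")
    @classmethod
    def _roles_known(cls, v: dict[str, str]) -> dict[str, str]:
        from .structure import ROLES

        bad = {r for r in v.values() if r not in ROLES}
        if bad:
            raise ValueError(f"unknown roles {sorted(bad)}")
        return v


class BindingConfig(BaseModel):
    """Configuration of a binding-assay analysis run."""

    model_config = ConfigDict(extra="forbid")

    assay: Literal["spr", "fp"]
    curves: dict[str, Path]  # label -> CSV path
    wildtype: str | None = None  # label of the wild-type curve (impact table)
    pooled: bool = True
    residual_floor: float = 20.0
    out_dir: Path = Path("results/binding")
    seed: int = 0
    verbosity: int = 1


def load_config(path: str | Path, model):
    """Load a YAML/JSON config file into a pydantic model."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return model.model_validate(data)
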