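"""Run configuration (schema-validated), serialization and trace export."""

from __future__ import annotations

import json
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, field_validator

from .parameters import BLOCKABLE, VARIANTS, ModelParameters
from .protocols import ProtocolSpec, drug_to_block


class SolverConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    rtol: float = Field(1e-6, gt=0)
    atol_ca: float = Field(1e-10, gt=0)
    atol: float = Field(1e-6, gt=0)


class RunConfig(BaseModel):
    """Validated configuration of one simulation run.

    The model is fully deterministic: identical configs reproduce
    byte-identical traces, so there is no seed field.
    """

    model_config = ConfigDict(extra="forbid")

    variant: str = "RA"
    temperature: float = 37.0
    protocol: dict = Field(default_factory=lambda: {"kind": "pacing",
                                                    "cl": 1000.0})
    drug: Optional[str] = None
    dose: Optional[str] = None
    block: dict = Field(default_factory=dict)
    ach: float = Field(0.0, ge=0)
    pka: float = Field(0.0, ge=0, le=1)
    solver: SolverConfig = Field(default_factory=SolverConfig)
    grid: float = Field(0.1, gt=0)
    record: list[str] = Field(default_factory=list)

    @field_validator("variant")
    @classmethod
    def _variant_known(cls, v):
        if v not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        return v

    @field_validator("block")
    @classmethod
    def _block_known(cls, b):
        for name, frac in b.items():
            if name not in BLOCKABLE:
                raise ValueError(f"unknown blockable current {name!r}")
            if not 0.0 <= float(frac) <= 1.0:
                raise ValueError("block fractions must lie in [0, 1]")
        return b

    def build(self) -> tuple[ModelParameters, ProtocolSpec]:
        params = ModelParameters.default(self.variant)
        params.values["temperature"] = self.temperature
        params.ach = self.ach
        params.pka = self.pka
        block = dict(self.block)
        if self.drug is not None:
            if self.dose is None:
                raise ValueError("drug specified without a dose")
            block.update(drug_to_block(self.drug, self.dose).block)
        if block:
            params = params.with_block(block)
        return params, ProtocolSpec(**self.protocol)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls.model_validate(json.loads(text))

    def to_json(self) -> str:
        return self.model_dump_json(indent=1)


def write_traces(result, csv_path, meta_path=None, params=None,
                 record=None) -> None:
    """CSV trace export with a JSON sidecar of protocol metadata."""
    frame = result.to_frame()
    if record:
        keep = ["t_ms", "V_mV"] + [c for c in frame.columns
                                   if any(c.startswith(r + "_")
                                          for r in record)]
        frame = frame[keep]
    frame.to_csv(csv_path, index=False)
    if meta_path is not None:
        proto = result.protocol
        meta = {
            "protocol": (json.loads(proto.to_json())
                         if proto is not None else None),
            "solver": result.meta,
            "parameter_digest": (params.digest() if params is not None
                                 else None),
            "variant": params.variant if params is not None else None,
        }
        with open(meta_path, "w") as fh:
            json.dump(meta, fh, indent=1)
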