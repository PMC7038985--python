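"""Declarative run configuration with schema validation.

Defaults mirror the study protocol: a 24-bp duplex, thirty 1 Å stretch
windows of 500 ps (metadata), the nine-point supercoiling grid and 50/200 mM
salt labels.  Unknown keys are errors, not warnings.
"""

from __future__ import annotations

import hashlib
import json
from typing import Literal

from pydantic import BaseModel, ConfigDict, Field, field_validator

from .trajectory import (
    BubbleSpec,
    MotifSpec,
    PerturbationSpec,
    StretchProtocol,
    STUDY_SEQUENCES,
)


class ProtocolConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    step_size: float = 1.0
    n_steps: int = 30
    frames_per_window: int = 25
    window_time: float = 500.0
    trap_constant: float = 500.0

    def build(self) -> StretchProtocol:
        return StretchProtocol(**self.model_dump())


class BubbleConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    bp_start: int
    bp_end: int
    onset_window: int
    severity: float = Field(1.0, ge=0.0, le=1.0)


class MotifConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    bp_start: int
    bp_end: int
    onset_window: int
    mode: Literal["non-canonical-stacking", "non-canonical-hbond"]


class PerturbationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    bubbles: list[BubbleConfig] = []
    motif_regions: list[MotifConfig] = []
    noise_sd: float = Field(0.15, ge=0.0)

    def build(self, salt_label: float) -> PerturbationSpec:
        return PerturbationSpec(
            bubbles=tuple(BubbleSpec(**b.model_dump()) for b in self.bubbles),
            motif_regions=tuple(MotifSpec(**m.model_dump())
                                for m in self.motif_regions),
            noise_sd=self.noise_sd,
            salt_label=salt_label,
        )


class ForceConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    enabled: bool = False
    spring_k: float = Field(2.0, ge=0.0)  # pN/Å
    noise_sd: float = Field(5.0, ge=0.0)  # pN


class RunConfig(BaseModel):
    """One synthetic stretching run, from sequence to reported metrics."""

    model_config = ConfigDict(extra="forbid")

    sequence: str = "(CG)12"  # study name or raw A/T/G/C string
    sigma: float = 0.0
    salt_label: float = 200.0  # mM, metadata
    twist0: float = 36.0  # deg per bp step
    rise0: float = 3.3  # Å per bp step
    protocol: ProtocolConfig = ProtocolConfig()
    perturbation: PerturbationConfig = PerturbationConfig()
    force: ForceConfig = ForceConfig()
    seed: int = 0
    n_trim: int = Field(2, ge=0)
    scheme: str | None = None  # motif scheme name; default from sequence
    outdir: str = "dnastretch_run"

    @field_validator("sigma")
    @classmethod
    def _sigma_bound(cls, v):
        if abs(v) > 0.2:
            raise ValueError(f"|sigma| must be <= 0.2, got {v}")
        return v

    @field_validator("sequence")
    @classmethod
    def _sequence_known(cls, v):
        if v in STUDY_SEQUENCES:
            return v
        bad = [c for c in v.upper() if c not in "ATGC"]
        if bad:
            raise ValueError(
                f"sequence must be a study name {sorted(STUDY_SEQUENCES)} or "
                f"an A/T/G/C string; invalid characters {bad}"
            )
        return v.upper()

    @property
    def bases(self) -> str:
        return STUDY_SEQUENCES.get(self.sequence, self.sequence)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)
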