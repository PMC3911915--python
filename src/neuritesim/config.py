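"""Validated run configuration (YAML) and its mapping onto protocols.

The configuration mirrors the model's parameter table plus a protocol
description.  Physical transport parameters are SI (as in the table);
human-facing quantities use the units of the figures: micrometres for
geometry, hours for protocol times, micromolar for the soma
concentration.  Unknown keys are rejected; every field left at its
default is logged at load time.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .growth import PerturbationEvent, read_trace
from .morphology import YTreeSpec
from .transport import TransportParameters
from .units import HOUR, UM, UMOLAR

__all__ = ["RunConfig", "load_config", "dump_config", "config_hash"]

log = logging.getLogger("neuritesim")

SCHEMA_VERSION = 1


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class ParamsConfig(_Strict):
    """Transport and growth parameters; defaults are the model's
    standard parameter table."""

    D: float = Field(1.0e-11, ge=0, description="tubulin diffusion constant [m^2/s]")
    f: float = Field(6.0e-3, ge=0, le=1, description="fraction bound to active transport")
    v: float = Field(440.0e-9, ge=0, description="active transport speed [m/s]")
    b: float = Field(5.67e-7, ge=0, description="tubulin decay rate [1/s]")
    X: float = Field(4.0e-14, ge=0, description="tubulin per unit length [mol/m]")
    p: float = Field(1.83e-6, ge=0, description="polymerization rate [m/(s*mM)]")
    q: float = Field(9.17e-9, ge=0, description="depolymerization rate [m/s]")
    c_soma_uM: float = Field(5.5, ge=0, description="clamped soma concentration [uM]")
    dt_s: float = Field(1.0, gt=0, description="integration step [s]")
    l_split_um: float = Field(2.5, gt=0, description="shaft split ceiling [um]")
    l_merge_um: float = Field(0.5, gt=0, description="shaft merge floor [um]")
    soma_clamp: bool = True
    interface_area: str = "distal"
    integrator: str = "implicit"

    def to_params(self) -> TransportParameters:
        return TransportParameters(
            diffusion=self.D,
            active_fraction=self.f,
            active_speed=self.v,
            decay=self.b,
            x_per_length=self.X,
            poly_rate=self.p,
            depoly_rate=self.q,
            c_soma=self.c_soma_uM * UMOLAR,
            dt=self.dt_s,
            l_split=self.l_split_um * UM,
            l_merge=self.l_merge_um * UM,
            soma_clamp=self.soma_clamp,
            interface_area=self.interface_area,
            integrator=self.integrator,
        )


class TreeConfig(_Strict):
    kind: str = "y_tree"  # 'y_tree' | 'branched' | 'swc'
    d_a_um: float = Field(50.0, gt=0)
    d_b_um: float = Field(10.0, gt=0)
    diameter_um: float = Field(1.0, gt=0)
    swc_path: str | None = None

    @field_validator("kind")
    @classmethod
    def _known_kind(cls, v: str) -> str:
        if v not in ("y_tree", "branched", "swc"):
            raise ValueError("tree kind must be 'y_tree', 'branched' or 'swc'")
        return v

    def to_source(self):
        if self.kind == "y_tree":
            return YTreeSpec(
                d_a=self.d_a_um * UM,
                d_b=self.d_b_um * UM,
                neurite_diameter=self.diameter_um * UM,
            )
        if self.kind == "branched":
            return "branched"
        if self.swc_path is None:
            raise ValueError("tree kind 'swc' requires swc_path")
        return self.swc_path


class EventConfig(_Strict):
    time_h: float = Field(ge=0)
    growth_cone: int
    multiplier: float = Field(gt=0)

    def to_event(self) -> PerturbationEvent:
        return PerturbationEvent(self.time_h * HOUR, self.growth_cone, self.multiplier)


class ProtocolConfig(_Strict):
    duration_h: float = Field(40.0, gt=0)
    burn_in_h: float = Field(0.0, ge=0)
    output_interval_s: float = Field(300.0, gt=0)
    events: list[EventConfig] = Field(default_factory=list)
    forced_traces: dict[int, str] = Field(
        default_factory=dict, description="growth cone id -> trace file"
    )


class RunConfig(_Strict):
    schema_version: int = SCHEMA_VERSION
    seed: int = 0
    params: ParamsConfig = Field(default_factory=ParamsConfig)
    tree: TreeConfig = Field(default_factory=TreeConfig)
    protocol: ProtocolConfig = Field(default_factory=ProtocolConfig)

    @field_validator("schema_version")
    @classmethod
    def _version(cls, v: int) -> int:
        if v != SCHEMA_VERSION:
            raise ValueError(f"unsupported schema_version {v}")
        return v

    def to_protocol(self):
        from .experiments import Protocol

        return Protocol(
            tree_source=self.tree.to_source(),
            duration=self.protocol.duration_h * HOUR,
            params=self.params.to_params(),
            burn_in=self.protocol.burn_in_h * HOUR,
            events=[e.to_event() for e in self.protocol.events],
            forced_traces={
                g: read_trace(p) for g, p in self.protocol.forced_traces.items()
            },
            output_interval=self.protocol.output_interval_s,
            seed=self.seed,
        )


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML config; ``None`` gives all defaults.
    Defaulted fields are logged."""
    if path is None:
        doc = {}
    else:
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
    cfg = RunConfig.model_validate(doc)
    for section_name in ("params", "tree", "protocol"):
        section = getattr(cfg, section_name)
        defaulted = [
            name
            for name in type(section).model_fields
            if name not in section.model_fields_set
        ]
        if defaulted:
            log.info("config %s: defaulted %s", section_name, ", ".join(defaulted))
    return cfg


def dump_config(cfg: RunConfig, path: str | Path | None = None) -> str:
    """Canonical YAML serialization (stable key order)."""
    text = yaml.safe_dump(cfg.model_dump(), sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def config_hash(cfg: RunConfig) -> str:
    """SHA-256 of the canonical serialization, for run manifests."""
    return hashlib.sha256(dump_config(cfg).encode()).hexdigest()


def write_manifest(
    path: str | Path, command: str, cfg: RunConfig, outputs: list[str]
) -> None:
    from . import __version__

    manifest = {
        "command": command,
        "config_sha256": config_hash(cfg),
        "seed": cfg.seed,
        "version": __version__,
        "outputs": sorted(outputs),
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
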