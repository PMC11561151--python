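"""Versioned YAML/JSON configuration for simulations.

A configuration file bundles the network, dopamine, plasticity and behaviour
parameter blocks with an arena layout and a session protocol.  Unknown keys
are rejected; missing keys fall back to the documented defaults, so a config
file only needs to state deviations.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .bpe import BPEParams, BPEScenario, WeightProfile
from .damod import DAParams
from .embodiment import Arena, BehaviorParams, Protocol, Zone
from .netcore import (AdaptiveThresholdParams, BackgroundParams,
                      MembraneParams, NetworkParams, ReceptorParams)
from .plasticity import PlasticityParams

__all__ = ["SCHEMA_VERSION", "SimulationConfig", "load_config", "save_config",
           "arena_from_dict", "arena_to_dict"]

SCHEMA_VERSION = 1


def _build(cls, data: dict):
    """Recursively construct a (possibly nested) parameter dataclass."""
    if data is None:
        return cls()
    kwargs = {}
    fields = {f.name: f for f in dataclasses.fields(cls)}
    for key, value in data.items():
        if key not in fields:
            raise ValueError(f"unknown key {key!r} for {cls.__name__}")
        f = fields[key]
        sub = f.type if dataclasses.is_dataclass(f.type) else None
        if sub is None and f.default_factory is not dataclasses.MISSING:  # type: ignore
            probe = f.default_factory()  # type: ignore
            if dataclasses.is_dataclass(probe):
                sub = type(probe)
        kwargs[key] = _build(sub, value) if (sub and isinstance(value, dict)) \
            else value
    return cls(**kwargs)


def arena_to_dict(arena: Arena) -> dict:
    return {
        "shape": arena.shape,
        "radius_cm": arena.radius_cm,
        "side_cm": arena.side_cm,
        "context_id": arena.context_id,
        "zones": [{"center_cm": list(map(float, z.center_cm)),
                   "radius_cm": z.radius_cm} for z in arena.zones],
    }


def arena_from_dict(d: dict) -> Arena:
    zones = [Zone(np.asarray(z["center_cm"], dtype=float), z["radius_cm"])
             for z in d.get("zones", [])]
    return Arena(shape=d.get("shape", "circle"),
                 radius_cm=d.get("radius_cm", 33.5),
                 side_cm=d.get("side_cm", 70.0),
                 zones=zones,
                 context_id=d.get("context_id", "R"))


@dataclass
class SimulationConfig:
    """Everything needed to rebuild and run one session reproducibly."""

    network: NetworkParams = field(default_factory=NetworkParams)
    dopamine: DAParams = field(default_factory=DAParams)
    plasticity: PlasticityParams = field(default_factory=PlasticityParams)
    behavior: BehaviorParams = field(default_factory=BehaviorParams)
    arena: Arena = field(default_factory=Arena)
    protocol: Protocol = field(
        default_factory=lambda: Protocol("central_conditioning"))
    duration_s: float = 120.0
    seed: int = 0
    schema_version: int = SCHEMA_VERSION

    def to_dict(self) -> dict:
        d = {
            "schema_version": self.schema_version,
            "duration_s": self.duration_s,
            "seed": self.seed,
            "network": dataclasses.asdict(self.network),
            "dopamine": dataclasses.asdict(self.dopamine),
            "plasticity": dataclasses.asdict(self.plasticity),
            "behavior": dataclasses.asdict(self.behavior),
            "arena": arena_to_dict(self.arena),
            "protocol": dataclasses.asdict(self.protocol),
        }
        return d


def load_config(path) -> SimulationConfig:
    """Load a YAML (or JSON) simulation config."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) if str(path).endswith((".yaml", ".yml")) \
        else json.loads(text)
    version = data.pop("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ValueError(f"unsupported schema version {version}")
    cfg = SimulationConfig(
        network=_build(NetworkParams, data.pop("network", None)),
        dopamine=_build(DAParams, data.pop("dopamine", None)),
        plasticity=_build(PlasticityParams, data.pop("plasticity", None)),
        behavior=_build(BehaviorParams, data.pop("behavior", None)),
        arena=arena_from_dict(data.pop("arena", {})),
        protocol=_build(Protocol, data.pop("protocol",
                                           {"kind": "central_conditioning"})),
        duration_s=data.pop("duration_s", 120.0),
        seed=data.pop("seed", 0),
    )
    if data:
        raise ValueError(f"unknown top-level keys: {sorted(data)}")
    return cfg


def save_config(cfg: SimulationConfig, path) -> None:
    path = Path(path)
    d = cfg.to_dict()
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(d, sort_keys=False))
    else:
        path.write_text(json.dumps(d, indent=2))


# scenario files for the reduced model share the schema style
def load_scenarios(path) -> tuple[BPEParams, list[tuple[str, BPEScenario]]]:
    """Load reduced-model parameters and named scenarios from YAML/JSON."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) if str(path).endswith((".yaml", ".yml")) \
        else json.loads(text)
    pdata = data.get("params", {})
    profile = _build(WeightProfile, pdata.pop("profile", None))
    params = _build(BPEParams, pdata)
    params.profile = profile
    scenarios = [(name, _build(BPEScenario, s))
                 for name, s in data.get("scenarios", {}).items()]
    return params, scenarios
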