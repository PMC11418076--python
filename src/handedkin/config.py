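"""Configuration parsing and run manifests.

A run configuration is a single YAML mapping with a versioned schema:

.. code-block:: yaml

    schema: 1
    demography: {n_breeders_per_sex: 10, dispersal_female: 0.3,
                 dispersal_male: 0.1, mating: monogamy}
    game: {scenario: within_group, surprise_advantage: 0.1,
           handedness_cost: 0.02, stakes: 0.5, group_stakes: 2.5}
    simulation: {n_patches: 200, control: own_genotype_additive,
                 mutation_sd: 0.05, mutation_rate: 0.02,
                 generations: 2000, seed: 1, init_x: 0.5}

CLI flags override file values.  Every CLI invocation writes exactly one
:class:`RunManifest` JSON next to its outputs, recording the full parameter
set, seed and package version, so any run can be replayed byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .demography import Demography
from .errors import ValidationError
from .games import GameParams
from .simulate import SimConfig

SCHEMA_VERSION = 1


def demography_from_dict(d: dict) -> Demography:
    try:
        return Demography(**d)
    except TypeError as exc:
        raise ValidationError(f"bad demography section: {exc}") from exc


def game_from_dict(d: dict) -> GameParams:
    try:
        return GameParams(**d)
    except TypeError as exc:
        raise ValidationError(f"bad game section: {exc}") from exc


def demography_to_dict(d: Demography) -> dict:
    return dataclasses.asdict(d)


def game_to_dict(g: GameParams) -> dict:
    return dataclasses.asdict(g)


def sim_config_to_dict(c: SimConfig) -> dict:
    out = dataclasses.asdict(c)
    out["demog"] = demography_to_dict(c.demog)
    out["game"] = game_to_dict(c.game) if c.game is not None else None
    return out


def sim_config_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    d["demog"] = demography_from_dict(d["demog"])
    if d.get("game") is not None:
        d["game"] = game_from_dict(d["game"])
    try:
        return SimConfig(**d)
    except TypeError as exc:
        raise ValidationError(f"bad simulation config: {exc}") from exc


def load_config(path: str | Path) -> dict[str, Any]:
    """Parse and validate a YAML run-configuration file."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValidationError("config file must contain a YAML mapping")
    schema = raw.get("schema", SCHEMA_VERSION)
    if schema != SCHEMA_VERSION:
        raise ValidationError(f"unsupported config schema {schema!r}")
    out: dict[str, Any] = {"schema": SCHEMA_VERSION}
    if "demography" in raw:
        out["demography"] = demography_from_dict(raw["demography"])
    if "game" in raw:
        out["game"] = game_from_dict(raw["game"])
    if "simulation" in raw:
        sim = dict(raw["simulation"])
        if "demog" not in sim and "demography" in raw:
            sim["demog"] = raw["demography"]
        if "game" not in sim and "game" in raw:
            sim["game"] = raw["game"]
        out["simulation"] = sim_config_from_dict(sim)
    return out


def emit_config(config: dict[str, Any]) -> str:
    """Serialise a parsed config back to YAML; parse(emit(c)) == c."""
    raw: dict[str, Any] = {"schema": SCHEMA_VERSION}
    if "demography" in config:
        raw["demography"] = demography_to_dict(config["demography"])
    if "game" in config:
        raw["game"] = game_to_dict(config["game"])
    if "simulation" in config:
        raw["simulation"] = sim_config_to_dict(config["simulation"])
    return yaml.safe_dump(raw, sort_keys=True)


@dataclass
class RunManifest:
    """Reproducibility record written by every CLI invocation."""

    command: str
    parameters: dict[str, Any]
    seed: int | None = None
    package_version: str = __version__
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )
    outputs: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(self.to_json() + "\n")
        return path
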