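"""Population-model configuration files (YAML/JSON, flat field names).

The packaged default (``data/canine_iohexol.yaml``) carries the published
final population estimates for iohexol in dogs and is the starting point
for every simulation and design-optimisation command.
"""

from __future__ import annotations

import json
from dataclasses import fields
from importlib import resources
from pathlib import Path

import yaml

from .model import InvalidParameterError, PopulationModel

__all__ = ["load_population_config", "save_population_config",
           "default_population"]

_FIELDS = [f.name for f in fields(PopulationModel)]


def _from_mapping(data: dict, source: str) -> PopulationModel:
    if not isinstance(data, dict):
        raise InvalidParameterError(f"{source}: expected a mapping of parameters")
    unknown = sorted(set(data) - set(_FIELDS))
    missing = sorted(set(_FIELDS) - set(data))
    problems = []
    if unknown:
        problems.append(f"unknown keys: {', '.join(unknown)}")
    if missing:
        problems.append(f"missing keys: {', '.join(missing)}")
    if problems:
        raise InvalidParameterError(f"{source}: " + "; ".join(problems))
    return PopulationModel(**{k: float(v) for k, v in data.items()})


def load_population_config(path) -> PopulationModel:
    """Load a PopulationModel from a YAML (or JSON) file with exact field names."""
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text)
    return _from_mapping(data, str(path))


def save_population_config(pop: PopulationModel, path) -> None:
    path = Path(path)
    data = pop.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n", encoding="utf-8")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False), encoding="utf-8")


def default_population() -> PopulationModel:
    """The packaged canine iohexol population model."""
    ref = resources.files("iohexolpk").joinpath("data/canine_iohexol.yaml")
    return _from_mapping(yaml.safe_load(ref.read_text(encoding="utf-8")),
                         "packaged default")
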