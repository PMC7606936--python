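"""Configuration files, result serialization, and test-fixture generation.

A run configuration is a YAML document with two optional top-level keys::

    scenario:                 # ScenarioConfig fields
      scenario_name: tau
      n_cells: 500
      seed: 7
    parameters:               # NetworkParameters overrides
      tau_production_basal: 0.09

Unknown keys anywhere are rejected with the offending key path.  An empty
file yields the full defaults (normal scenario, 20 days, calibrated
parameters).  The versioned default parameter file ships as
``data/default_params.yaml``.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .engine import run_simulation
from .network import (
    SCENARIOS,
    ConfigurationError,
    NetworkParameters,
    ScenarioConfig,
)

__all__ = [
    "load_config",
    "save_config",
    "load_params",
    "save_params",
    "default_params",
    "RunManifest",
    "make_fixture_population",
]

_SCENARIO_FIELDS = {f.name for f in dataclasses.fields(ScenarioConfig)}


def load_params(path) -> NetworkParameters:
    """Read a full or partial parameter file (YAML mapping of field: value)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: expected a mapping of parameter names")
    data.pop("format_version", None)
    merged = NetworkParameters().to_dict()
    unknown = set(data) - set(merged)
    if unknown:
        raise ConfigurationError(f"{path}: unknown parameter(s) {sorted(unknown)}")
    merged.update(data)
    return NetworkParameters.from_dict(merged)


def save_params(params: NetworkParameters, path) -> None:
    data = {"format_version": 1}
    data.update({k: float(v) for k, v in params.to_dict().items()})
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def default_params() -> NetworkParameters:
    """The shipped calibrated defaults (from ``data/default_params.yaml``)."""
    ref = resources.files("neurovuln").joinpath("data/default_params.yaml")
    with resources.as_file(ref) as path:
        return load_params(path)


def load_config(path) -> tuple[ScenarioConfig, NetworkParameters]:
    """Parse a run configuration; defaults filled, unknown keys rejected.

    Returns the validated scenario configuration and the *effective base*
    parameters (calibrated defaults plus any ``parameters:`` overrides;
    scenario perturbations are applied later by the engine).
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: expected a mapping")
    unknown = set(data) - {"scenario", "parameters"}
    if unknown:
        raise ConfigurationError(f"{path}: unknown top-level key(s) {sorted(unknown)}")

    sc_data = data.get("scenario") or {}
    if not isinstance(sc_data, dict):
        raise ConfigurationError(f"{path}: 'scenario' must be a mapping")
    unknown = set(sc_data) - _SCENARIO_FIELDS
    if unknown:
        raise ConfigurationError(f"{path}: scenario: unknown key(s) {sorted(unknown)}")

    name = sc_data.get("scenario_name", "normal")
    if name not in SCENARIOS:
        raise ConfigurationError(
            f"{path}: scenario.scenario_name: unknown scenario {name!r}"
        )
    tau_mult, scales = SCENARIOS[name]
    defaults = {"tau_multiplier": tau_mult, "node_scales": dict(scales)}
    defaults.update(sc_data)
    defaults["scenario_name"] = name
    cfg = ScenarioConfig(**defaults)
    try:
        cfg.validate()
    except ConfigurationError as err:
        raise ConfigurationError(f"{path}: scenario: {err}") from err

    overrides = data.get("parameters") or {}
    if not isinstance(overrides, dict):
        raise ConfigurationError(f"{path}: 'parameters' must be a mapping")
    base = NetworkParameters().to_dict()
    unknown = set(overrides) - set(base)
    if unknown:
        raise ConfigurationError(f"{path}: parameters: unknown key(s) {sorted(unknown)}")
    base.update(overrides)
    params = NetworkParameters.from_dict(base)
    return cfg, params


def save_config(cfg: ScenarioConfig, path, params: NetworkParameters | None = None) -> None:
    """Write a config echo (scenario plus non-default parameter overrides)."""
    doc: dict = {"scenario": dataclasses.asdict(cfg)}
    if params is not None:
        ref = NetworkParameters().to_dict()
        diff = {k: float(v) for k, v in params.to_dict().items() if v != ref[k]}
        if diff:
            doc["parameters"] = diff
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


@dataclass
class RunManifest:
    """Provenance record written alongside every results directory."""

    command: str
    config_path: str
    seed: int
    version: str = __version__
    started: str = ""
    finished: str = ""
    outputs: list = field(default_factory=list)

    def start(self) -> "RunManifest":
        self.started = datetime.datetime.now(datetime.timezone.utc).isoformat()
        return self

    def finish(self, outputs) -> "RunManifest":
        self.finished = datetime.datetime.now(datetime.timezone.utc).isoformat()
        self.outputs = [str(o) for o in outputs]
        return self

    def write(self, directory) -> Path:
        path = Path(directory) / "manifest.json"
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)
        return path


def make_fixture_population(n_cells: int, seed: int) -> pd.DataFrame:
    """Deterministic miniature population snapshot for regression tests.

    Runs a short (2-day) default simulation of at most 100 cells and returns
    the final per-cell records (molecular state, pool counts, phenotype),
    byte-stable for a fixed seed.
    """
    if n_cells > 100:
        raise ConfigurationError("fixture populations are capped at 100 cells")
    cfg = ScenarioConfig(n_cells=n_cells, duration=2.0, dt=0.01, seed=seed)
    traj = run_simulation(cfg)
    final = traj.per_cell[traj.per_cell.time == traj.per_cell.time.max()]
    return final.reset_index(drop=True).round(9)
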