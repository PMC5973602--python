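"""Run configuration: TOML parsing, validation, registry resolution, round-trip."""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .params import (DEFAULT_INITIAL, REGISTRY, ConfigurationError,
                     ModelParams, MutationParams)
from .types import TumorState

__all__ = ["RunConfig", "load_config", "save_config", "resolve_config"]

_MODEL_KEYS = {f.name for f in dataclasses.fields(ModelParams)}
_MUTATION_KEYS = {"rate_per_cell_per_day", "p_major", "p_double"}
_INITIAL_KEYS = {"n00", "n01", "n10", "n11", "R"}
_SOLVER_KEYS = {"rtol", "atol", "method", "sample_interval",
                "extinction_threshold", "max_chunk_days"}
_TOP_KEYS = {"registry", "horizon", "seed", "n_tumors",
             "model", "mutation", "initial", "solver"}


@dataclass
class RunConfig:
    """Fully resolved configuration for one run."""

    model: ModelParams
    mutation: MutationParams | None = None
    initial: dict = field(default_factory=lambda: dict(DEFAULT_INITIAL))
    horizon: float = 3650.0
    seed: int = 0
    n_tumors: int = 200
    solver: dict = field(default_factory=dict)
    registry: str | None = None

    def initial_state(self) -> TumorState:
        d = self.initial
        return TumorState(n=[d["n00"], d["n01"], d["n10"], d["n11"]],
                          R=d["R"], t=0.0)


def _check_unknown(section: dict, allowed: set[str], where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) in {where}: {', '.join(sorted(unknown))}")


def resolve_config(data: dict) -> RunConfig:
    """Build a validated RunConfig from a parsed mapping."""
    _check_unknown(data, _TOP_KEYS, "config")
    registry = data.get("registry", "published_defaults")
    if registry is not None and registry not in REGISTRY:
        raise ConfigurationError(
            f"unknown registry {registry!r}; available: {sorted(REGISTRY)}")
    model_values = dict(REGISTRY[registry]) if registry else {}
    model_section = data.get("model", {})
    _check_unknown(model_section, _MODEL_KEYS, "[model]")
    model_values.update(model_section)
    model = ModelParams(**model_values)

    mutation = None
    if "mutation" in data:
        _check_unknown(data["mutation"], _MUTATION_KEYS, "[mutation]")
        mutation = MutationParams(**data["mutation"])

    initial = dict(DEFAULT_INITIAL)
    if "initial" in data:
        _check_unknown(data["initial"], _INITIAL_KEYS, "[initial]")
        initial.update(data["initial"])
    if any(v < 0 for v in initial.values()):
        raise ConfigurationError(f"initial populations/resource must be "
                                 f"nonnegative: {initial}")

    solver = dict(data.get("solver", {}))
    _check_unknown(solver, _SOLVER_KEYS, "[solver]")

    horizon = float(data.get("horizon", 3650.0))
    if horizon <= 0:
        raise ConfigurationError(f"horizon must be positive, got {horizon}")
    return RunConfig(model=model, mutation=mutation, initial=initial,
                     horizon=horizon, seed=int(data.get("seed", 0)),
                     n_tumors=int(data.get("n_tumors", 200)),
                     solver=solver, registry=registry)


def load_config(path) -> RunConfig:
    """Load and validate a TOML run configuration.

    An empty file resolves to the registry defaults ("published_defaults").
    Unknown keys are rejected with the offending key named.
    """
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    return resolve_config(data)


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    if isinstance(v, (float, np.floating)):
        return repr(float(v))
    return '"' + str(v).replace('"', '\\"') + '"'


def save_config(cfg: RunConfig, path) -> None:
    """Write a resolved configuration back to TOML (round-trips exactly)."""
    lines = []
    if cfg.registry:
        lines.append(f'registry = "{cfg.registry}"')
    lines.append(f"horizon = {_toml_value(cfg.horizon)}")
    lines.append(f"seed = {cfg.seed}")
    lines.append(f"n_tumors = {cfg.n_tumors}")
    lines.append("")
    lines.append("[model]")
    for key in sorted(_MODEL_KEYS):
        v = getattr(cfg.model, key)
        if v is None:
            continue
        lines.append(f"{key} = {_toml_value(v)}")
    if cfg.mutation is not None:
        lines.append("")
        lines.append("[mutation]")
        for key in sorted(_MUTATION_KEYS):
            lines.append(f"{key} = {_toml_value(getattr(cfg.mutation, key))}")
    lines.append("")
    lines.append("[initial]")
    for key in ("n00", "n01", "n10", "n11", "R"):
        lines.append(f"{key} = {_toml_value(cfg.initial[key])}")
    if cfg.solver:
        lines.append("")
        lines.append("[solver]")
        for key in sorted(cfg.solver):
            lines.append(f"{key} = {_toml_value(cfg.solver[key])}")
    Path(path).write_text("\n".join(lines) + "\n")
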