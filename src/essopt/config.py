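"""Run configuration: a serializable mapping that replays a run exactly.

Configs are JSON or YAML mappings with blocks ``problem``, ``solver``,
``ess``, ``cess``, ``multistart``, plus a top-level ``seed``.  A saved
resolved config plus its seed reproduces a run bit-for-bit.
"""

from __future__ import annotations

import importlib
import json
from pathlib import Path
from typing import Any, Callable

import numpy as np
import yaml

from .benchmarks import benchmark_objective
from .cess import CooperationConfig
from .cmnet import build_toy_network_problem, default_grid, generate_synthetic_data
from .ess import ThreadSettings
from .local_search import DhcSettings
from .problem import ObjectiveDataset, OptimizationProblem


class ConfigError(ValueError):
    """Raised with the offending key named."""


_PROBLEM_REGISTRY: dict[str, Callable[..., OptimizationProblem]] = {}


def register_problem(name: str, factory: Callable[..., OptimizationProblem]) -> None:
    """Register a named problem factory (the plug-in contract)."""
    _PROBLEM_REGISTRY[name] = factory


def load_plugin(entry: str) -> Callable[..., OptimizationProblem]:
    """Resolve a ``module:callable`` problem factory."""
    if ":" not in entry:
        raise ConfigError(f"problem.entry must be 'module:callable', got {entry!r}")
    mod_name, attr = entry.split(":", 1)
    module = importlib.import_module(mod_name)
    return getattr(module, attr)


def load_config(path: str | Path) -> dict[str, Any]:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        cfg = yaml.safe_load(text)
    elif path.suffix == ".json":
        cfg = json.loads(text)
    else:  # try YAML, a superset of JSON
        cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ConfigError("config root must be a mapping")
    return cfg


def _require(cfg: dict, key: str, context: str) -> Any:
    if key not in cfg:
        raise ConfigError(f"missing config key: {context}.{key}" if context else f"missing config key: {key}")
    return cfg[key]


def build_problem(cfg: dict[str, Any]) -> OptimizationProblem:
    pcfg = _require(cfg, "problem", "")
    kind = _require(pcfg, "kind", "problem")
    if kind == "benchmark":
        return benchmark_objective(
            _require(pcfg, "name", "problem"), int(_require(pcfg, "n_par", "problem"))
        )
    if kind == "toy_network":
        network = build_toy_network_problem(
            n_reactions=int(pcfg.get("n_reactions", 3)),
            seed=int(pcfg.get("network_seed", 0)),
        )
        variant = pcfg.get("variant", "dynamic")
        if "measurements" in pcfg:
            dataset = ObjectiveDataset.from_csv(pcfg["measurements"])
        else:
            grid = None
            if "grid_points" in pcfg:
                grid = default_grid(int(pcfg["grid_points"]), float(pcfg.get("grid_spacing", 1.0)))
            dataset = generate_synthetic_data(
                network,
                variant=variant,
                grid=grid,
                noise_cv=float(pcfg.get("noise_cv", 0.0)),
                seed=int(pcfg.get("data_seed", 0)),
            ).dataset
        return network.make_problem(dataset, variant)
    if kind == "registered":
        name = _require(pcfg, "name", "problem")
        if name not in _PROBLEM_REGISTRY:
            raise ConfigError(
                f"problem.name {name!r} not registered; known: {sorted(_PROBLEM_REGISTRY)}"
            )
        return _PROBLEM_REGISTRY[name](**pcfg.get("kwargs", {}))
    if kind == "plugin":
        factory = load_plugin(_require(pcfg, "entry", "problem"))
        return factory(**pcfg.get("kwargs", {}))
    raise ConfigError(f"unknown problem.kind {kind!r}")


def build_ess_settings(cfg: dict[str, Any], seed: int) -> ThreadSettings:
    ecfg = dict(cfg.get("ess", {}))
    local_cfg = ecfg.pop("local", {})
    allowed = {f for f in ThreadSettings.__dataclass_fields__} - {"local_settings"}
    unknown = set(ecfg) - allowed
    if unknown:
        raise ConfigError(f"unknown ess key(s): {sorted(unknown)}")
    settings = ThreadSettings(**ecfg)
    settings.rng_seed = seed
    if local_cfg:
        bad = set(local_cfg) - set(DhcSettings.__dataclass_fields__)
        if bad:
            raise ConfigError(f"unknown ess.local key(s): {sorted(bad)}")
        settings.local_settings = DhcSettings(**local_cfg)
    return settings


def build_coop_config(cfg: dict[str, Any], seed: int) -> CooperationConfig:
    ccfg = dict(cfg.get("cess", {}))
    ccfg.pop("psi_overrides", None)
    unknown = set(ccfg) - set(CooperationConfig.__dataclass_fields__)
    if unknown:
        raise ConfigError(f"unknown cess key(s): {sorted(unknown)}")
    coop = CooperationConfig(**ccfg)
    coop.base_seed = seed
    return coop


def resolved_config(cfg: dict[str, Any], seed: int) -> dict[str, Any]:
    """The config as actually used (seed substituted), for replay."""
    out = json.loads(json.dumps(cfg, default=_jsonable))
    out["seed"] = seed
    return out


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def dump_config(cfg: dict[str, Any], path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))
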