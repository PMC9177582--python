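"""YAML run configuration.

One file configures a whole run: growth-law parameters, solver settings,
inference settings, simulation conditions and cross-validation settings.
Unknown keys are rejected; every field left at its default is logged, so a
run log plus the config suffices to reproduce a run exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields

import yaml

from .growth import GompertzParams
from .master import SolverConfig
from .states import RATE_NAMES, RateVector
from .synthetic import DiameterDistribution, SimConfig

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class InferenceSettings:
    lower: float = 0.0
    upper: float = 10.0
    init: float = 0.01
    multistart: int = 5
    bootstrap_samples: int = 50
    seed: int = 0
    maxfev: int = 5000


@dataclass(frozen=True)
class CVSettings:
    k: int = 10
    seed: int = 0
    grid_step: float = 0.25


@dataclass(frozen=True)
class RunConfig:
    growth: GompertzParams = field(default_factory=GompertzParams)
    solver: SolverConfig = field(default_factory=SolverConfig)
    inference: InferenceSettings = field(default_factory=InferenceSettings)
    simulation: SimConfig = field(default_factory=SimConfig)
    cv: CVSettings = field(default_factory=CVSettings)


def _build(cls, data: dict, path: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} under {path!r}")
    for name in known - set(data):
        default = getattr(cls(), name) if path else None
        logger.info("config: %s.%s left at default", path, name)
    return cls(**data)


def _simulation(data: dict) -> SimConfig:
    data = dict(data)
    if "theta_true" in data:
        th = data["theta_true"]
        unknown = set(th) - set(RATE_NAMES)
        if unknown:
            raise ValueError(f"unknown rate name(s) {sorted(unknown)} in theta_true")
        base = SimConfig().theta_true.as_dict()
        base.update(th)
        data["theta_true"] = RateVector(**base)
    if "diameter_dist" in data:
        data["diameter_dist"] = _build(DiameterDistribution, data["diameter_dist"], "simulation.diameter_dist")
    if "subtype_weights" in data:
        data["subtype_weights"] = tuple(float(w) for w in data["subtype_weights"])
    if "growth" in data:
        data["growth"] = _build(GompertzParams, data["growth"], "simulation.growth")
    return _build(SimConfig, data, "simulation")


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load a RunConfig from YAML (all-defaults when ``path`` is None)."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    if overrides:
        for block, vals in overrides.items():
            data.setdefault(block, {}).update(vals)
    known_blocks = {"growth", "solver", "inference", "simulation", "cv"}
    unknown = set(data) - known_blocks
    if unknown:
        raise ValueError(f"unknown config block(s): {sorted(unknown)}")
    growth = _build(GompertzParams, data.get("growth", {}), "growth")
    solver = _build(SolverConfig, data.get("solver", {}), "solver")
    inference = _build(InferenceSettings, data.get("inference", {}), "inference")
    sim_data = dict(data.get("simulation", {}))
    sim_data.setdefault("growth", {})
    if isinstance(sim_data["growth"], dict) and not sim_data["growth"]:
        sim_data["growth"] = data.get("growth", {})
    simulation = _simulation(sim_data)
    cv = _build(CVSettings, data.get("cv", {}), "cv")
    return RunConfig(growth=growth, solver=solver, inference=inference, simulation=simulation, cv=cv)
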