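"""Pipeline configuration: YAML/JSON round-trippable, unknown keys rejected."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .genotypes import GenotypePerturbation, genotype_registry
from .kinetics import RateParameters, StimulusSpec, ValidationError
from .simulate import SolverSettings

__all__ = ["PipelineConfig", "ConfigError", "load_config", "save_config"]

_SECTIONS = ("parameters", "stimulus", "solver", "genotypes", "qpcr",
             "paths", "seed")

_STIMULUS_KEYS = ("shape", "onset", "duration", "amplitude")
_SOLVER_KEYS = ("rtol", "atol", "n_points", "method", "horizon", "threshold")
_QPCR_KEYS = ("alpha", "ct_threshold")
_GENOTYPE_KEYS = ("eta_scale", "krep_scale", "skip_protein_functional",
                  "extra_depolarization", "leak_scale", "agonist_gain")


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Fully-resolved run configuration.

    ``horizon`` and the 20%-of-peak return ``threshold`` live in the solver
    section; ``genotypes`` holds the registry after any config edits.
    """

    params: RateParameters = field(default_factory=RateParameters)
    stimulus: StimulusSpec = field(default_factory=StimulusSpec)
    solver: SolverSettings = field(default_factory=SolverSettings)
    horizon: float = 50.0
    threshold: float = 0.2
    genotypes: dict[str, GenotypePerturbation] = field(default_factory=genotype_registry)
    alpha: float = 0.05
    ct_threshold: float = 33.0
    paths: dict[str, str] = field(default_factory=dict)
    seed: int = 0

    def as_dict(self) -> dict:
        return {
            "parameters": self.params.as_dict(),
            "stimulus": {"shape": self.stimulus.shape,
                         "onset": self.stimulus.onset,
                         "duration": self.stimulus.duration,
                         "amplitude": self.stimulus.amplitude},
            "solver": {"rtol": self.solver.rtol, "atol": self.solver.atol,
                       "n_points": self.solver.n_points,
                       "method": self.solver.method,
                       "horizon": self.horizon, "threshold": self.threshold},
            "genotypes": {name: {k: v for k, v in g.as_dict().items() if k != "name"}
                          for name, g in self.genotypes.items()},
            "qpcr": {"alpha": self.alpha, "ct_threshold": self.ct_threshold},
            "paths": dict(self.paths),
            "seed": int(self.seed),
        }


def _check_keys(section: str, d: dict, allowed) -> None:
    unknown = set(d) - set(allowed)
    if unknown:
        raise ConfigError(
            f"unknown key(s) in section {section!r}: {sorted(unknown)}; "
            f"allowed: {sorted(allowed)}")


def resolve_config(raw: dict | None) -> PipelineConfig:
    raw = raw or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    _check_keys("<root>", raw, _SECTIONS)

    try:
        params = RateParameters.from_dict(raw.get("parameters") or {})
    except ValidationError as exc:
        raise ConfigError(f"section 'parameters': {exc}") from exc

    stim_raw = raw.get("stimulus") or {}
    _check_keys("stimulus", stim_raw, _STIMULUS_KEYS)
    stimulus = StimulusSpec(**stim_raw)

    solver_raw = dict(raw.get("solver") or {})
    _check_keys("solver", solver_raw, _SOLVER_KEYS)
    horizon = float(solver_raw.pop("horizon", 50.0))
    threshold = float(solver_raw.pop("threshold", 0.2))
    solver = SolverSettings(**solver_raw)

    qpcr_raw = raw.get("qpcr") or {}
    _check_keys("qpcr", qpcr_raw, _QPCR_KEYS)

    registry = genotype_registry()
    for name, edits in (raw.get("genotypes") or {}).items():
        _check_keys(f"genotypes.{name}", edits, _GENOTYPE_KEYS)
        base = registry.get(name, GenotypePerturbation(name=name))
        registry[name] = base.replace(**edits)

    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        raise ConfigError(f"seed must be an integer, got {seed!r}")

    return PipelineConfig(
        params=params, stimulus=stimulus, solver=solver,
        horizon=horizon, threshold=threshold, genotypes=registry,
        alpha=float(qpcr_raw.get("alpha", 0.05)),
        ct_threshold=float(qpcr_raw.get("ct_threshold", 33.0)),
        paths={str(k): str(v) for k, v in (raw.get("paths") or {}).items()},
        seed=seed,
    )


def load_config(path) -> PipelineConfig:
    """Read a YAML or JSON config file; absent sections get defaults."""
    path = Path(path)
    text = path.read_text()
    try:
        if path.suffix == ".json":
            raw = json.loads(text) if text.strip() else {}
        else:
            raw = yaml.safe_load(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    return resolve_config(raw)


def save_config(config: PipelineConfig, path) -> None:
    path = Path(path)
    d = config.as_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))
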