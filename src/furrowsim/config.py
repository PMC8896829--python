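"""Run configuration: YAML/JSON round-trip with strict validation.

All lengths are micrometres, areas square micrometres; spring constants
and energies are in the model's arbitrary units (the standard parameter
set is unitless).  Unknown keys are rejected so that typos never
silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .equilibrate import default_schedule
from .geometry import GeometryParams
from .mechanics import ModelParams

__all__ = ["SolverSettings", "RunConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class SolverSettings:
    """Minimizer settings (see :func:`furrowsim.equilibrate.minimize_energy`)."""

    gtol: float | None = None      # None: scaled default 1e-6 * mu0 * a0
    max_iter: int | None = None    # None: per-method default
    method: str = "newton"
    max_step: float = 1.0          # per-iteration step cap, micrometres
    symmetrize: bool = True

    def __post_init__(self) -> None:
        if self.method not in ("newton", "lbfgs"):
            raise ValueError(f"unknown solver method {self.method!r}")
        if self.max_step <= 0:
            raise ValueError("max_step must be positive")


@dataclass
class RunConfig:
    """Everything needed to reproduce a simulation run."""

    geometry: GeometryParams = field(default_factory=GeometryParams)
    model: ModelParams = field(default_factory=ModelParams)
    schedule: list[float] = field(default_factory=default_schedule)
    solver: SolverSettings = field(default_factory=SolverSettings)
    output_dir: str = "furrowsim_out"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.log_level not in ("DEBUG", "INFO", "WARNING", "ERROR"):
            raise ValueError(f"invalid log_level {self.log_level!r}")
        sched = list(map(float, self.schedule))
        if any(s <= 0 for s in sched) or any(
            b <= a for a, b in zip(sched[1:], sched[:-1])
        ):
            raise ValueError("schedule must be positive and strictly decreasing")
        self.schedule = sched

    def to_dict(self) -> dict:
        return {
            "geometry": dataclasses.asdict(self.geometry),
            "model": dataclasses.asdict(self.model),
            "schedule": list(self.schedule),
            "solver": dataclasses.asdict(self.solver),
            "output_dir": self.output_dir,
            "log_level": self.log_level,
        }


_SECTION_TYPES = {
    "geometry": GeometryParams,
    "model": ModelParams,
    "solver": SolverSettings,
}


def _build_section(cls, data: dict, section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(
            f"unknown keys in config section {section!r}: {sorted(unknown)}"
        )
    return cls(**data)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML (or JSON) run configuration.

    Missing sections and fields fall back to the standard defaults
    (Ka=30, Kl=20, mu0=5000, sigma=3, Kv=5000, KY=1, ...); unknown keys
    raise with every offending key named.
    """
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")

    top_known = {"geometry", "model", "schedule", "solver", "output_dir", "log_level"}
    unknown = set(data) - top_known
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")

    kwargs = {}
    for section, cls in _SECTION_TYPES.items():
        if section in data:
            if not isinstance(data[section], dict):
                raise ValueError(f"config section {section!r} must be a mapping")
            kwargs[section] = _build_section(cls, data[section], section)
    if "schedule" in data:
        kwargs["schedule"] = [float(v) for v in data["schedule"]]
    for key in ("output_dir", "log_level"):
        if key in data:
            kwargs[key] = data[key]
    return RunConfig(**kwargs)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Write a config so that ``load_config(save_config(c)) == c``."""
    path = Path(path)
    payload = cfg.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(payload, indent=2))
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))


def apply_overrides(cfg: RunConfig, overrides: list[str]) -> RunConfig:
    """Apply ``section.key=value`` command-line overrides to a config."""
    data = cfg.to_dict()
    for item in overrides:
        if "=" not in item:
            raise ValueError(f"override must look like section.key=value: {item!r}")
        key, raw = item.split("=", 1)
        parts = key.split(".")
        try:
            value = yaml.safe_load(raw)
        except yaml.YAMLError:
            value = raw
        node = data
        for part in parts[:-1]:
            if part not in node or not isinstance(node[part], dict):
                raise ValueError(f"unknown override section {key!r}")
            node = node[part]
        if parts[-1] not in node and parts[-1] not in ("schedule",):
            raise ValueError(f"unknown override key {key!r}")
        node[parts[-1]] = value
    kwargs = {
        section: _build_section(cls, data[section], section)
        for section, cls in _SECTION_TYPES.items()
    }
    return RunConfig(
        schedule=[float(v) for v in data["schedule"]],
        output_dir=data["output_dir"],
        log_level=data["log_level"],
        **kwargs,
    )
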