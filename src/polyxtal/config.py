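"""Run configuration: every tunable of the search in one TOML file.

Sections map one-to-one onto the parameter dataclasses ([thermo],
[barostat], [dynamics], [ost], [alchemical]) plus a [search] section
for the space-group list, the CSD probability cutoff and the job
layout.  Unknown keys are rejected with the offending section named;
every default equals the production value where one exists.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .dynamics import BarostatParams, DynamicsParams, ThermoConditions
from .energy import AlchemicalParams
from .ost import OSTParams
from .symmetry import available_space_groups

__all__ = ["RunConfig", "load_config", "dump_config"]


@dataclass
class RunConfig:
    """All parameters of a polymorph search."""

    thermo: ThermoConditions = field(default_factory=ThermoConditions)
    barostat: BarostatParams = field(default_factory=BarostatParams)
    dynamics: DynamicsParams = field(default_factory=DynamicsParams)
    ost: OSTParams = field(default_factory=OSTParams)
    alchemical: AlchemicalParams = field(default_factory=AlchemicalParams)
    space_groups: list[str] = field(default_factory=list)
    csd_cutoff: float = 0.5  # percent; groups below are not searched
    walkers: int = 12
    jobs: int = 1

    def __post_init__(self) -> None:
        if not self.space_groups:
            self.space_groups = [g.symbol for g in available_space_groups()
                                 if g.csd_weight > self.csd_cutoff]

    def effective_parameters(self) -> dict:
        """Flat mapping of every effective parameter value (for logging)."""
        out: dict = {}
        for section in ("thermo", "barostat", "dynamics", "ost", "alchemical"):
            obj = getattr(self, section)
            for f in dataclasses.fields(obj):
                out[f"{section}.{f.name}"] = getattr(obj, f.name)
        out["search.space_groups"] = ",".join(self.space_groups)
        out["search.csd_cutoff"] = self.csd_cutoff
        out["search.walkers"] = self.walkers
        out["search.jobs"] = self.jobs
        return out


_SECTIONS = {
    "thermo": ThermoConditions,
    "barostat": BarostatParams,
    "dynamics": DynamicsParams,
    "ost": OSTParams,
    "alchemical": AlchemicalParams,
}
_SEARCH_KEYS = {"space_groups", "csd_cutoff", "walkers", "jobs"}


def load_config(path) -> RunConfig:
    """Read a TOML run configuration, rejecting unknown sections or keys."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    kwargs: dict = {}
    for section, payload in data.items():
        if section == "search":
            unknown = set(payload) - _SEARCH_KEYS
            if unknown:
                raise ValueError(f"{path}: unknown keys in [search]: {sorted(unknown)}")
            kwargs.update(payload)
        elif section in _SECTIONS:
            cls = _SECTIONS[section]
            known = {f.name for f in dataclasses.fields(cls)}
            unknown = set(payload) - known
            if unknown:
                raise ValueError(f"{path}: unknown keys in [{section}]: {sorted(unknown)}")
            kwargs[section] = cls(**payload)
        else:
            raise ValueError(f"{path}: unknown section [{section}]")
    return RunConfig(**kwargs)


def dump_config(config: RunConfig, path) -> None:
    """Write the full effective configuration as TOML."""
    lines = []
    for section, cls in _SECTIONS.items():
        lines.append(f"[{section}]")
        obj = getattr(config, section)
        for f in dataclasses.fields(cls):
            v = getattr(obj, f.name)
            lines.append(f"{f.name} = {str(v).lower() if isinstance(v, bool) else v}")
        lines.append("")
    lines.append("[search]")
    groups = ", ".join(f'"{g}"' for g in config.space_groups)
    lines.append(f"space_groups = [{groups}]")
    lines.append(f"csd_cutoff = {config.csd_cutoff}")
    lines.append(f"walkers = {config.walkers}")
    lines.append(f"jobs = {config.jobs}")
    Path(path).write_text("\n".join(lines) + "\n")
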