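"""Run configuration: a flat ``key: value`` text format with dotted
sections, mapped onto solver settings and model parameters.

Unknown keys are rejected so that typos fail loudly; every default is the
documented default of the corresponding dataclass.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

from .electrostatics import SolverSettings
from .engine import DEFAULT_PARAMS, PkaModelParams

__all__ = ["RunConfig", "ConfigError"]


class ConfigError(ValueError):
    pass


@dataclass
class SamplingConfig:
    network_radius: float = 6.0
    torsion_step: float = 30.0
    isosteric_envelope: float = 1.5
    clash_factor: float = 0.7
    strict_clash_factor: float = 0.8


@dataclass
class RunConfig:
    solver: SolverSettings = field(default_factory=SolverSettings)
    sampling: SamplingConfig = field(default_factory=SamplingConfig)
    params: dict = field(default_factory=lambda: {
        rt: dataclasses.replace(p) for rt, p in DEFAULT_PARAMS.items()})
    log_level: str = "INFO"
    seed: int = 0

    @classmethod
    def from_text(cls, text: str) -> "RunConfig":
        cfg = cls()
        for lineno, raw in enumerate(text.splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if ":" not in line:
                raise ConfigError(f"line {lineno}: expected 'key: value'")
            key, value = (s.strip() for s in line.split(":", 1))
            cfg._set(key, value, lineno)
        return cfg

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls.from_text(fh.read())

    def _set(self, key: str, value: str, lineno: int) -> None:
        parts = key.split(".")
        if parts[0] == "solver" and len(parts) == 2:
            self._set_field(self.solver, parts[1], value, lineno)
        elif parts[0] == "sampling" and len(parts) == 2:
            self._set_field(self.sampling, parts[1], value, lineno)
        elif parts[0] == "model" and len(parts) == 3 \
                and parts[1] in ("HIS", "ASP"):
            self._set_field(self.params[parts[1]], parts[2], value, lineno)
        elif key == "log_level":
            self.log_level = value
        elif key == "seed":
            self.seed = int(value)
        else:
            raise ConfigError(f"line {lineno}: unknown key {key!r}")

    @staticmethod
    def _set_field(obj, name, value, lineno):
        fields = {f.name: f for f in dataclasses.fields(obj)}
        if name not in fields:
            raise ConfigError(f"line {lineno}: unknown key "
                              f"{type(obj).__name__}.{name}")
        typ = fields[name].type
        cur = getattr(obj, name)
        try:
            if isinstance(cur, bool):
                setattr(obj, name, value.lower() in ("1", "true", "yes"))
            elif isinstance(cur, int) and not isinstance(cur, bool):
                setattr(obj, name, int(value))
            elif isinstance(cur, float):
                setattr(obj, name, float(value))
            else:
                setattr(obj, name, value)
        except ValueError:
            raise ConfigError(f"line {lineno}: bad value {value!r} for "
                              f"{name} ({typ})") from None

    def to_text(self) -> str:
        lines = []
        for section, obj in (("solver", self.solver),
                             ("sampling", self.sampling)):
            for f in dataclasses.fields(obj):
                lines.append(f"{section}.{f.name}: {getattr(obj, f.name)}")
        for rt, p in self.params.items():
            for f in dataclasses.fields(p):
                if f.name == "restype":
                    continue
                lines.append(f"model.{rt}.{f.name}: {getattr(p, f.name)}")
        lines.append(f"log_level: {self.log_level}")
        lines.append(f"seed: {self.seed}")
        return "\n".join(lines) + "\n"
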