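"""Run configuration: validated, nested, serializable.

Every physical default equals the baseline of the reference simulation
(anatomical radii 6.44/11.46 mm, 1.6 mm onset separation, 72 m/s^2 joint
acceleration, 13 N film load, synovial-fluid properties, 200 um bubble,
observation at 1 cm).  Configs load from TOML or JSON, reject unknown keys,
and round-trip exactly through ``to_dict``/``from_dict``.
"""

from __future__ import annotations

import dataclasses
import json
import math
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .errors import ConfigError
from .pressure import DEFAULT_LOAD_FRACTION

__all__ = ["RunConfig", "JointConfig", "LoadConfig", "FluidConfig",
           "BubbleConfig", "SolverConfig", "AcousticsConfig", "OutputConfig"]


@dataclass(frozen=True)
class JointConfig:
    r_metacarpal_mm: float = 6.44
    r_phalanx_mm: float = 11.46
    separation_mm: float = 1.6
    theta1_rad: float = math.pi / 4.0
    acceleration_m_s2: float = 72.0
    duration_s: float = 0.01


@dataclass(frozen=True)
class LoadConfig:
    w_newton: float = 13.0
    p_atm_pa: float = 101325.0
    load_fraction: float = DEFAULT_LOAD_FRACTION


@dataclass(frozen=True)
class FluidConfig:
    rho_kg_m3: float = 1015.0
    mu_pa_s: float = 0.4
    surface_tension_n_m: float = 0.0467
    vapor_pressure_pa: float = 6500.0
    polytropic_index: float = 1.3


@dataclass(frozen=True)
class BubbleConfig:
    r0_um: float = 200.0
    #: "vapor": anchor the inception pressure at max(p_amb(0), P_v);
    #: "atmospheric": anchor at the zero-load pressure.
    inception_anchor: str = "vapor"
    stop_at_rebound: bool = False

    def __post_init__(self) -> None:
        if self.inception_anchor not in ("vapor", "atmospheric"):
            raise ConfigError(
                f"inception_anchor must be 'vapor' or 'atmospheric', "
                f"got {self.inception_anchor!r}"
            )


@dataclass(frozen=True)
class SolverConfig:
    method: str = "Radau"
    rtol: float = 1e-7
    atol: float = 1e-7
    max_step_fraction: float = 1.0 / 400.0

    def __post_init__(self) -> None:
        if self.method not in ("Radau", "BDF", "LSODA"):
            raise ConfigError(f"unsupported stiff method {self.method!r}")


@dataclass(frozen=True)
class AcousticsConfig:
    rho_m_kg_m3: float = 1015.0
    distance_m: float = 0.01
    p_ref_pa: float = 2e-5


@dataclass(frozen=True)
class OutputConfig:
    resample_hz: float = 44000.0
    pad_to_s: float = 1.0
    wav_sample_rate: int = 44100
    window: Optional[str] = None


_SECTIONS = {
    "joint": JointConfig,
    "load": LoadConfig,
    "fluid": FluidConfig,
    "bubble": BubbleConfig,
    "solver": SolverConfig,
    "acoustics": AcousticsConfig,
    "output": OutputConfig,
}


@dataclass(frozen=True)
class RunConfig:
    joint: JointConfig = field(default_factory=JointConfig)
    load: LoadConfig = field(default_factory=LoadConfig)
    fluid: FluidConfig = field(default_factory=FluidConfig)
    bubble: BubbleConfig = field(default_factory=BubbleConfig)
    solver: SolverConfig = field(default_factory=SolverConfig)
    acoustics: AcousticsConfig = field(default_factory=AcousticsConfig)
    output: OutputConfig = field(default_factory=OutputConfig)

    # -- construction ------------------------------------------------------
    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        if not isinstance(data, dict):
            raise ConfigError("config must be a mapping of sections")
        unknown = set(data) - set(_SECTIONS)
        if unknown:
            raise ConfigError(f"unknown config sections: {sorted(unknown)}")
        sections = {}
        for name, section_cls in _SECTIONS.items():
            block = data.get(name, {})
            if not isinstance(block, dict):
                raise ConfigError(f"section [{name}] must be a table")
            valid = {f.name for f in dataclasses.fields(section_cls)}
            bad = set(block) - valid
            if bad:
                raise ConfigError(
                    f"unknown keys in [{name}]: {sorted(bad)}"
                )
            try:
                sections[name] = section_cls(**block)
            except TypeError as exc:  # wrong types etc.
                raise ConfigError(f"invalid section [{name}]: {exc}") from exc
        return cls(**sections)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        if path.suffix.lower() == ".json":
            data = json.loads(path.read_text())
        elif path.suffix.lower() == ".toml":
            data = tomllib.loads(path.read_text())
        else:
            raise ConfigError(f"unsupported config format: {path.suffix!r}")
        return cls.from_dict(data)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {name: dataclasses.asdict(getattr(self, name))
                for name in _SECTIONS}

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    def save(self, path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    def replace_value(self, section: str, key: str, value) -> "RunConfig":
        """Functional update of one key, revalidating the section."""
        if section not in _SECTIONS:
            raise ConfigError(f"unknown section {section!r}")
        block = dataclasses.asdict(getattr(self, section))
        if key not in block:
            raise ConfigError(f"unknown key {key!r} in [{section}]")
        block[key] = value
        return dataclasses.replace(self, **{section: _SECTIONS[section](**block)})
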