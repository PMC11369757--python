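"""TOML run configuration with full defaults and strict key checking.

Every directive has a default, so an empty file is a valid configuration;
unknown keys are rejected with their dotted location. The directive names
``transfer_learning`` and ``full_seeding`` mirror the training engine's
configuration file.
"""

from __future__ import annotations

import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .gpr import DEFAULT_NOISE_BOUNDS, DEFAULT_THETA_BOUNDS
from .hyperopt import GWOConfig
from .transfer import TLConfig

__all__ = ["RunConfig", "ConfigError", "load_config", "dump_config"]


class ConfigError(ValueError):
    """Bad configuration file (unknown key, wrong type)."""


@dataclass
class DataSection:
    n_train: int = 1500
    n_val: int = 300
    n_test: int = 500
    spread: float = 0.05
    energy_margin: float = 1.0
    charge_margin: float = 0.001
    xyz_path: str = ""
    properties_path: str = ""


@dataclass
class KernelSection:
    strict_mod3: bool = False
    search_prefactor: bool = False


@dataclass
class GWOSection:
    W: int = 50
    pool: int = 500
    tau: int = 200
    a_max: float = 2.0
    n_lucky: int = 5
    p_period: int = 5
    r_lucky: float = 0.20
    theta_min: float = DEFAULT_THETA_BOUNDS[0]
    theta_max: float = DEFAULT_THETA_BOUNDS[1]
    noise_min: float = DEFAULT_NOISE_BOUNDS[0]
    noise_max: float = DEFAULT_NOISE_BOUNDS[1]
    vanilla_C: bool = False


@dataclass
class TransferSection:
    transfer_learning: int = 0
    eta: float = 0.25
    zeta: float = 0.10
    r_max: float = 0.25
    full_seeding: int = 0
    n_sources: int = 1
    a_max_guess: float = 2.0
    a_max_relax: float = 1.0


@dataclass
class TrainSection:
    targets: list[str] = field(default_factory=lambda: ["E_IQA", "Q00"])


@dataclass
class ExperimentSection:
    train_sizes: list[int] = field(default_factory=lambda: [100, 200, 400])
    etas: list[float] = field(default_factory=lambda: [0.01, 0.10, 0.25])
    zetas: list[float] = field(default_factory=lambda: [0.0, 0.05, 0.10])
    grid: bool = True
    learning_curve: bool = False


@dataclass
class RunConfig:
    seed: int = 0
    data: DataSection = field(default_factory=DataSection)
    kernel: KernelSection = field(default_factory=KernelSection)
    gwo: GWOSection = field(default_factory=GWOSection)
    transfer: TransferSection = field(default_factory=TransferSection)
    train: TrainSection = field(default_factory=TrainSection)
    experiment: ExperimentSection = field(default_factory=ExperimentSection)

    def gwo_config(self, seed: int | None = None) -> GWOConfig:
        g = self.gwo
        return GWOConfig(
            W=g.W, pool=g.pool, tau=g.tau, a_max=g.a_max,
            n_lucky=g.n_lucky, p_period=g.p_period, r_lucky=g.r_lucky,
            theta_bounds=(g.theta_min, g.theta_max),
            noise_bounds=(g.noise_min, g.noise_max),
            seed=self.seed if seed is None else seed,
            vanilla_C=g.vanilla_C,
            search_prefactor=self.kernel.search_prefactor,
        )

    def tl_config(self) -> TLConfig:
        t = self.transfer
        return TLConfig(eta=t.eta, zeta=t.zeta, r_max=t.r_max,
                        full_seeding=bool(t.full_seeding),
                        n_sources=t.n_sources, a_max_guess=t.a_max_guess,
                        a_max_relax=t.a_max_relax)


_SECTIONS = {
    "data": DataSection, "kernel": KernelSection, "gwo": GWOSection,
    "transfer": TransferSection, "train": TrainSection,
    "experiment": ExperimentSection,
}


def _fill(cls, mapping: dict, location: str):
    obj = cls()
    fields = obj.__dataclass_fields__
    for key, value in mapping.items():
        if key not in fields:
            raise ConfigError(f"unknown key {location}.{key}")
        current = getattr(obj, key)
        if isinstance(current, bool):
            if not isinstance(value, bool):
                raise ConfigError(f"{location}.{key} must be a boolean")
        elif isinstance(current, int) and not isinstance(value, bool):
            if isinstance(value, float) and not value.is_integer():
                raise ConfigError(f"{location}.{key} must be an integer")
            value = int(value)
        elif isinstance(current, float):
            value = float(value)
        setattr(obj, key, value)
    return obj


def parse_config(data: dict) -> RunConfig:
    cfg = RunConfig()
    for key, value in data.items():
        if key == "seed":
            cfg.seed = int(value)
        elif key in _SECTIONS:
            if not isinstance(value, dict):
                raise ConfigError(f"{key} must be a table")
            setattr(cfg, key, _fill(_SECTIONS[key], value, key))
        else:
            raise ConfigError(f"unknown key {key}")
    return cfg


def load_config(path) -> RunConfig:
    with open(path, "rb") as fh:
        try:
            data = tomllib.load(fh)
        except tomllib.TOMLDecodeError as exc:
            raise ConfigError(f"{path}: {exc}") from exc
    return parse_config(data)


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return f'"{v}"'
    if isinstance(v, list):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v)}")


def dump_config(cfg: RunConfig) -> str:
    """Serialize back to TOML text (parse(dump(parse(x))) is identity)."""
    out = [f"seed = {cfg.seed}", ""]
    for name in _SECTIONS:
        out.append(f"[{name}]")
        for key, value in asdict(getattr(cfg, name)).items():
            out.append(f"{key} = {_toml_value(value)}")
        out.append("")
    return "\n".join(out)
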