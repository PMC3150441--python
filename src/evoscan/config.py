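"""Run configuration: one TOML file with a section per stage.

Defaults equal the study constants: SNP thresholds 0.30/0.10/0.80, 5x
minimum depth, 1 kb bins, CBS alpha 0.01 / min width 5 / sd-undo 4 /
10,000 permutations, mu = 6.44e-10 per bp per generation, ploidy 2.
Unknown keys are rejected.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field

from .cnv import CbsParams
from .errors import ConfigError
from .filtering import FilterParams
from .genome import SACCHAROMYCES_NUCLEAR_BP
from .stats import DEFAULT_MU


@dataclass(frozen=True)
class NeutralParams:
    mu: float = DEFAULT_MU
    genome_length: int = SACCHAROMYCES_NUCLEAR_BP
    ploidy: int = 2
    p_coding: float = 0.721
    p_nonsyn: float = 0.787


@dataclass(frozen=True)
class FitnessParams:
    mode: str = "chemostat"
    culture_volume_ml: float = 400.0
    dilution_factor: float = 100.0
    growth_window: int = 5


@dataclass(frozen=True)
class CnvParams:
    bin_width: int = 1000
    pseudocount: float = 0.5


@dataclass
class RunConfig:
    seed: int = 0
    log_level: str = "INFO"
    filter: FilterParams = field(default_factory=FilterParams)
    cbs: CbsParams = field(default_factory=CbsParams)
    cnv: CnvParams = field(default_factory=CnvParams)
    neutral: NeutralParams = field(default_factory=NeutralParams)
    fitness: FitnessParams = field(default_factory=FitnessParams)


_SECTIONS = {"filter": FilterParams, "cbs": CbsParams, "cnv": CnvParams,
             "neutral": NeutralParams, "fitness": FitnessParams}
_TOP_KEYS = {"seed", "log_level"}


def parse_config(text: str) -> RunConfig:
    data = tomllib.loads(text)
    kwargs = {}
    for key, value in data.items():
        if key in _TOP_KEYS:
            kwargs[key] = value
        elif key in _SECTIONS:
            cls = _SECTIONS[key]
            known = {f.name for f in dataclasses.fields(cls)}
            unknown = set(value) - known
            if unknown:
                raise ConfigError(f"unknown keys in [{key}]: {sorted(unknown)}")
            kwargs[key] = cls(**value)
        else:
            raise ConfigError(f"unknown config key {key!r}")
    return RunConfig(**kwargs)


def load_config(path) -> RunConfig:
    with open(path, "rb") as fh:
        return parse_config(fh.read().decode())


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, str):
        return f'"{v}"'
    if isinstance(v, float):
        return repr(v)
    return str(v)


def serialize_config(cfg: RunConfig) -> str:
    """Emit TOML that :func:`parse_config` maps back to the same RunConfig."""
    lines = [f"seed = {cfg.seed}", f'log_level = "{cfg.log_level}"', ""]
    for section, cls in _SECTIONS.items():
        lines.append(f"[{section}]")
        obj = getattr(cfg, section)
        for f in dataclasses.fields(cls):
            lines.append(f"{f.name} = {_toml_value(getattr(obj, f.name))}")
        lines.append("")
    return "\n".join(lines)
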