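"""Configuration files, seed streams and result I/O.

A run configuration is a JSON or YAML document whose sections mirror the
parameter dataclasses field-for-field.  Unknown keys are rejected with the
offending field path so typos fail loudly.  One root seed feeds named child
streams (initialization, binarization, splits, ...), so adding a consumer of
randomness never perturbs the draws of the others.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from .binary import TransferParams
from .core import OcoaParams
from .errors import ConfigError
from .objectives import SubsetFitnessParams
from .synthetic import GeneratorSpec


def seed_stream(seed: int, name: str) -> np.random.Generator:
    """Independent named child stream of a root seed.

    The child is keyed by ``(seed, crc32(name))`` through a SeedSequence, so
    streams for different names are statistically independent and each is
    stable across runs and platforms.
    """
    key = zlib.crc32(name.encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


_SECTION_TYPES = {
    "optimizer": OcoaParams,
    "transfer": TransferParams,
    "fitness": SubsetFitnessParams,
    "generator": GeneratorSpec,
}


@dataclass
class RunConfig:
    """Validated parameter bundle for a command-line run."""

    seed: int = 0
    verbosity: str = "info"
    optimizer: OcoaParams = field(default_factory=OcoaParams)
    transfer: TransferParams = field(default_factory=TransferParams)
    fitness: SubsetFitnessParams = field(default_factory=SubsetFitnessParams)
    generator: GeneratorSpec = field(default_factory=GeneratorSpec)

    def to_dict(self) -> Dict:
        out: Dict = {"seed": self.seed, "verbosity": self.verbosity}
        for name in _SECTION_TYPES:
            out[name] = dataclasses.asdict(getattr(self, name))
        return out


def _build_section(cls, data: Dict, path: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        key = sorted(unknown)[0]
        raise ConfigError(f"unknown key {path}.{key!r}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid section {path!r}: {exc}") from exc


def config_from_dict(data: Dict) -> RunConfig:
    if not isinstance(data, dict):
        raise ConfigError("configuration root must be a mapping")
    known = {"seed", "verbosity", *_SECTION_TYPES}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown key {sorted(unknown)[0]!r}")
    cfg = RunConfig(seed=int(data.get("seed", 0)), verbosity=str(data.get("verbosity", "info")))
    for name, cls in _SECTION_TYPES.items():
        if name in data:
            setattr(cfg, name, _build_section(cls, dict(data[name]), name))
    return cfg


def load_config(path) -> RunConfig:
    """Load and validate a JSON or YAML run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    try:
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ConfigError(f"could not parse {path}: {exc}") from exc
    return config_from_dict(data)


def save_config(config: RunConfig, path) -> None:
    """Write a configuration that :func:`load_config` round-trips losslessly."""
    path = Path(path)
    data = config.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


RESULT_COLUMNS: List[str] = [
    "algorithm",
    "average_error",
    "average_select_size",
    "average_fitness",
    "best_fitness",
    "worst_fitness",
    "std_fitness",
]


def write_results(records, path, columns: Optional[List[str]] = None) -> None:
    """Write result records to CSV with stable column order and 9-decimal floats."""
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        records = list(records)
        if not records:
            raise ConfigError("no records to write")
        df = pd.DataFrame(records)
    if df.empty:
        raise ConfigError("no records to write")
    if columns is not None:
        df = df[columns]
    df.to_csv(path, index=False, float_format="%.9f")


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path)
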