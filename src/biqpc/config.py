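"""Run configuration: defaults, YAML parsing and lossless round-tripping."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["RunConfig", "parse_config", "ConfigError"]


class ConfigError(ValueError):
    """Raised for unknown keys, type mismatches or unparsable config files."""


@dataclass
class RunConfig:
    """Settings of a command-line run; defaults reproduce the study conditions
    (100 Hz, 5-s epochs, 128 epochs, 50 % overlap, 0.25 Hz bispectral grid,
    0.5 Hz neighborhood, FDR q < 0.05, lag_max 50, nboots by the
    sqrt(resolution) rule)."""

    fs: float = 100.0
    epoch_duration: float = 5.0
    n_epochs: int = 128
    overlap_fraction: float = 0.5
    d: float = 0.5
    q_threshold: float = 0.05
    lag_max: int = 50
    nboots: int | None = None
    seed: int = 0
    out_dir: str = "."

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        fields = {f.name: f for f in dataclasses.fields(cls)}
        unknown = sorted(set(mapping) - set(fields))
        if unknown:
            raise ConfigError(f"unknown config keys: {', '.join(unknown)}")
        coerced = {}
        for key, value in mapping.items():
            if value is None and key == "nboots":
                coerced[key] = None
                continue
            target = {"fs": float, "epoch_duration": float, "overlap_fraction": float,
                      "d": float, "q_threshold": float, "n_epochs": int, "lag_max": int,
                      "nboots": int, "seed": int, "out_dir": str}[key]
            try:
                if target is int and isinstance(value, float) and value != int(value):
                    raise ValueError
                coerced[key] = target(value)
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"config key {key!r}: cannot interpret {value!r}") from exc
        return cls(**coerced)


def parse_config(path: str | Path) -> RunConfig:
    """Read a YAML config; an empty file yields all defaults."""
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        line = f" at line {mark.line + 1}" if mark is not None else ""
        raise ConfigError(f"malformed config file{line}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("config file must contain a key-value mapping")
    return RunConfig.from_mapping(data)
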