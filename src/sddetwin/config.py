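"""Run configuration: schema-validated settings driving the pipeline.

A run is fully described by a small mapping (YAML or JSON file, or an
inline dict): preset name, cohort size, master seed, target prevalence,
optional grid overrides and sensitivity settings, and an output directory.
Unknown keys are rejected by name; the resolved configuration is written
next to every run's outputs so any artifact can be regenerated exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .inflammation_models import available_presets

__all__ = ["RunConfig", "parse_config", "resolved_config_dict"]

_GRID_KEYS = {"t0", "t_end", "dt"}
_SENS_KEYS = {"prevalences", "sd_fraction", "cv", "perturbed_parameters"}


@dataclass(frozen=True)
class RunConfig:
    """Immutable, validated settings for one simulation run."""

    preset: str = "reference"
    n_subjects: int = 100
    master_seed: int = 0
    prevalence: float = 0.20
    grid_overrides: dict = field(default_factory=dict)
    sensitivity: dict = field(default_factory=dict)
    output_dir: str = "sddetwin-output"

    def __post_init__(self) -> None:
        if self.preset not in available_presets():
            raise ValueError(
                f"unknown preset {self.preset!r}; available: {available_presets()}"
            )
        if self.n_subjects < 1:
            raise ValueError(f"n_subjects must be >= 1, got {self.n_subjects}")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError(f"prevalence must lie in [0, 1], got {self.prevalence}")
        bad = set(self.grid_overrides) - _GRID_KEYS
        if bad:
            raise ValueError(f"unknown grid override key(s): {sorted(bad)}")
        bad = set(self.sensitivity) - _SENS_KEYS
        if bad:
            raise ValueError(f"unknown sensitivity key(s): {sorted(bad)}")


def parse_config(source=None) -> RunConfig:
    """Build a RunConfig from a YAML/JSON path, a mapping, or nothing.

    Missing keys take their defaults; unknown top-level keys are rejected
    with a message naming the offender. An empty source yields the full
    default configuration.
    """
    if source is None:
        raw = {}
    elif isinstance(source, (str, Path)):
        path = Path(source)
        if not path.is_file():
            raise FileNotFoundError(f"config file not found: {path}")
        raw = yaml.safe_load(path.read_text()) or {}
    elif isinstance(source, dict):
        raw = dict(source)
    else:
        raise TypeError(f"cannot parse config from {type(source).__name__}")

    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    return RunConfig(**raw)


def resolved_config_dict(cfg: RunConfig) -> dict:
    """Plain-dict view of the resolved configuration (for the run record)."""
    return dataclasses.asdict(cfg)


def write_resolved_config(cfg: RunConfig, directory: Path) -> Path:
    """Write the resolved config as JSON next to the run's outputs."""
    directory.mkdir(parents=True, exist_ok=True)
    out = directory / "resolved_config.json"
    out.write_text(json.dumps(resolved_config_dict(cfg), indent=2) + "\n")
    return out
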