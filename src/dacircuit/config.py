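"""Plain-text run configuration: YAML load/save, validation, hashing."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .circuit import ModelParameters
from .task import DEFAULT_COUNTS, TimingConfig

__all__ = ["RunConfig", "load_config", "save_config", "config_hash"]

_TIMING_FIELDS = {f.name for f in dataclasses.fields(TimingConfig)}


@dataclass
class RunConfig:
    """Everything needed to reproduce a simulation or sweep run."""

    parameters: dict[str, float] = field(default_factory=dict)
    timing: dict[str, float] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_COUNTS))
    schedule_seed: int = 0
    sweep_parameters: list[str] = field(default_factory=list)
    cohort_n: int = 50
    sweep_seed: int = 0
    vsr_min: float = 0.90
    mv_min_sd: float = 0.03
    output_dir: str = "results"
    verbosity: int = 1

    def __post_init__(self) -> None:
        unknown = set(self.parameters) - set(ModelParameters.field_names())
        if unknown:
            raise ValueError(
                f"unknown model parameter(s) {sorted(unknown)}; valid names: "
                f"{', '.join(ModelParameters.field_names())}"
            )
        unknown_timing = set(self.timing) - _TIMING_FIELDS
        if unknown_timing:
            raise ValueError(
                f"unknown timing field(s) {sorted(unknown_timing)}; valid "
                f"names: {', '.join(sorted(_TIMING_FIELDS))}"
            )

    # -- materialised objects --------------------------------------------
    def model_parameters(self) -> ModelParameters:
        return ModelParameters.from_dict(self.parameters) if self.parameters \
            else ModelParameters()

    def timing_config(self) -> TimingConfig:
        timing = dict(self.timing)
        window_keys = {"analysis_window", "baseline_window"}
        for key in window_keys & set(timing):
            timing[key] = tuple(timing[key])
        return TimingConfig(**timing)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(
            f"unknown config key(s) {sorted(unknown)}; valid keys: "
            f"{', '.join(sorted(known))}"
        )
    return RunConfig(**raw)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def config_hash(config: RunConfig) -> str:
    """Stable hash of the full configuration, for provenance logging."""
    canonical = json.dumps(config.to_dict(), sort_keys=True, default=list)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]
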