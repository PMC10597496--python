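"""Run configuration: a validated, YAML-serializable bundle of every knob.

Every stochastic component carries its own integer seed so any run can be
reproduced bit-exactly from its saved configuration.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .errors import ConfigurationError

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class Seeds:
    stimulus: int = 1
    frames: int = 2
    sweep: int = 3
    replication: int = 4
    reconstruction: int = 5
    spike_variance: int = 6


@dataclass
class RunConfig:
    """Full experiment configuration with defaults for every field."""

    model: str = "base"
    # geometry / synapse overrides forwarded to load_model
    overrides: dict = field(default_factory=dict)
    # stimulus
    expected_interval_ms: float = 40.0
    duration_ms: float = 10_000.0
    # window parameters
    n_window: int = 10
    include_output_spikes: bool = False
    extension_ms: float = 20.0
    # experiment sizes
    n_patterns: int = 50
    pattern_length: int = 50
    k_frames: int = 100
    k_random_frames: int = 10_000
    frame_run_duration_ms: float = 100_000.0
    n_pairs: int = 500
    reconstruction_duration_ms: float = 100.0
    n_values: tuple = (3, 5, 10, 15, 25, 50)
    # numerics
    dt_ms: float = 0.025
    tau_vr_ms: float = 10.0
    seeds: Seeds = field(default_factory=Seeds)

    def __post_init__(self) -> None:
        if isinstance(self.seeds, dict):
            unknown = set(self.seeds) - {f.name for f in fields(Seeds)}
            if unknown:
                raise ConfigurationError(f"unknown seed keys: {sorted(unknown)}")
            self.seeds = Seeds(**self.seeds)
        self.n_values = tuple(int(n) for n in self.n_values)
        for key in ("expected_interval_ms", "duration_ms", "extension_ms",
                    "dt_ms", "tau_vr_ms", "frame_run_duration_ms",
                    "reconstruction_duration_ms"):
            if getattr(self, key) <= 0:
                raise ConfigurationError(f"{key} must be > 0")
        for key in ("n_window", "n_patterns", "pattern_length", "k_frames",
                    "k_random_frames", "n_pairs"):
            if getattr(self, key) < 1:
                raise ConfigurationError(f"{key} must be >= 1")
        for key, val in self.overrides.items():
            if key.startswith("tau") and val <= 0:
                raise ConfigurationError(f"override {key} must be > 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["n_values"] = list(self.n_values)
        return d


def load_config(path_or_mapping) -> RunConfig:
    """Load and validate a YAML config file (or an already-parsed mapping).

    Unknown keys are rejected with the offending key named; omitted keys
    take their defaults.
    """
    if isinstance(path_or_mapping, dict):
        raw = dict(path_or_mapping)
    else:
        with open(path_or_mapping) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"{path_or_mapping}: expected a mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
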