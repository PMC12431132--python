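"""Run configuration: YAML serialization and per-stage seed derivation."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """A configuration/schema problem (CLI exit code 1)."""


class DataError(RuntimeError):
    """Missing or inconsistent input data (CLI exit code 2)."""


class NumericError(RuntimeError):
    """A numeric failure in a pipeline stage (CLI exit code 3)."""


#: Stage order used for seed fan-out.
STAGES = (
    "simulate", "preprocess", "scalogram", "train-cnn",
    "extract-features", "train-svm", "evaluate", "ablate-depth",
    "compare-kernels",
)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: (seed * 1000003 + stage index) mod 2^31."""
    if stage not in STAGES:
        raise ConfigError(f"unknown stage {stage!r}")
    return (int(global_seed) * 1000003 + STAGES.index(stage)) % (2**31)


@dataclass
class RunConfig:
    """Everything needed to reproduce a run, serializable to YAML."""

    seed: int = 0
    simulate: dict = field(default_factory=dict)     # SimConfig overrides
    preprocess: dict = field(default_factory=lambda: {
        "low_hz": 0.1, "high_hz": 30.0, "window_s": 30.0, "channels": ["C3", "C4"],
        "windows_per_session": None,
    })
    scalogram: dict = field(default_factory=lambda: {
        "n_scales": 64, "freq_range": [0.5, 30.0], "colormap": "viridis",
    })
    cnn: dict = field(default_factory=lambda: {
        "depth": 3, "epochs": 50, "batch_size": 32, "learning_rate": 0.001,
        "patience": 10,
    })
    svm: dict = field(default_factory=lambda: {
        "kernel": "rbf", "C": 1.0, "gamma": 0.4, "search": False,
    })
    eval: dict = field(default_factory=lambda: {
        "mode": "pooled_random", "train_fraction": 0.70, "augment": "before_split",
    })

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        raw = yaml.safe_load(path.read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
        cfg = cls()
        for key, value in raw.items():
            if not hasattr(cfg, key):
                raise ConfigError(f"unknown config field {key!r}")
            current = getattr(cfg, key)
            if isinstance(current, dict):
                if not isinstance(value, dict):
                    raise ConfigError(f"config field {key!r} must be a mapping")
                unknown = set(value) - set(current) if current else set()
                # simulate/scalogram accept any SimConfig/transformer override
                if key in ("preprocess", "cnn", "svm", "eval") and unknown:
                    raise ConfigError(f"unknown key(s) {sorted(unknown)} in {key!r}")
                current.update(value)
            else:
                setattr(cfg, key, value)
        return cfg
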