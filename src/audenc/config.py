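"""Run configuration: strict YAML in, dataclasses out.

Unknown keys are errors, not warnings — a typo in a config must fail
loudly, not silently fall back to a default. Every stage seed is derived
from the single top-level seed through named ``numpy`` seed sequences,
so a config plus a seed pins the whole run.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .stimulus import StimulusSpec


class ConfigError(ValueError):
    pass


def _build(cls, mapping, section):
    if mapping is None:
        return cls()
    if not isinstance(mapping, dict):
        raise ConfigError(f"section '{section}' must be a mapping")
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(
            f"unknown keys in section '{section}': {sorted(unknown)}; "
            f"allowed: {sorted(allowed)}"
        )
    return cls(**mapping)


@dataclass(frozen=True)
class ArchConfig:
    """Shared encoder architecture (auto-encoder and classifier)."""

    filters: tuple = (32, 64, 128, 256)
    filter_lengths: tuple = (64, 32, 16, 8)
    pool_factors: tuple = (1, 2, 2, 2)
    l2_weight: float = 1e-3

    def __post_init__(self):
        object.__setattr__(self, "filters", tuple(self.filters))
        object.__setattr__(self, "filter_lengths", tuple(self.filter_lengths))
        object.__setattr__(self, "pool_factors", tuple(self.pool_factors))


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer settings shared by both trainable models."""

    learning_rate: float = 2e-4
    beta_1: float = 0.5
    beta_2: float = 0.999
    epsilon: float = 1e-8
    weight_decay: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 500
    tol: float = 1e-5
    patience: int = 50

    def __post_init__(self):
        if self.batch_size < 1:
            raise ConfigError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth voxel population for the synthetic BOLD data."""

    n_per_layer: int = 10
    n_null: int = 40
    k_nonzero: int = 5
    snr: float = 5.0


@dataclass(frozen=True)
class EncodingConfig:
    lambda_grid: tuple = (0.05, 0.10, 0.15)
    lam: float | str = "auto"  # fixed penalty, or "auto" for LOO selection

    def __post_init__(self):
        object.__setattr__(self, "lambda_grid", tuple(self.lambda_grid))


@dataclass(frozen=True)
class GroupConfig:
    z_min: float = 2.3
    p_max: float = 0.01


@dataclass(frozen=True)
class ClassifierTrainConfig:
    max_epochs: int = 100
    validation_fraction: float = 0.1
    patience: int = 10
    warm_start_from_dcae: bool = False


@dataclass
class RunConfig:
    stimulus: StimulusSpec = field(default_factory=StimulusSpec)
    arch: ArchConfig = field(default_factory=ArchConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    classifier: ClassifierTrainConfig = field(default_factory=ClassifierTrainConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    encoding: EncodingConfig = field(default_factory=EncodingConfig)
    group: GroupConfig = field(default_factory=GroupConfig)
    seed: int = 0

    _SECTIONS = {
        "stimulus": StimulusSpec,
        "arch": ArchConfig,
        "training": TrainConfig,
        "classifier": ClassifierTrainConfig,
        "simulation": SimulationConfig,
        "encoding": EncodingConfig,
        "group": GroupConfig,
    }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d or {})
        seed = d.pop("seed", 0)
        unknown = set(d) - set(cls._SECTIONS)
        if unknown:
            raise ConfigError(f"unknown top-level sections: {sorted(unknown)}")
        parts = {
            name: _build(section_cls, d.get(name), name)
            for name, section_cls in cls._SECTIONS.items()
        }
        return cls(seed=int(seed), **parts)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        out = {
            name: dataclasses.asdict(getattr(self, name))
            for name in self._SECTIONS
        }
        out["seed"] = self.seed
        # tuples -> lists for clean YAML round-trips
        return yaml.safe_load(yaml.safe_dump(out, default_flow_style=False))

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), default_flow_style=False))

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed (< 2^31) derived from the run seed."""
        ss = np.random.SeedSequence(
            entropy=self.seed, spawn_key=tuple(stage.encode())
        )
        return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def demo_config(seed: int = 0) -> RunConfig:
    """Desk-scale configuration: runs the full pipeline on one CPU.

    Audio at 2 kHz with 30-s excerpts (20 TR windows each), 2 excerpts
    per category, 2 subjects, and a narrow 4-layer encoder. These are
    the package's standing desk-scale study conditions, not knobs.
    """
    return RunConfig(
        stimulus=StimulusSpec(
            sample_rate=2000,
            tr=1.5,
            n_categories=3,
            excerpts_per_category=2,
            excerpt_duration=30.0,
            n_subjects=2,
        ),
        arch=ArchConfig(
            filters=(8, 8, 16, 16), filter_lengths=(16, 8, 8, 8), pool_factors=(1, 2, 2, 2)
        ),
        training=TrainConfig(learning_rate=1e-3, max_epochs=60, patience=15),
        classifier=ClassifierTrainConfig(max_epochs=20, patience=5),
        simulation=SimulationConfig(n_per_layer=10, n_null=40, k_nonzero=5, snr=5.0),
        encoding=EncodingConfig(lam=0.1),
        seed=seed,
    )
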