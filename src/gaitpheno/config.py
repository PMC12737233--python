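"""Run configuration blocks shared across the pipeline stages.

Every tunable the pipeline exposes lives in one of the small dataclasses
below; :class:`RunConfig` bundles them together with paths and the master
seed so a whole run can be described by a single YAML file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import yaml


@dataclass
class SignalConfig:
    """IMU signal conventions: sampling rate, anti-noise low-pass cutoff and
    the common length strides are resampled to (percent-of-gait-cycle grid)."""

    sampling_rate_hz: float = 104.0
    lowpass_cutoff_hz: float = 4.0
    normalized_length: int = 100

    def __post_init__(self) -> None:
        if not 0 < self.lowpass_cutoff_hz < self.sampling_rate_hz / 2:
            raise ValueError(
                "lowpass_cutoff_hz must lie in (0, Nyquist); got "
                f"{self.lowpass_cutoff_hz} at fs={self.sampling_rate_hz}"
            )
        if self.normalized_length < 10:
            raise ValueError("normalized_length must be >= 10")


@dataclass
class ReducerConfig:
    """Channel-reduction settings: PCA keeps the smallest number of components
    reaching ``variance_target`` cumulative explained variance."""

    method: str = "pca"
    variance_target: float = 0.80
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("pca", "tsne"):
            raise ValueError(f"unknown reducer {self.method!r}")
        if not 0 < self.variance_target <= 1:
            raise ValueError("variance_target must be in (0, 1]")


#: The seven fall-related parameters screened by the effect-size gate.
KEY_PARAMETERS = (
    "cadence",
    "step_speed",
    "stride_length",
    "clearance",
    "swing_pct",
    "sppb",
    "tug_s",
)


@dataclass
class GateConfig:
    """Effect-size gate: a clustering condition is admissible only when the
    between-cluster effect size strictly exceeds ``effect_threshold`` (0.14,
    the minimum clinically meaningful value) on at least ``min_passing`` of
    the key parameters."""

    key_parameters: tuple = KEY_PARAMETERS
    effect_threshold: float = 0.14
    min_passing: int = 4
    normality_alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.effect_threshold <= 0:
            raise ValueError("effect_threshold must be > 0")
        if self.min_passing > len(self.key_parameters):
            raise ValueError("min_passing exceeds number of key parameters")


@dataclass
class RunConfig:
    """Single-file configuration for an end-to-end run."""

    output_dir: str = "results/pipeline"
    cohort_dir: str | None = None  # None -> simulate
    n_subjects: int = 146
    separation: float = 1.0
    master_seed: int = 7
    signal: SignalConfig = field(default_factory=SignalConfig)
    reducer: ReducerConfig = field(default_factory=ReducerConfig)
    gate: GateConfig = field(default_factory=GateConfig)
    fusion_weight: float = 1.0
    mds_dim: int = 5
    grid_size: str = "small"  # "small" | "full"
    consensus_n_features: int = 25
    screening_fixed_cutoff: float = 13.50
    missing_rate: float = 0.0

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key, sub in (("signal", SignalConfig), ("reducer", ReducerConfig), ("gate", GateConfig)):
            if key in raw and isinstance(raw[key], dict):
                if key == "gate" and "key_parameters" in raw[key]:
                    raw[key]["key_parameters"] = tuple(raw[key]["key_parameters"])
                raw[key] = sub(**raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def child_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (< 2**31) derived from the master seed."""
    h = np.uint32(2166136261)
    for ch in stage.encode():
        h = np.uint32((int(h) ^ ch) * 16777619 & 0xFFFFFFFF)
    return int((int(h) ^ (master_seed * 2654435761)) % (2**31 - 1))
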