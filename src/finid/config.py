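"""Run configuration shared by every pipeline stage.

All tunables live in one nested structure so that a model file can record
exactly which extraction settings produced it (``config_hash``) and refuse
descriptors extracted under different settings.  The hash is a SHA-256 digest
of the canonical (sorted-key) JSON serialization, so it is stable under field
reordering in YAML files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Any

import yaml


@dataclass(frozen=True)
class ScaleSpaceConfig:
    """Gaussian scale stack and DoG reduction settings.

    sigma0 and k follow the classic SIFT choices (1.6, sqrt(2)); a single
    octave of ``n_levels`` Gaussian levels yields ``n_levels - 1`` DoG rasters.
    ``reduce_mode`` selects how the standard-deviation threshold prunes DoG
    samples: ``abs_le`` (default) eliminates samples with |D| <= sigma_D as
    redundant, keeping the salient minority; ``signed_le`` retains samples
    with D <= sigma_D (the thresholding comparison read as a retention
    rule); ``none`` disables pruning.  ``pooling`` chooses one pooled sigma
    over all levels and pixels (``pooled``) or one sigma per DoG level
    (``per_level``).  Six Gaussian levels give three interior DoG layers
    for the 3x3x3 extremum search.
    """

    sigma0: float = 1.6
    k: float = 2.0 ** 0.5
    n_levels: int = 6
    reduce_mode: str = "abs_le"  # abs_le | signed_le | none
    pooling: str = "pooled"  # pooled | per_level


@dataclass(frozen=True)
class FeatureConfig:
    """Keypoint detection, orientation and descriptor settings."""

    contrast_threshold: float = 0.03
    n_bins: int = 36
    window_sigma_factor: float = 1.5
    peak_mode: str = "peak80"  # peak80 | literal_mean
    sigma_g_mode: str = "half_window"  # half_window | half_scale
    edge_exclusion: int = 4
    max_iter: int = 5
    edge_response_threshold: float = 0.0  # 0 disables principal-curvature filtering


@dataclass(frozen=True)
class ClassifierConfig:
    aggregator: str = "mean"  # mean | median
    n_train_per_class: int = 20


@dataclass(frozen=True)
class EvaluationConfig:
    split_seed: int = 0
    train_frac: float = 0.5


@dataclass(frozen=True)
class RunConfig:
    scale_space: ScaleSpaceConfig = field(default_factory=ScaleSpaceConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def with_updates(self, **block_updates: dict[str, Any]) -> "RunConfig":
        """Return a copy with per-block field overrides.

        Example: ``cfg.with_updates(scale_space={"reduce_mode": "abs_le"})``.
        """
        blocks: dict[str, Any] = {}
        for name, updates in block_updates.items():
            if name not in ("scale_space", "features", "classifier", "evaluation"):
                raise KeyError(f"unknown config block: {name}")
            blocks[name] = replace(getattr(self, name), **updates)
        return replace(self, **blocks)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        known = {
            "scale_space": ScaleSpaceConfig,
            "features": FeatureConfig,
            "classifier": ClassifierConfig,
            "evaluation": EvaluationConfig,
        }
        kwargs = {}
        for name, block_cls in known.items():
            block = data.get(name, {})
            if not isinstance(block, dict):
                raise ValueError(f"config block {name!r} must be a mapping")
            valid = {f for f in block_cls.__dataclass_fields__}
            unknown = set(block) - valid
            if unknown:
                raise ValueError(f"unknown keys in config block {name!r}: {sorted(unknown)}")
            kwargs[name] = block_cls(**block)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)


DEFAULT_CONFIG = RunConfig()
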