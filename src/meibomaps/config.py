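"""Run configuration: one serializable object covering every stage.

The resolved configuration (after defaults) is written into every output
sidecar together with its hash, so any map or score on disk can be traced
back to the exact parameters that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .maps import DEFAULT_CTHETA_THRESHOLD, DEFAULT_GQ_THRESHOLD
from .stft import WindowSpec

__all__ = ["AnalysisConfig"]


@dataclass(frozen=True)
class PreprocessConfig:
    clip_limit: float = 0.01
    tile: int = 64
    method: str = "otsu"      # binarization: 'otsu' | 'adaptive'
    block_size: int = 51      # adaptive only


@dataclass(frozen=True)
class PolarConfig:
    n_q: int = 64
    n_theta: int = 90


@dataclass(frozen=True)
class FitConfig:
    dc_exclusion_bins: int = 2
    max_residual: float = 0.35


@dataclass(frozen=True)
class ThresholdConfig:
    g_q: float = DEFAULT_GQ_THRESHOLD           # (cycles/px) per map pixel
    c_theta: float = DEFAULT_CTHETA_THRESHOLD   # unitless, in [0, 1]


@dataclass(frozen=True)
class ClassifierConfig:
    method: str = "lda"       # 'lda' | 'pca'
    density: str = "kde"      # 'kde' | 'normal'


@dataclass(frozen=True)
class AnalysisConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    window: WindowSpec = field(default_factory=WindowSpec)
    polar: PolarConfig = field(default_factory=PolarConfig)
    fit: FitConfig = field(default_factory=FitConfig)
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    neighborhood: int = 3     # C_theta neighborhood, map pixels
    n_bins: int = 64          # feature histograms
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        kw = dict(d)
        parts = {
            "preprocess": PreprocessConfig,
            "window": WindowSpec,
            "polar": PolarConfig,
            "fit": FitConfig,
            "thresholds": ThresholdConfig,
            "classifier": ClassifierConfig,
        }
        for key, typ in parts.items():
            if key in kw and isinstance(kw[key], dict):
                kw[key] = typ(**kw[key])
        return cls(**kw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]
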