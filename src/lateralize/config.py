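"""Pipeline configuration: the printed analysis settings in one place.

Defaults: band 0.01-0.08 Hz, 4 mm FWHM smoothing, binarization thresholds
0.05..0.30 step 0.05, candidate-filter alpha 0.05, 500-tree forests repeated
50 times with top-50 pooling, linear SVM with C = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .classify import ClassifierConfig
from .selection import RFConfig
from .synthetic import CohortSpec

__all__ = ["PipelineConfig", "demo_config"]


@dataclass
class PipelineConfig:
    band: tuple[float, float] = (0.01, 0.08)
    fwhm_mm: float = 4.0
    thresholds: tuple[float, ...] = (0.05, 0.10, 0.15, 0.20, 0.25, 0.30)
    candidate_alpha: float = 0.05
    rf: RFConfig = field(default_factory=RFConfig)
    svm_c: float = 1.0
    n_null: int = 100
    group_alpha: float = 0.01
    min_cluster_size: int = 16
    seed: int = 0
    cohort: CohortSpec | None = None

    def __post_init__(self) -> None:
        t = tuple(self.thresholds)
        if any(not 0 < x < 1 for x in t) or any(a >= b for a, b in zip(t, t[1:])):
            raise ValueError("thresholds must be strictly increasing within (0, 1)")
        low, high = self.band
        if not 0 <= low < high:
            raise ValueError("band must satisfy 0 <= low < high")
        if self.cohort is not None and high >= 1.0 / (2.0 * self.cohort.tr):
            raise ValueError("band upper edge must lie below the Nyquist frequency")

    def classifier_config(self) -> ClassifierConfig:
        return ClassifierConfig(rf=self.rf, svm_c=self.svm_c,
                                candidate_alpha=self.candidate_alpha)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["band"] = list(self.band)
        d["thresholds"] = list(self.thresholds)
        if self.cohort is not None:
            d["cohort"] = self.cohort.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("rf") and isinstance(d["rf"], dict):
            d["rf"] = RFConfig(**d["rf"])
        if d.get("cohort") and isinstance(d["cohort"], dict):
            d["cohort"] = CohortSpec.from_dict(d["cohort"])
        if "band" in d:
            d["band"] = tuple(d["band"])
        if "thresholds" in d:
            d["thresholds"] = tuple(d["thresholds"])
        return cls(**d)

    def save_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def demo_config(seed: int = 0, effects: bool = True) -> PipelineConfig:
    """Small-cohort demonstration settings: 12 regions on a 12x12x8 grid,
    7 left / 5 right subjects, reduced forest sizes so a full nested LOOCV
    runs in seconds."""
    from .synthetic import strong_lateralized_effects, EffectSpec

    cohort = CohortSpec(
        n_left=7, n_right=5, grid=(12, 12, 8), n_regions=12,
        effect=strong_lateralized_effects(12) if effects else EffectSpec(),
        seed=seed,
    )
    return PipelineConfig(
        rf=RFConfig(n_trees=20, n_reps=2, top_k=5),
        n_null=6,
        seed=seed,
        cohort=cohort,
    )
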