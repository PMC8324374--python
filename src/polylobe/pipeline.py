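"""End-to-end pipeline and its configuration bundle."""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
import yaml

from .counting import CountReport, count_nuclei
from .features import feature_vector
from .lobes import (
    ClassifierThresholds,
    LobarDecision,
    MergeConfig,
    classify_component,
    merge_lobes,
)
from .segmentation import LabelMap, SegmentationConfig, segment_nuclei

__all__ = ["PipelineConfig", "classify_map", "process_image", "PipelineResult"]


@dataclass
class PipelineConfig:
    """All tunable parameters of the counting pipeline in one place.

    Loadable from YAML; unknown keys are rejected so a typo in a config
    file fails loudly instead of silently using a default.
    """

    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    thresholds: ClassifierThresholds = field(default_factory=ClassifierThresholds)
    merge: MergeConfig = field(default_factory=MergeConfig)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        sections = {
            "segmentation": SegmentationConfig,
            "thresholds": ClassifierThresholds,
            "merge": MergeConfig,
        }
        unknown = set(d) - set(sections)
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        kwargs = {}
        for name, typ in sections.items():
            sub = d.get(name, {})
            allowed = {f.name for f in fields(typ)}
            bad = set(sub) - allowed
            if bad:
                raise ValueError(f"unknown keys in [{name}]: {sorted(bad)}")
            kwargs[name] = typ(**sub)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class PipelineResult:
    segmented: LabelMap
    initial_decisions: list[LobarDecision]
    merged: LabelMap
    decisions: list[LobarDecision]
    report: CountReport


def classify_map(
    lmap: LabelMap, thresholds: ClassifierThresholds
) -> list[LobarDecision]:
    """Classify every component of a label map."""
    return [
        classify_component(feature_vector(c), thresholds, label=c.label)
        for c in lmap.components
    ]


def process_image(
    img: np.ndarray, cfg: PipelineConfig | None = None
) -> PipelineResult:
    """Segment, classify, merge lobes and count one micrograph."""
    cfg = cfg or PipelineConfig()
    segmented = segment_nuclei(img, cfg.segmentation)
    initial = classify_map(segmented, cfg.thresholds)
    merged, final = merge_lobes(
        segmented,
        initial,
        cfg.merge,
        cfg.thresholds,
        connectivity=cfg.segmentation.connectivity,
    )
    report = count_nuclei(merged, final)
    return PipelineResult(
        segmented=segmented,
        initial_decisions=initial,
        merged=merged,
        decisions=final,
        report=report,
    )
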