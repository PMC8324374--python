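"""Leukocyte counting and segmentation-accuracy evaluation.

After lobe merging, each connected region of the label map is one leukocyte
nucleus, so the total count ``T`` is simply the number of regions.  The five
per-type counters (neutrophil ``T_N``, eosinophil ``T_E``, basophil ``T_B``,
monocyte ``T_M``, lymphocyte ``T_L``) are bookkeeping slots filled from
ground truth when available; their sum may never exceed ``T`` — exceeding it
is surfaced as a consistency error rather than silently truncated.

Evaluation uses a per-image "segmentation ratio": an image is counted
correct iff the predicted region count equals the ground-truth cell count
AND the predicted regions match ground-truth nuclei one-to-one by
majority-pixel overlap.  Per-class accuracy is correct/samples x 100 and the
pooled accuracy is total-correct / total-samples (never the mean of class
accuracies).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lobes import LobarDecision
from .segmentation import LabelMap

__all__ = [
    "CountReport",
    "ClassAccuracy",
    "EvalResult",
    "count_nuclei",
    "image_is_correct",
    "evaluate_segmentation",
    "LEUKOCYTE_CLASSES",
]

LEUKOCYTE_CLASSES = ("neutrophil", "eosinophil", "basophil", "monocyte", "lymphocyte")


@dataclass
class CountReport:
    T: int
    polylobar_count: int
    unilobar_count: int
    per_type: dict[str, int] = field(
        default_factory=lambda: {k: 0 for k in LEUKOCYTE_CLASSES}
    )

    def __post_init__(self) -> None:
        if self.polylobar_count + self.unilobar_count != self.T:
            raise ValueError("polylobar + unilobar tallies must equal T")
        if sum(self.per_type.values()) > self.T:
            raise ValueError(
                f"per-type counters sum to {sum(self.per_type.values())} > T={self.T}"
            )


@dataclass(frozen=True)
class ClassAccuracy:
    cls: str
    n_samples: int
    n_correct: int

    @property
    def accuracy_pct(self) -> float:
        return 100.0 * self.n_correct / self.n_samples if self.n_samples else 0.0

    @property
    def accuracy_1dp(self) -> float:
        """Accuracy truncated (not rounded) to one decimal place, the
        convention used in published per-class accuracy tables
        (290/300 prints as 96.6, not 96.7)."""
        return _trunc1(self.accuracy_pct)


@dataclass(frozen=True)
class EvalResult:
    per_class: list[ClassAccuracy]

    @property
    def overall_accuracy_pct(self) -> float:
        n = sum(c.n_samples for c in self.per_class)
        k = sum(c.n_correct for c in self.per_class)
        return 100.0 * k / n if n else 0.0

    @property
    def overall_accuracy_1dp(self) -> float:
        return _trunc1(self.overall_accuracy_pct)


def _trunc1(pct: float) -> float:
    # truncate toward zero at 1 dp; nudge for float representation error
    return np.floor(pct * 10 + 1e-9) / 10


def count_nuclei(
    merged: LabelMap,
    decisions: list[LobarDecision],
    truth_types: list[str] | None = None,
) -> CountReport:
    """Count report from a merged label map and its final decisions.

    ``truth_types`` optionally supplies ground-truth leukocyte classes to
    populate the per-type counters (there is no image-based five-type
    classifier; the counters are plumbing for evaluation pipelines).
    """
    if len(decisions) != merged.n:
        raise ValueError("decisions must cover every component")
    poly = sum(1 for d in decisions if d.is_polylobar)
    report = CountReport(
        T=merged.n, polylobar_count=poly, unilobar_count=merged.n - poly
    )
    if truth_types is not None:
        for t in truth_types:
            if t not in report.per_type:
                raise ValueError(f"unknown leukocyte class {t!r}")
            report.per_type[t] += 1
        if sum(report.per_type.values()) > report.T:
            raise ValueError("per-type counter sum exceeds total count T")
    return report


def image_is_correct(predicted: LabelMap, truth_masks: list[np.ndarray]) -> bool:
    """One image is correct iff counts match and regions pair 1:1 by
    majority-pixel overlap with ground-truth nucleus masks."""
    if predicted.n != len(truth_masks):
        return False
    if predicted.n == 0:
        return True
    assigned: set[int] = set()
    for comp in predicted.components:
        overlaps = [
            int(m[comp.coords[:, 0], comp.coords[:, 1]].sum()) for m in truth_masks
        ]
        best = int(np.argmax(overlaps))
        if overlaps[best] * 2 <= comp.area:  # needs a strict pixel majority
            return False
        if best in assigned:
            return False
        assigned.add(best)
    return len(assigned) == len(truth_masks)


def evaluate_segmentation(
    predicted: list[LabelMap],
    truths: list,
) -> EvalResult:
    """Per-class and pooled segmentation accuracy over paired images.

    ``truths`` are :class:`polylobe.synth.GroundTruth` objects (anything
    with ``nucleus_masks`` and ``cell_types``).  Each image is attributed
    to the class of its first cell (one-cell-per-image datasets are the
    intended use; multi-cell images count under their first cell's class).
    """
    if len(predicted) != len(truths):
        raise ValueError("predicted and truth lists must pair 1:1")
    if not predicted:
        raise ValueError("nothing to evaluate")
    stats: dict[str, list[int]] = {}
    for lmap, gt in zip(predicted, truths):
        cls = gt.cell_types[0] if gt.cell_types else "empty"
        n, k = stats.setdefault(cls, [0, 0])
        stats[cls][0] = n + 1
        stats[cls][1] = k + int(image_is_correct(lmap, gt.nucleus_masks))
    order = [c for c in LEUKOCYTE_CLASSES if c in stats] + [
        c for c in stats if c not in LEUKOCYTE_CLASSES
    ]
    return EvalResult(
        per_class=[ClassAccuracy(c, stats[c][0], stats[c][1]) for c in order]
    )
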