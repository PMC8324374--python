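"""Polylobar-candidate classification and minimal-distance lobe merging.

A segmented micrograph may show one polylobar nucleus as several disconnected
regions (its lobes), because the chromatin filaments joining the lobes are
too thin to photograph.  Counting each region as a cell would overcount, so:

1. Every region is classified **polylobar-candidate** or **unilobar** by a
   three-rule cascade on its shape descriptors, each rule with an empirical
   threshold:

   * rule 1: eccentricity ``e > X1`` and ellipse plumpness ``P2 < X2``
     (elongated, hollow-looking groups of lobes);
   * rule 2: rectangle plumpness ``P1 < X3`` and aspect ratio ``s < X4``
     (sprawling, box-underfilling shapes);
   * rule 3: area ``A < X5`` (a single lobe is far smaller than any whole
     unilobar nucleus);
   * otherwise unilobar.

2. Candidate regions are merged by the **minimal-distance rule**: take the
   first unprocessed candidate, find the nearest other region by minimum
   edge-to-edge Euclidean distance, and if that region is also a candidate,
   the gap is within the merge distance cap and the merged area is plausible
   for one nucleus, connect the closest edge-pixel pair with a straight
   line, fill interior holes, relabel and re-classify the merged region.
   Repeat until no merge fires.

Unilobar regions are never absorbed, the component count never increases,
and the procedure is idempotent at its fixpoint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial.distance import cdist
from skimage.draw import line as draw_line
from skimage.feature import canny

from .features import ShapeFeatures, feature_vector
from .segmentation import Component, LabelMap, label_components

__all__ = [
    "ClassifierThresholds",
    "LobarDecision",
    "MergeConfig",
    "classify_component",
    "detect_edges",
    "min_pair_distance",
    "connect_pair",
    "merge_lobes",
]


@dataclass
class ClassifierThresholds:
    """Empirical cascade thresholds X1..X5 (see module docstring).

    Defaults are calibrated for the default synthetic smear geometry; real
    data needs recalibration (see :func:`calibrate_thresholds`).
    """

    x1: float = 0.90   # eccentricity floor for rule 1
    x2: float = 0.85   # ellipse-plumpness ceiling for rule 1
    x3: float = 0.55   # rectangle-plumpness ceiling for rule 2
    x4: float = 0.80   # aspect-ratio ceiling for rule 2
    x5: int = 250      # area ceiling (px) for rule 3

    def __post_init__(self) -> None:
        if not 0 <= self.x1 < 1:
            raise ValueError("x1 must be in [0, 1)")
        if min(self.x2, self.x3, self.x4) <= 0 or self.x5 < 1:
            raise ValueError("x2..x4 must be > 0 and x5 >= 1")


@dataclass(frozen=True)
class LobarDecision:
    label: int
    verdict: str               # "polylobar" | "unilobar"
    rule_fired: str            # "rule2_ecc" | "rule3_rect" | "rule4_area" | "none"

    @property
    def is_polylobar(self) -> bool:
        return self.verdict == "polylobar"


@dataclass
class MergeConfig:
    """Merge guards.

    d_max
        Absolute cap on the edge-to-edge merge distance (px).  When None,
        an adaptive cap is used: 0.6 x the equivalent diameter
        ``2*sqrt(A/pi)`` of the larger component of the pair — lobe gaps
        are small relative to nucleus size, inter-cell gaps are not.
    a_max
        Maximum plausible single-nucleus area; merges exceeding it are
        rejected.
    max_iterations
        Safety cap on merge passes; exceeded only on a logic error.
    """

    d_max: float | None = None
    a_max: int = 2000
    max_iterations: int = 1000
    canny_sigma: float = 1.0

    def pair_cap(self, area_a: int, area_b: int) -> float:
        if self.d_max is not None:
            return self.d_max
        return 0.6 * 2.0 * math.sqrt(max(area_a, area_b) / math.pi)


def classify_component(
    f: ShapeFeatures, th: ClassifierThresholds, label: int = 0
) -> LobarDecision:
    """Run the three-rule cascade on one component's shape descriptors.

    Degenerate features (collapsed ellipse fit) are conservatively judged
    unilobar so a stray artifact never triggers merging.
    """
    if f.degenerate:
        return LobarDecision(label=label, verdict="unilobar", rule_fired="none")
    if f.e > th.x1 and f.P2 < th.x2:
        return LobarDecision(label=label, verdict="polylobar", rule_fired="rule2_ecc")
    if f.P1 < th.x3 and f.s < th.x4:
        return LobarDecision(label=label, verdict="polylobar", rule_fired="rule3_rect")
    if f.A < th.x5:
        return LobarDecision(label=label, verdict="polylobar", rule_fired="rule4_area")
    return LobarDecision(label=label, verdict="unilobar", rule_fired="none")


def detect_edges(
    c: Component, shape: tuple[int, int], sigma: float = 1.0
) -> np.ndarray:
    """Edge pixels of the component's mask via the Canny operator.

    Returns an ``(k, 2)`` array of (row, col) coordinates in row-major
    order.  On a binary mask Canny reduces to boundary extraction; for
    regions too small for the smoothed gradient to respond, the
    morphological boundary (mask minus its erosion) is returned instead,
    so the result is never empty.
    """
    if c.area < 1:
        raise ValueError("empty component")
    mask = c.mask(shape)
    raw = canny(mask.astype(float), sigma=sigma)
    # the thin canny trace straddles the step edge; keep its on-region
    # pixels and snap off-region ones to the adjacent boundary pixel so
    # every reported edge pixel belongs to the component
    inner = mask & ~ndi.binary_erosion(mask)
    snapped = ndi.binary_dilation(raw & ~mask, np.ones((3, 3), bool)) & inner
    edges = (raw & mask) | snapped
    if not edges.any():
        edges = inner if inner.any() else mask
    rr, cc = np.nonzero(edges)
    return np.column_stack([rr, cc])


def min_pair_distance(
    ea: np.ndarray, eb: np.ndarray
) -> tuple[float, tuple[int, int], tuple[int, int]]:
    """Minimum Euclidean distance between two edge-pixel sets.

    Returns ``(d, pa, pb)`` where the pair (pa, pb) attains the minimum;
    ties are broken by row-major order of pa, then pb, so the result is
    deterministic.
    """
    ea = np.asarray(ea)
    eb = np.asarray(eb)
    if len(ea) == 0 or len(eb) == 0:
        raise ValueError("edge sets must be non-empty")
    # row-major sort makes argmin's first-hit the deterministic tie-break
    ea = ea[np.lexsort((ea[:, 1], ea[:, 0]))]
    eb = eb[np.lexsort((eb[:, 1], eb[:, 0]))]
    d2 = cdist(ea, eb, metric="sqeuclidean")
    flat = int(np.argmin(d2))
    i, j = divmod(flat, d2.shape[1])
    d = math.sqrt(float(d2[i, j]))
    return d, (int(ea[i, 0]), int(ea[i, 1])), (int(eb[j, 0]), int(eb[j, 1]))


def connect_pair(
    mask: np.ndarray, pa: tuple[int, int], pb: tuple[int, int]
) -> np.ndarray:
    """Join two points with a digital straight line, then fill holes.

    The Bresenham segment from pa to pb is set to foreground; interior
    holes of the result are filled (a lobe ring closed by the new bridge
    becomes solid).  Returns a new mask.
    """
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    for p in (pa, pb):
        if not (0 <= p[0] < h and 0 <= p[1] < w):
            raise ValueError(f"point {p} outside mask bounds {mask.shape}")
    out = mask.copy()
    rr, cc = draw_line(pa[0], pa[1], pb[0], pb[1])
    out[rr, cc] = True
    return ndi.binary_fill_holes(out)


def merge_lobes(
    lmap: LabelMap,
    decisions: list[LobarDecision],
    cfg: MergeConfig | None = None,
    thresholds: ClassifierThresholds | None = None,
    connectivity: int = 8,
) -> tuple[LabelMap, list[LobarDecision]]:
    """Iteratively merge polylobar-candidate regions by minimal distance.

    Scan order is row-major (label order); each accepted merge reduces the
    component count by exactly one and triggers re-classification of the
    merged region, so a group of lobes that has become nucleus-like stops
    attracting further merges.  Returns the merged label map and the final
    per-component decisions.

    Raises
    ------
    RuntimeError
        If ``cfg.max_iterations`` passes do not reach a fixpoint.
    """
    cfg = cfg or MergeConfig()
    thresholds = thresholds or ClassifierThresholds()
    if len(decisions) != lmap.n:
        raise ValueError("decisions must cover every component")

    shape = lmap.shape
    comps: list[Component] = list(lmap.components)
    verdicts: list[LobarDecision] = list(decisions)
    edges: dict[int, np.ndarray] = {}

    def edge_of(i: int) -> np.ndarray:
        key = id(comps[i])
        if key not in edges:
            edges[key] = detect_edges(comps[i], shape, sigma=cfg.canny_sigma)
        return edges[key]

    for _ in range(cfg.max_iterations):
        processed: set[int] = set()
        merged_this_pass = False
        while True:
            cand = next(
                (
                    i
                    for i in range(len(comps))
                    if i not in processed and verdicts[i].is_polylobar
                ),
                None,
            )
            if cand is None:
                break
            if len(comps) == 1:
                processed.add(cand)
                continue
            # nearest other component by edge-to-edge distance
            best = None
            for j in range(len(comps)):
                if j == cand:
                    continue
                d, pa, pb = min_pair_distance(edge_of(cand), edge_of(j))
                if best is None or d < best[0]:
                    best = (d, j, pa, pb)
            d, j, pa, pb = best
            cap = cfg.pair_cap(comps[cand].area, comps[j].area)
            if (
                d <= cap
                and verdicts[j].is_polylobar
                and comps[cand].area + comps[j].area <= cfg.a_max
            ):
                # connect, fill, and relabel the union of the two regions
                pair_mask = comps[cand].mask(shape) | comps[j].mask(shape)
                joined = connect_pair(pair_mask, pa, pb)
                sub = label_components(joined, connectivity)
                if sub.n != 1:  # line left the pair disconnected: give up
                    processed.add(cand)
                    continue
                merged = sub.components[0]
                keep = [k for k in range(len(comps)) if k not in (cand, j)]
                comps = [comps[k] for k in keep] + [merged]
                verdicts = [verdicts[k] for k in keep] + [
                    classify_component(
                        feature_vector(merged), thresholds, label=len(comps)
                    )
                ]
                processed = set()
                merged_this_pass = True
            else:
                processed.add(cand)
        if not merged_this_pass:
            return _rebuild(comps, verdicts, shape), _relabel(verdicts)
    raise RuntimeError("merge_lobes did not reach a fixpoint")


def _rebuild(
    comps: list[Component], verdicts: list[LobarDecision], shape: tuple[int, int]
) -> LabelMap:
    # deterministic output order: by first (row-major) pixel of each component
    order = sorted(
        range(len(comps)), key=lambda i: (comps[i].coords[0, 0], comps[i].coords[0, 1])
    )
    labels = np.zeros(shape, dtype=np.int32)
    out = []
    for new_lab, i in enumerate(order, start=1):
        c = comps[i]
        labels[c.coords[:, 0], c.coords[:, 1]] = new_lab
        out.append(Component(label=new_lab, coords=c.coords, area=c.area))
    verdicts[:] = [
        LobarDecision(label=k + 1, verdict=verdicts[i].verdict, rule_fired=verdicts[i].rule_fired)
        for k, i in enumerate(order)
    ]
    return LabelMap(labels=labels, components=out)


def _relabel(verdicts: list[LobarDecision]) -> list[LobarDecision]:
    return list(verdicts)


def calibrate_thresholds(
    polylobar_features: list[ShapeFeatures],
    unilobar_features: list[ShapeFeatures],
    margin: float = 0.0,
) -> ClassifierThresholds:
    """Set X1..X5 from labeled feature distributions.

    Analogous to the minimum-area rule used for the platelet filter: X5 is
    placed between the largest lobe area and the smallest unilobar nucleus
    area, X1/X2 bracket the unilobar eccentricity/plumpness extremes, and
    X3/X4 are left at defaults unless the distributions separate.
    """
    if not polylobar_features or not unilobar_features:
        raise ValueError("need labeled features for both classes")
    uni_e = max(f.e for f in unilobar_features)
    uni_p2 = min(f.P2 for f in unilobar_features)
    max_lobe_a = max(f.A for f in polylobar_features)
    min_uni_a = min(f.A for f in unilobar_features)
    x5 = int((max_lobe_a + min_uni_a) / 2)
    return ClassifierThresholds(
        x1=min(0.99, uni_e + margin),
        x2=max(1e-6, uni_p2 - margin),
        x5=max(1, x5),
    )
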