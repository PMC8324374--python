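"""Nucleus segmentation: Otsu threshold, binarization, labeling, area filter.

The segmentation chain turns a stained-smear micrograph into a label map of
candidate nucleus regions:

1. the blue-minus-green difference image separates nuclear material from
   background, erythrocytes and cytoplasm (see :mod:`polylobe.imaging`);
2. Otsu's method picks the gray threshold ``T1`` that maximizes the
   between-class variance of the difference histogram;
3. connected components of the binary image are labeled;
4. an area threshold ``S`` removes platelets, which are always much smaller
   than any nucleus lobe; ``S`` is calibrated as the minimum nucleus(-lobe)
   area seen in training data.

Components with area >= S survive the filter (a component exactly at the
calibrated minimum is retained).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .imaging import channel_difference, histogram

__all__ = [
    "Component",
    "LabelMap",
    "SegmentationConfig",
    "otsu_threshold",
    "binarize",
    "label_components",
    "area_filter",
    "calibrate_area_threshold",
    "segment_nuclei",
]


@dataclass(frozen=True)
class Component:
    """One labeled connected region.

    ``coords`` is an ``(area, 2)`` integer array of ``(row, col)`` pixel
    coordinates, sorted row-major.
    """

    label: int
    coords: np.ndarray
    area: int

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Render the component as a boolean mask of the given image shape."""
        m = np.zeros(shape, dtype=bool)
        m[self.coords[:, 0], self.coords[:, 1]] = True
        return m


@dataclass(frozen=True)
class LabelMap:
    """A labeled segmentation: background is 0, components are 1..n."""

    labels: np.ndarray
    components: list[Component] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.components)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


@dataclass
class SegmentationConfig:
    """Tunable segmentation parameters.

    area_threshold
        Minimum component area ``S`` in pixels; platelets fall below it.
    connectivity
        4 or 8. Default 8 so lobes joined by thin diagonal filaments do not
        fracture into separate components.
    otsu_override
        Optional fixed threshold ``T1``; when None, Otsu's method is applied
        to the difference-image histogram.
    """

    area_threshold: int = 150
    connectivity: int = 8
    otsu_override: int | None = None

    def __post_init__(self) -> None:
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.area_threshold < 0:
            raise ValueError("area_threshold must be >= 0")


def otsu_threshold(hist: np.ndarray) -> int:
    """Otsu's optimal threshold from a 256-bin histogram.

    Returns the gray level ``t`` maximizing the between-class variance
    ``sigma_B^2(t) = w0 * w1 * (mu0 - mu1)^2`` where class 0 holds levels
    ``<= t`` and class 1 holds levels ``> t``.  The variance is taken as 0
    when either class is empty; ties are broken toward the smallest ``t``,
    so a single-level histogram yields 0.
    """
    hist = np.asarray(hist, dtype=np.float64)
    if hist.shape != (256,):
        raise ValueError("histogram must have 256 bins")
    total = hist.sum()
    if total <= 0:
        raise ValueError("empty histogram")

    p = hist / total
    levels = np.arange(256)
    w0 = np.cumsum(p)                     # weight of class {0..t}
    m = np.cumsum(p * levels)             # first moment of class {0..t}
    mt = m[-1]
    w1 = 1.0 - w0
    # sigma_B^2 = (mt*w0 - m)^2 / (w0*w1); 0 where a class is empty
    num = (mt * w0 - m) ** 2
    den = w0 * w1
    sigma = np.zeros(256)
    valid = den > 0
    sigma[valid] = num[valid] / den[valid]
    return int(np.argmax(sigma))


def binarize(gray: np.ndarray, t1: int) -> np.ndarray:
    """Foreground mask: pixels strictly above ``t1`` (nuclei + platelets)."""
    if not 0 <= t1 <= 255:
        raise ValueError("threshold must be in [0, 255]")
    return np.asarray(gray) > t1


_STRUCTS = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


def label_components(mask: np.ndarray, connectivity: int = 8) -> LabelMap:
    """Connected-component labeling of a binary mask.

    Labels are assigned 1..n in row-major first-encounter order, which is
    what :func:`scipy.ndimage.label` produces; the result is deterministic.
    """
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndi.label(mask, structure=_STRUCTS[connectivity])
    return _from_labels(labels.astype(np.int32), n)


def _from_labels(labels: np.ndarray, n: int) -> LabelMap:
    comps = []
    # value_indices gives per-label coordinate arrays in one pass
    idx = ndi.value_indices(labels, ignore_value=0)
    for lab in range(1, n + 1):
        rows, cols = idx[lab]
        coords = np.column_stack([rows, cols]).astype(np.int64)
        comps.append(Component(label=lab, coords=coords, area=len(rows)))
    return LabelMap(labels=labels, components=comps)


def area_filter(lmap: LabelMap, s: int) -> LabelMap:
    """Keep components with area >= ``s``; relabel survivors 1..n'.

    This is the platelet filter: every platelet is far smaller than any
    nucleus lobe, so an area cut at the minimum training nucleus area
    removes platelets exactly.  The filter is idempotent and n'(s) is
    non-increasing in s.
    """
    if s < 0:
        raise ValueError("area threshold must be >= 0")
    out = np.zeros_like(lmap.labels)
    comps = []
    new_lab = 0
    for c in lmap.components:
        if c.area >= s:
            new_lab += 1
            out[c.coords[:, 0], c.coords[:, 1]] = new_lab
            comps.append(Component(label=new_lab, coords=c.coords, area=c.area))
    return LabelMap(labels=out, components=comps)


def calibrate_area_threshold(
    training_areas: list[int] | np.ndarray, safety_factor: float = 1.0
) -> int:
    """Area threshold ``S`` from ground-truth nucleus(-lobe) areas.

    Returns the minimum training area, optionally scaled by a safety factor
    (< 1 leaves headroom below the smallest observed nucleus).
    """
    areas = np.asarray(training_areas)
    if areas.size == 0:
        raise ValueError("need at least one training area")
    if np.any(areas <= 0):
        raise ValueError("areas must be positive")
    return int(np.floor(areas.min() * safety_factor))


def segment_nuclei(img: np.ndarray, cfg: SegmentationConfig | None = None) -> LabelMap:
    """Full segmentation chain: difference image -> Otsu -> label -> area filter.

    A pure function of (image, config): the same inputs always produce the
    identical label map.
    """
    cfg = cfg or SegmentationConfig()
    diff = channel_difference(img)
    t1 = cfg.otsu_override if cfg.otsu_override is not None else otsu_threshold(
        histogram(diff)
    )
    mask = binarize(diff, t1)
    lmap = label_components(mask, cfg.connectivity)
    return area_filter(lmap, cfg.area_threshold)
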