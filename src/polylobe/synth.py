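"""Synthetic Wright-stain-like blood-smear micrographs with ground truth.

Real annotated smear corpora are rarely redistributable, so the test
substrate here is generated: a light background, pink erythrocytes, small
dark platelets and blue-purple nuclei.  Leukocyte nuclei are either
unilobar (one filled ellipse — lymphocytes, monocytes, basophils) or
polylobar (2–5 disk lobes along a gently jittered chain — neutrophils and
eosinophils) with the three connection modes seen in micrographs: lobes
joined by thin chromatin *filaments*, lobes *overlapping*, or lobes
*completely disconnected* (the case the merge step exists for).

Colors are chosen so the blue-minus-green difference separates classes by
construction: nucleus B−G = 100 and platelet B−G = 80 sit far above the
background (5) and erythrocyte (10) levels, guaranteeing a clean Otsu
split.  Erythrocytes are rendered but deliberately invisible to the
difference image (B ≈ G), as they are in real stains.

Default geometry (all overridable per spec):

==================  =======================  ==========================
element             size                     resulting pixel area
==================  =======================  ==========================
polylobar lobe      disk r ∈ [7.5, 8.5] px   ≈ 170–230  (≥ S, < X5)
unilobar nucleus    ellipse a ∈ [10, 13],    ≈ 270–530  (≥ X5)
                    b/a ∈ [0.85, 1]
platelet            disk r ∈ [2, 3.5] px     ≈ 13–40    (< S)
erythrocyte         disk r ∈ [9, 13] px      (not in any ground truth)
lobe gap            4–6 px edge-to-edge      (≤ adaptive merge cap ≈ 9)
==================  =======================  ==========================
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import line as draw_line

__all__ = [
    "CellSpec",
    "SynthSpec",
    "GroundTruth",
    "make_cell_image",
    "case_preset",
    "make_dataset",
    "TABLE_MIX",
]

# class mix of the reference 300-image evaluation corpus
TABLE_MIX = {
    "neutrophil": 113 / 300,
    "eosinophil": 36 / 300,
    "basophil": 18 / 300,
    "monocyte": 69 / 300,
    "lymphocyte": 64 / 300,
}

DEFAULT_COLORS = {
    "background": (235, 225, 230),
    "erythrocyte": (230, 180, 190),
    "nucleus": (95, 60, 160),
    "platelet": (120, 85, 165),
}

CONNECTION_MODES = ("filament", "overlap", "disconnected")


@dataclass
class CellSpec:
    """One leukocyte in the scene.

    ``kind`` is "unilobar" (lobe_count must be 1) or "polylobar"
    (lobe_count 2–5).  For polylobar cells ``lobe_radii`` gives one disk
    radius per lobe, ``lobe_gap`` the edge-to-edge spacing of consecutive
    lobes in disconnected mode, and ``orientation`` the chain direction in
    radians.  For unilobar cells ``lobe_radii[0]`` is the ellipse
    semi-major axis and ``axis_ratio`` the b/a ratio.
    """

    cell_type: str
    kind: str
    center: tuple[float, float]
    lobe_count: int = 1
    lobe_radii: tuple[float, ...] = (11.0,)
    lobe_gap: float = 5.0
    connection_mode: str = "disconnected"
    orientation: float = 0.0
    axis_ratio: float = 0.9

    def __post_init__(self) -> None:
        if self.kind not in ("unilobar", "polylobar"):
            raise ValueError(f"unknown cell kind {self.kind!r}")
        if (self.kind == "unilobar") != (self.lobe_count == 1):
            raise ValueError("lobe_count must be 1 iff the cell is unilobar")
        if not 1 <= self.lobe_count <= 5:
            raise ValueError("lobe_count must be in [1, 5]")
        if self.connection_mode not in CONNECTION_MODES:
            raise ValueError(f"unknown connection mode {self.connection_mode!r}")
        if len(self.lobe_radii) != self.lobe_count:
            raise ValueError("need one radius per lobe")


@dataclass
class SynthSpec:
    """Full scene description; rendering is deterministic given ``seed``."""

    height: int = 192
    width: int = 192
    cells: list[CellSpec] = field(default_factory=list)
    n_platelets: int = 4
    platelet_radius_range: tuple[float, float] = (2.0, 3.5)
    n_erythrocytes: int = 6
    erythrocyte_radius_range: tuple[float, float] = (9.0, 13.0)
    colors: dict[str, tuple[int, int, int]] = field(
        default_factory=lambda: dict(DEFAULT_COLORS)
    )
    seed: int = 0


@dataclass
class GroundTruth:
    """Per-image oracle: one nucleus mask per cell (all lobes of a cell in
    one mask), the cell types, and the platelet mask."""

    nucleus_masks: list[np.ndarray]
    cell_types: list[str]
    platelet_mask: np.ndarray

    @property
    def cell_count(self) -> int:
        return len(self.nucleus_masks)


def _render_cell(cell: CellSpec, shape: tuple[int, int], rng) -> np.ndarray:
    """Boolean nucleus mask for one cell."""
    mask = np.zeros(shape, dtype=bool)
    if cell.kind == "unilobar":
        a = cell.lobe_radii[0]
        draw = draw_ellipse(
            cell.center[0],
            cell.center[1],
            a * cell.axis_ratio,
            a,
            shape=shape,
            rotation=cell.orientation,
        )
        mask[draw] = True
        return mask

    # polylobar: lobe centers along a chain with small angular jitter
    radii = cell.lobe_radii
    centers = [np.array([0.0, 0.0])]
    theta = cell.orientation
    for i in range(1, cell.lobe_count):
        theta += rng.uniform(-0.14, 0.14)  # ~±8 degrees per step
        if cell.connection_mode == "overlap":
            step = 0.75 * (radii[i - 1] + radii[i])
        else:
            step = radii[i - 1] + radii[i] + cell.lobe_gap
        centers.append(centers[-1] + step * np.array([np.sin(theta), np.cos(theta)]))
    centers = np.array(centers)
    centers += np.asarray(cell.center) - centers.mean(axis=0)

    for (r0, c0), r in zip(centers, radii):
        rr, cc = draw_disk((r0, c0), r, shape=shape)
        mask[rr, cc] = True
    if cell.connection_mode == "filament":
        for i in range(1, cell.lobe_count):
            p = np.round(centers[i - 1]).astype(int)
            q = np.round(centers[i]).astype(int)
            rr, cc = draw_line(p[0], p[1], q[0], q[1])
            ok = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
            mask[rr[ok], cc[ok]] = True
            mask[np.clip(rr[ok] + 1, 0, shape[0] - 1), cc[ok]] = True  # 2 px wide
    return mask


def make_cell_image(spec: SynthSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render the scene; deterministic for a fixed spec (including seed).

    Raises
    ------
    ValueError
        If two cells' nucleus masks overlap or touch — the scene must be
        unambiguous for ground truth to be meaningful.
    """
    rng = np.random.default_rng(spec.seed)
    shape = (spec.height, spec.width)
    img = np.empty((*shape, 3), dtype=np.uint8)
    img[:] = spec.colors["background"]

    # erythrocytes first: under everything, invisible to B-G
    for _ in range(spec.n_erythrocytes):
        r = rng.uniform(*spec.erythrocyte_radius_range)
        c = (rng.uniform(0, spec.height), rng.uniform(0, spec.width))
        rr, cc = draw_disk(c, r, shape=shape)
        img[rr, cc] = spec.colors["erythrocyte"]

    nucleus_masks = [_render_cell(cell, shape, rng) for cell in spec.cells]
    occupied = np.zeros(shape, dtype=bool)
    for i, m in enumerate(nucleus_masks):
        grown = ndi.binary_dilation(m, np.ones((3, 3), dtype=bool))
        if (grown & occupied).any():
            raise ValueError(f"cell {i} overlaps or touches another cell")
        occupied |= grown

    # platelets: rejection-sampled clear of nuclei and of each other
    platelet_mask = np.zeros(shape, dtype=bool)
    keepout = ndi.binary_dilation(occupied, np.ones((5, 5), dtype=bool))
    placed = 0
    for _ in range(200 * max(spec.n_platelets, 1)):
        if placed == spec.n_platelets:
            break
        r = rng.uniform(*spec.platelet_radius_range)
        c = (rng.uniform(5, spec.height - 5), rng.uniform(5, spec.width - 5))
        rr, cc = draw_disk(c, r, shape=shape)
        if keepout[rr, cc].any():
            continue
        platelet_mask[rr, cc] = True
        keepout[rr, cc] = True
        keepout |= ndi.binary_dilation(platelet_mask, np.ones((5, 5), dtype=bool))
        placed += 1

    img[platelet_mask] = spec.colors["platelet"]
    for m in nucleus_masks:
        img[m] = spec.colors["nucleus"]

    truth = GroundTruth(
        nucleus_masks=nucleus_masks,
        cell_types=[c.cell_type for c in spec.cells],
        platelet_mask=platelet_mask,
    )
    return img, truth


def _polylobar_cell(rng, cell_type: str, center, n_lobes: int | None = None) -> CellSpec:
    k = n_lobes if n_lobes is not None else int(rng.integers(2, 6))
    return CellSpec(
        cell_type=cell_type,
        kind="polylobar",
        center=center,
        lobe_count=k,
        lobe_radii=tuple(rng.uniform(7.5, 8.5, size=k)),
        lobe_gap=float(rng.uniform(4.0, 6.0)),
        connection_mode=str(rng.choice(CONNECTION_MODES)),
        orientation=float(rng.uniform(0, np.pi)),
    )


def _unilobar_cell(rng, cell_type: str, center) -> CellSpec:
    lo, hi = {
        "basophil": (10.0, 11.5),
        "monocyte": (11.5, 13.0),
        "lymphocyte": (10.0, 12.5),
    }.get(cell_type, (10.0, 13.0))
    return CellSpec(
        cell_type=cell_type,
        kind="unilobar",
        center=center,
        lobe_radii=(float(rng.uniform(lo, hi)),),
        axis_ratio=float(rng.uniform(0.85, 1.0)),
        orientation=float(rng.uniform(0, np.pi)),
    )


def case_preset(k: int, seed: int = 0) -> SynthSpec:
    """Specs for the four misjudgment-prone scenarios.

    1. a single polylobar nucleus, lobes completely disconnected — the
       minimal-distance connection must fire repeatedly (truth count 1);
    2. two unilobar cells close together — nothing may merge (truth 2);
    3. one unilobar and one polylobar cell at similar distances — only the
       lobes merge (truth 2);
    4. two polylobar cells — each merges internally, never across
       (truth 2).
    """
    if k not in (1, 2, 3, 4):
        raise ValueError("case must be 1..4")
    rng = np.random.default_rng([seed, 900 + k])
    h = w = 192
    spec = SynthSpec(height=h, width=w, seed=int(rng.integers(0, 2**31)))
    jit = lambda: float(rng.uniform(-4, 4))
    if k == 1:
        cell = _polylobar_cell(rng, "neutrophil", (h / 2 + jit(), w / 2 + jit()),
                               n_lobes=int(rng.integers(3, 5)))
        cell.connection_mode = "disconnected"
        cell.orientation = float(rng.uniform(0, np.pi))
        spec.cells = [cell]
    elif k == 2:
        dy = float(rng.uniform(34, 40))  # edge gap ~10-16 px between ellipses
        c0 = (h / 2 - dy / 2 + jit(), w / 2 + jit())
        c1 = (h / 2 + dy / 2 + jit(), w / 2 + jit())
        spec.cells = [
            _unilobar_cell(rng, "monocyte", c0),
            _unilobar_cell(rng, "lymphocyte", c1),
        ]
    elif k == 3:
        # horizontal 2-lobe chain on top, unilobar below
        cell_a = _polylobar_cell(rng, "neutrophil", (h / 2 - 24 + jit(), w / 2 + jit()),
                                 n_lobes=2)
        cell_a.connection_mode = "disconnected"
        cell_a.orientation = float(rng.uniform(-0.2, 0.2))
        cell_b = _unilobar_cell(rng, "lymphocyte", (h / 2 + 18 + jit(), w / 2 + jit()))
        spec.cells = [cell_a, cell_b]
    else:
        dy = float(rng.uniform(42, 48))  # inter-chain gap well above merge cap
        cells = []
        for row in (h / 2 - dy / 2, h / 2 + dy / 2):
            cell = _polylobar_cell(rng, "neutrophil", (row + jit() / 2, w / 2 + jit()),
                                   n_lobes=2)
            cell.connection_mode = "disconnected"
            cell.orientation = float(rng.uniform(-0.2, 0.2))
            cells.append(cell)
        spec.cells = cells
    return spec


def _class_sequence(n: int, mix: dict[str, float]) -> list[str]:
    """Deterministic class labels by greedy quota-deficit assignment.

    Image i goes to the class with the largest deficit p_c*(i+1) - n_c, so
    class counts track the target proportions at every prefix — a dataset
    of size n and one of size n+1 share their first n images — and at any
    n where the quotas are integral the counts are exact.
    """
    classes = list(mix)
    assigned = {c: 0 for c in classes}
    labels = []
    for i in range(n):
        c = max(classes, key=lambda c: (mix[c] * (i + 1) - assigned[c], c))
        assigned[c] += 1
        labels.append(c)
    return labels


def _class_counts(n: int, mix: dict[str, float]) -> dict[str, int]:
    seq = _class_sequence(n, mix)
    return {c: seq.count(c) for c in mix}


def make_dataset(
    n: int,
    class_mix: dict[str, float] | None = None,
    seed: int = 0,
) -> list[tuple[np.ndarray, GroundTruth]]:
    """Generate *n* single-leukocyte scenes at the given class mix.

    Per-image RNG substreams are derived from ``(seed, image index)``, so
    datasets of different sizes share their common prefix.  Class labels
    are apportioned deterministically (largest remainder) and interleaved
    by a seeded shuffle.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mix = class_mix or TABLE_MIX
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError("class proportions must sum to 1")
    labels = _class_sequence(n, mix)

    out = []
    for i, cls in enumerate(labels):
        rng = np.random.default_rng([seed, i])
        h = w = 192
        center = (h / 2 + rng.uniform(-10, 10), w / 2 + rng.uniform(-10, 10))
        if cls in ("neutrophil", "eosinophil"):
            n_lobes = 2 if cls == "eosinophil" else None
            cell = _polylobar_cell(rng, cls, center, n_lobes=n_lobes)
        else:
            cell = _unilobar_cell(rng, cls, center)
        spec = SynthSpec(
            height=h,
            width=w,
            cells=[cell],
            n_platelets=int(rng.integers(3, 7)),
            n_erythrocytes=int(rng.integers(5, 9)),
            seed=int(rng.integers(0, 2**31)),
        )
        out.append(make_cell_image(spec))
    return out
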