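"""Five morphological shape descriptors for a nucleus region.

For a connected component these are:

* ``A``  — area, the pixel count of the region;
* ``P1`` — rectangle plumpness ``A / (a1 * b1)``, with ``a1``/``b1`` the
  horizontal/vertical extents of the axis-aligned bounding box;
* ``s``  — aspect ratio ``b1 / a1`` (posture: s ~ 1 round or diagonal,
  s << 1 lying down, s >> 1 upright);
* ``P2`` — ellipse plumpness ``A / (pi * a2 * b2)``, with ``a2 >= b2`` the
  semi-axes of the moment-equivalent ellipse;
* ``e``  — eccentricity ``sqrt(a2^2 - b2^2) / a2`` in [0, 1): 0 for a
  circle, toward 1 for a flat ellipse.

The "circumscribed ellipse" is the moment-equivalent ellipse (same second
central moments as the region), not a minimum enclosing ellipse: it is
unique, cheap, and for an ideal elliptical region it recovers the region's
own axes, making ``P2 ~ 1`` for full convex shapes.  Under this convention
``P2`` can slightly exceed 1 for very compact shapes, so the invariant is
``P2 > 0``.  Semi-axes come from the eigenvalues ``l1 >= l2`` of the second
central moment matrix as ``a2 = 2*sqrt(l1)``, ``b2 = 2*sqrt(l2)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .segmentation import Component

__all__ = [
    "Rect",
    "Ellipse",
    "ShapeFeatures",
    "component_area",
    "bounding_rectangle",
    "rect_plumpness",
    "aspect_ratio",
    "fit_ellipse",
    "ellipse_plumpness",
    "eccentricity",
    "feature_vector",
]

# degenerate (collinear / single-pixel) regions get this minor semi-axis
_B2_FLOOR = 0.5


@dataclass(frozen=True)
class Rect:
    """Tight axis-aligned bounding box: a1 = horizontal extent (columns),
    b1 = vertical extent (rows), origin = top-left (row, col)."""

    a1: int
    b1: int
    origin: tuple[int, int]


@dataclass(frozen=True)
class Ellipse:
    """Moment-equivalent ellipse; ``a2 >= b2`` are the semi-axes in pixels.

    ``orientation`` is the angle (radians, in (-pi/2, pi/2]) between the
    major axis and the horizontal image axis.  ``degenerate`` flags regions
    whose minor axis collapsed (single pixel or collinear pixels).
    """

    a2: float
    b2: float
    center: tuple[float, float]
    orientation: float
    degenerate: bool = False


@dataclass(frozen=True)
class ShapeFeatures:
    A: int
    P1: float
    s: float
    P2: float
    e: float
    degenerate: bool = False


def component_area(c: Component) -> int:
    """Area = number of pixels in the region."""
    if c.area < 1:
        raise ValueError("empty component")
    return c.area


def bounding_rectangle(c: Component) -> Rect:
    """Tight axis-aligned bounding box of the component."""
    if c.area < 1:
        raise ValueError("empty component")
    rows = c.coords[:, 0]
    cols = c.coords[:, 1]
    r0, c0 = int(rows.min()), int(cols.min())
    b1 = int(rows.max()) - r0 + 1
    a1 = int(cols.max()) - c0 + 1
    return Rect(a1=a1, b1=b1, origin=(r0, c0))


def rect_plumpness(c: Component) -> float:
    """P1 = A / (a1 * b1); equals 1 iff the component fills its box."""
    r = bounding_rectangle(c)
    return c.area / (r.a1 * r.b1)


def aspect_ratio(r: Rect) -> float:
    """s = b1 / a1."""
    return r.b1 / r.a1


def fit_ellipse(c: Component) -> Ellipse:
    """Moment-equivalent ellipse of the component.

    The center is the pixel centroid; orientation and semi-axes come from
    the eigen-decomposition of the second central moment matrix, with each
    pixel treated as a unit square (the +1/12 term) so a discretized ideal
    ellipse maps back onto its own axes.  Collinear or single-pixel regions
    are degenerate: b2 is floored at 0.5 px and flagged.
    """
    if c.area < 1:
        raise ValueError("empty component")
    pts = c.coords.astype(np.float64)
    center = pts.mean(axis=0)
    d = pts - center
    raw_cov = d.T @ d / len(pts)
    # degeneracy is judged on the raw moments: single pixels and collinear
    # sets have a zero minor eigenvalue before the pixel-square correction
    degenerate = float(np.linalg.eigvalsh(raw_cov)[0]) < 1e-9
    # second central moments with unit-square pixel correction
    cov = raw_cov + np.eye(2) / 12.0
    evals, evecs = np.linalg.eigh(cov)  # ascending
    l2, l1 = float(evals[0]), float(evals[1])
    a2 = 2.0 * math.sqrt(max(l1, 0.0))
    b2 = 2.0 * math.sqrt(max(l2, 0.0))
    # orientation of the major axis relative to the column (horizontal) axis
    vy, vx = evecs[0, 1], evecs[1, 1]
    theta = math.atan2(vy, vx)
    if theta <= -math.pi / 2:
        theta += math.pi
    elif theta > math.pi / 2:
        theta -= math.pi
    if degenerate:
        b2 = _B2_FLOOR
        a2 = max(a2, _B2_FLOOR)
    return Ellipse(
        a2=a2,
        b2=b2,
        center=(float(center[0]), float(center[1])),
        orientation=theta,
        degenerate=degenerate,
    )


def ellipse_plumpness(c: Component, el: Ellipse | None = None) -> float:
    """P2 = A / (pi * a2 * b2)."""
    el = el or fit_ellipse(c)
    if el.degenerate:
        raise ValueError("P2 undefined for a degenerate ellipse")
    return c.area / (math.pi * el.a2 * el.b2)


def eccentricity(el: Ellipse) -> float:
    """e = sqrt(a2^2 - b2^2) / a2, in [0, 1)."""
    if el.b2 > el.a2 or el.b2 <= 0:
        raise ValueError("ellipse must satisfy a2 >= b2 > 0")
    return math.sqrt(el.a2**2 - el.b2**2) / el.a2


def feature_vector(c: Component) -> ShapeFeatures:
    """Bundle all five descriptors for one component.

    Degenerate regions (where the fitted ellipse collapses) carry a flag;
    their P2 uses the floored minor axis rather than raising, so the
    downstream classifier can handle them conservatively.
    """
    a = component_area(c)
    rect = bounding_rectangle(c)
    el = fit_ellipse(c)
    p2 = a / (math.pi * el.a2 * el.b2)
    return ShapeFeatures(
        A=a,
        P1=a / (rect.a1 * rect.b1),
        s=aspect_ratio(rect),
        P2=p2,
        e=eccentricity(el),
        degenerate=el.degenerate,
    )
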