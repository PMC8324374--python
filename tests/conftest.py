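import numpy as np
import pytest

from polylobe.segmentation import Component, label_components


def component_from_mask(mask: np.ndarray) -> Component:
    """Single labeled component from a boolean mask (must be connected)."""
    lmap = label_components(np.asarray(mask, dtype=bool), 8)
    assert lmap.n == 1, "helper expects a single connected region"
    return lmap.components[0]


def disk_mask(radius: int, pad: int = 4) -> np.ndarray:
    size = 2 * (radius + pad) + 1
    c = radius + pad
    yy, xx = np.mgrid[:size, :size]
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius**2


def ellipse_mask(a: float, b: float, pad: int = 4) -> np.ndarray:
    """Axis-aligned filled ellipse, semi-axis a horizontal, b vertical."""
    size = 2 * (int(max(a, b)) + pad) + 1
    c = size // 2
    yy, xx = np.mgrid[:size, :size]
    return ((xx - c) / a) ** 2 + ((yy - c) / b) ** 2 <= 1.0


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
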