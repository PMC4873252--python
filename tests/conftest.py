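import math

import numpy as np
import pytest

import biovol as bv


@pytest.fixture
def sphere_m() -> bv.SilhouetteMeasurements:
    """Exact measurements of a unit-radius sphere silhouette."""
    return bv.SilhouetteMeasurements(area_A=math.pi, length_l=2.0, width_d=2.0)


@pytest.fixture
def stadium_m() -> bv.SilhouetteMeasurements:
    """Exact measurements of the 2:1 cylinder-with-hemispherical-ends silhouette."""
    return bv.SilhouetteMeasurements(area_A=4.0 + math.pi, length_l=4.0, width_d=2.0)


@pytest.fixture
def plus_sign_mask() -> np.ndarray:
    """Branched (plus-sign) silhouette: five a x a squares in a cross.

    Area 5a^2, convex hull 7a^2 (the hull cuts four corner triangles of a^2/2
    off the 3a x 3a box), so the concavity index is 1 - 5/7 ~ 0.286 > 0.2.
    """
    a = 40
    mask = np.zeros((3 * a, 3 * a), dtype=bool)
    mask[a : 2 * a, :] = True
    mask[:, a : 2 * a] = True
    return mask


def disk_mask(radius_px: float, pad: int = 2) -> np.ndarray:
    """Pixel-center rasterisation of a disk, used as a pixel-counting oracle."""
    n = int(2 * radius_px) + 2 * pad + 1
    c = (n - 1) / 2
    yy, xx = np.indices((n, n))
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius_px**2
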