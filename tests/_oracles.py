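"""Independent brute-force reference implementations used only by tests."""

from __future__ import annotations

import math

import numpy as np


def ray_cast_contains(polygons, x: float, y: float) -> bool:
    """Even-odd point-in-polygon-union test by explicit ray casting.

    A point is inside the union if it is inside any polygon; inside a
    polygon if a horizontal ray to +x crosses its edges an odd number of
    times.  Written independently of any geometry library.
    """
    for verts in polygons:
        verts = np.asarray(verts, dtype=float)
        n = len(verts)
        crossings = 0
        for i in range(n):
            x1, y1 = verts[i]
            x2, y2 = verts[(i + 1) % n]
            if (y1 > y) != (y2 > y):
                x_cross = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
                if x_cross > x:
                    crossings += 1
        if crossings % 2 == 1:
            return True
    return False


def brute_force_mask(polygons, height: int, width: int) -> np.ndarray:
    """Rasterize via the pixel-center rule using :func:`ray_cast_contains`."""
    mask = np.zeros((height, width), dtype=bool)
    for r in range(height):
        for c in range(width):
            mask[r, c] = ray_cast_contains(polygons, c + 0.5, r + 0.5)
    return mask


def brute_paired_t(a, b):
    """Paired t statistic and two-sided p from explicit sums (no shortcuts)."""
    from scipy.stats import t as tdist

    d = [float(x) - float(y) for x, y in zip(a, b)]
    n = len(d)
    mean = sum(d) / n
    var = sum((x - mean) ** 2 for x in d) / (n - 1)
    t = mean / math.sqrt(var / n)
    p = 2.0 * tdist.sf(abs(t), n - 1)
    return t, p


def brute_unpaired_t(a, b, equal_var=True):
    """Two-sample t statistic and two-sided p from explicit sums."""
    from scipy.stats import t as tdist

    a = [float(x) for x in a]
    b = [float(x) for x in b]
    n1, n2 = len(a), len(b)
    m1, m2 = sum(a) / n1, sum(b) / n2
    v1 = sum((x - m1) ** 2 for x in a) / (n1 - 1)
    v2 = sum((x - m2) ** 2 for x in b) / (n2 - 1)
    if equal_var:
        df = n1 + n2 - 2
        sp = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        se = math.sqrt(sp * (1 / n1 + 1 / n2))
    else:
        se = math.sqrt(v1 / n1 + v2 / n2)
        df = (v1 / n1 + v2 / n2) ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    t = (m1 - m2) / se
    p = 2.0 * tdist.sf(abs(t), df)
    return t, p
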