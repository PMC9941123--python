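"""Exact convex-hull pixel counting for solidity.

Solidity is defined here with an explicit geometric convention so that it is
exactly reproducible: the convex image of an object is the set of pixel
centres lying inside (boundary inclusive) the convex hull of the object's own
pixel centres.  Under this convention a digital disc has solidity exactly 1
(the hull of the disc's lattice points contains no other lattice point),
while any concavity — a notch, a crescent, a donut rendered as a ring —
strictly lowers it.  All vertices are integer lattice points, so boundary
decisions are numerically unambiguous at any tolerance well below
1/(image diagonal).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull, QhullError

_TOL = 1e-9


def convex_hull_pixel_count(coords: np.ndarray) -> int:
    """Number of pixel centres inside the hull of the object's pixel centres.

    Parameters
    ----------
    coords:
        ``(n, 2)`` integer array of (row, col) pixel coordinates.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must be (n, 2)")
    n = coords.shape[0]
    if n == 0:
        return 0
    try:
        hull = ConvexHull(coords)
    except QhullError:
        # degenerate hull (single pixel or collinear run): the convex image
        # is the component itself for any 8-connected pixel line
        return n
    rmin, cmin = coords.min(axis=0).astype(int)
    rmax, cmax = coords.max(axis=0).astype(int)
    rr, cc = np.meshgrid(
        np.arange(rmin, rmax + 1), np.arange(cmin, cmax + 1), indexing="ij"
    )
    pts = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    # hull.equations: normal . x + offset <= 0 for interior points
    inside = np.all(pts @ hull.equations[:, :2].T + hull.equations[:, 2] <= _TOL, axis=1)
    return int(inside.sum())


def solidity(coords: np.ndarray) -> float:
    """Area / convex-image area for a pixel set."""
    hull_px = convex_hull_pixel_count(coords)
    if hull_px == 0:
        return 0.0
    return float(len(coords) / hull_px)
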