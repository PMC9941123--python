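"""Independent brute-force reference implementations used as test oracles.

Everything here is written from the definitions (explicit loops, exhaustive
scans, union-find), deliberately avoiding the code paths and libraries the
package uses for the same quantities: histograms + explicit between-class
variance maximisation for thresholding, BFS flood fill for components,
structuring-element loops for morphology, raw moment sums for features,
monotone-chain hulls with exact integer point-in-polygon tests for solidity,
and pairwise union-find for the across-slice deduplication.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------- threshold
def otsu_threshold(values: np.ndarray) -> float:
    """Otsu's method: maximise between-class variance over 256-bin splits."""
    values = np.asarray(values, dtype=float).ravel()
    hist, edges = np.histogram(values, bins=256)
    centers = (edges[:-1] + edges[1:]) / 2.0
    best_score, best_t = -1.0, centers[0]
    for i in range(255):
        w0 = hist[: i + 1].sum()
        w1 = hist[i + 1 :].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = float(np.dot(hist[: i + 1], centers[: i + 1])) / w0
        mu1 = float(np.dot(hist[i + 1 :], centers[i + 1 :])) / w1
        score = w0 * w1 * (mu0 - mu1) ** 2
        if score > best_score:
            best_score, best_t = score, centers[i]
    return float(best_t)


def binarize_stack(stack: np.ndarray, method) -> np.ndarray:
    masks = np.zeros(stack.shape, dtype=bool)
    for s in range(stack.shape[0]):
        sl = stack[s]
        if sl.max() == sl.min():
            if not isinstance(method, str):
                masks[s] = sl > float(method)
            continue
        t = float(method) if not isinstance(method, str) else otsu_threshold(sl)
        masks[s] = sl > t
    return masks


# --------------------------------------------------------------- morphology
def _disk_offsets(radius: int) -> list[tuple[int, int]]:
    return [
        (dr, dc)
        for dr in range(-radius, radius + 1)
        for dc in range(-radius, radius + 1)
        if dr * dr + dc * dc <= radius * radius
    ]


def erode(mask: np.ndarray, radius: int) -> np.ndarray:
    offs = _disk_offsets(radius)
    out = np.zeros_like(mask)
    R, C = mask.shape
    for r in range(R):
        for c in range(C):
            if not mask[r, c]:
                continue
            ok = True
            for dr, dc in offs:
                rr, cc = r + dr, c + dc
                if not (0 <= rr < R and 0 <= cc < C) or not mask[rr, cc]:
                    ok = False
                    break
            out[r, c] = ok
    return out


def dilate(mask: np.ndarray, radius: int) -> np.ndarray:
    offs = _disk_offsets(radius)
    out = np.zeros_like(mask)
    R, C = mask.shape
    for r in range(R):
        for c in range(C):
            if mask[r, c]:
                for dr, dc in offs:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < R and 0 <= cc < C:
                        out[rr, cc] = True
    return out


def open_mask(mask: np.ndarray, radius: int) -> np.ndarray:
    if radius == 0:
        return mask.copy()
    return dilate(erode(mask, radius), radius)


# --------------------------------------------------------------- components
def connected_components(mask: np.ndarray) -> list[list[tuple[int, int]]]:
    """8-connected components via BFS flood fill."""
    R, C = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for r in range(R):
        for c in range(C):
            if not mask[r, c] or seen[r, c]:
                continue
            queue = [(r, c)]
            seen[r, c] = True
            comp = []
            while queue:
                cr, cc = queue.pop()
                comp.append((cr, cc))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        nr, nc = cr + dr, cc + dc
                        if 0 <= nr < R and 0 <= nc < C and mask[nr, nc] and not seen[nr, nc]:
                            seen[nr, nc] = True
                            queue.append((nr, nc))
            comps.append(comp)
    return comps


def label_components_3d(mask: np.ndarray) -> int:
    """Count 26-connected components in a 3-D boolean stack (brute force)."""
    S, R, C = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    count = 0
    for s in range(S):
        for r in range(R):
            for c in range(C):
                if not mask[s, r, c] or seen[s, r, c]:
                    continue
                count += 1
                queue = [(s, r, c)]
                seen[s, r, c] = True
                while queue:
                    cs, cr, cc = queue.pop()
                    for ds in (-1, 0, 1):
                        for dr in (-1, 0, 1):
                            for dc in (-1, 0, 1):
                                ns, nr, nc = cs + ds, cr + dr, cc + dc
                                if (
                                    0 <= ns < S and 0 <= nr < R and 0 <= nc < C
                                    and mask[ns, nr, nc] and not seen[ns, nr, nc]
                                ):
                                    seen[ns, nr, nc] = True
                                    queue.append((ns, nr, nc))
    return count


# ------------------------------------------------------------------ features
def _hull_monotone_chain(points: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Andrew's monotone chain on integer points; returns CCW hull vertices."""
    pts = sorted(set(points))
    if len(pts) <= 2:
        return pts

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    lower = []
    for p in pts:
        while len(lower) >= 2 and cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    upper = []
    for p in reversed(pts):
        while len(upper) >= 2 and cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    return lower[:-1] + upper[:-1]


def convex_pixel_count(comp: list[tuple[int, int]]) -> int:
    """Pixel centres inside the hull of the component's own pixel centres
    (boundary inclusive); all orientation tests are exact integer arithmetic.
    """
    hull = _hull_monotone_chain(list(comp))
    if len(hull) <= 2:
        return len(set(comp))
    rmin = min(r for r, _ in comp)
    rmax = max(r for r, _ in comp)
    cmin = min(c for _, c in comp)
    cmax = max(c for _, c in comp)
    count = 0
    m = len(hull)
    for r in range(rmin, rmax + 1):
        for c in range(cmin, cmax + 1):
            inside = True
            for i in range(m):
                a, b = hull[i], hull[(i + 1) % m]
                if (b[0] - a[0]) * (c - a[1]) - (b[1] - a[1]) * (r - a[0]) < 0:
                    inside = False
                    break
            if inside:
                count += 1
    return count


def component_features(comp: list[tuple[int, int]], intensity: np.ndarray) -> dict:
    """Shape features from raw moment sums (regionprops definitions)."""
    n = len(comp)
    sr = sum(r for r, _ in comp)
    sc = sum(c for _, c in comp)
    r0, c0 = sr / n, sc / n
    mu20 = sum((r - r0) ** 2 for r, _ in comp) / n
    mu02 = sum((c - c0) ** 2 for _, c in comp) / n
    mu11 = sum((r - r0) * (c - c0) for r, c in comp) / n
    tr = mu20 + mu02
    det_term = math.sqrt(max(0.0, (mu20 - mu02) ** 2 + 4.0 * mu11**2))
    l1 = (tr + det_term) / 2.0
    l2 = (tr - det_term) / 2.0
    ecc = 0.0 if l1 <= 0 else math.sqrt(1.0 - max(0.0, l2) / l1)
    rmin = min(r for r, _ in comp)
    rmax = max(r for r, _ in comp)
    cmin = min(c for _, c in comp)
    cmax = max(c for _, c in comp)
    bbox_area = (rmax - rmin + 1) * (cmax - cmin + 1)
    total = 0.0
    for r, c in comp:
        total += float(intensity[r, c])
    return {
        "area": n,
        "centroid": (r0, c0),
        "extent": n / bbox_area,
        "eccentricity": ecc,
        "equivalent_diameter": math.sqrt(4.0 * n / math.pi),
        "solidity": n / convex_pixel_count(comp),
        "total_intensity": total,
    }


# ---------------------------------------------------------------- dedup
def dedup_union_find(objects: list[dict], tol: float) -> list[dict]:
    """Reference deduplication: pairwise Chebyshev box + union-find,
    largest area wins, ties to the lowest slice then smallest centroid."""
    n = len(objects)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i in range(n):
        for j in range(n):
            if i == j or objects[i]["slice"] == objects[j]["slice"]:
                continue
            (ri, ci), (rj, cj) = objects[i]["centroid"], objects[j]["centroid"]
            if abs(ri - rj) <= tol and abs(ci - cj) <= tol:
                pi, pj = find(i), find(j)
                if pi != pj:
                    parent[pi] = pj
    groups: dict[int, list[dict]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(objects[i])
    keep = []
    for members in groups.values():
        members.sort(key=lambda o: (-o["area"], o["slice"], o["centroid"]))
        keep.append(members[0])
    keep.sort(key=lambda o: (o["slice"], o["centroid"]))
    return keep


# --------------------------------------------------------- whole pipeline
def segment_region_bruteforce(
    green: np.ndarray,
    red: np.ndarray,
    *,
    threshold_method="otsu",
    extent_min=0.50,
    eccentricity_max=0.85,
    solidity_min=0.75,
    opening_radius_px=1,
    min_area_px=25,
    max_area_px=750,
    dedup_tolerance_px=4.0,
) -> list[dict]:
    """Reference implementation of the per-region segmentation pipeline."""
    diff = green.astype(float) - red.astype(float)
    diff[diff < 0] = 0.0
    masks = binarize_stack(diff, threshold_method)
    objects = []
    for s in range(masks.shape[0]):
        opened = open_mask(masks[s], opening_radius_px)
        for comp in connected_components(opened):
            feats = component_features(comp, diff[s])
            feats["slice"] = s
            feats["pixels"] = frozenset(comp)
            objects.append(feats)
    kept = [
        o
        for o in objects
        if o["extent"] >= extent_min
        and o["eccentricity"] < eccentricity_max
        and o["solidity"] > solidity_min
        and min_area_px <= o["area"] <= max_area_px
    ]
    return dedup_union_find(kept, dedup_tolerance_px)
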