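"""Nuclei segmentation with dual-channel autofluorescence subtraction.

The canonical pipeline per region stack, run slice by slice:

1. subtract the red (autofluorescence) channel from the green (reporter)
   channel, clipping negatives to zero;
2. binarise each slice of the difference with an automatic histogram
   threshold (Otsu by default; the threshold used is logged per slice);
3. smooth the mask by morphological opening with a disc;
4. label 8-connected components per slice and extract shape features;
5. keep objects that fill >= 50% of their bounding box (extent), have
   eccentricity under 0.85 and solidity above 0.75 — the filter inequalities
   are strict or inclusive exactly as written;
6. delete objects smaller than neurons or larger than intestinal nuclei
   (inclusive area bounds, defaults expressed in um^2);
7. deduplicate nuclei seen in several slices: centroids within +/- 4 px in
   BOTH coordinates (a Chebyshev box) on different slices are grouped by
   transitive closure and only the largest-area member is kept.

A compatibility mode (``binary_subtract=True``) binarises both channels first
and subtracts the masks instead; per-nucleus intensities are always summed on
the clipped difference stack so the autofluorescence correction carries
through to the intensity measure.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import scipy.ndimage as ndi
from skimage import measure
from skimage.filters import threshold_otsu, threshold_triangle
from skimage.morphology import disk

from ._hull import solidity as _solidity
from .stacks import StackPair, WormImageSet

log = logging.getLogger(__name__)

_STRUCT_8 = np.ones((3, 3), dtype=bool)


@dataclass
class SegmentationParams:
    """Thresholds of the segmentation pipeline.

    ``threshold_method`` is either a named automatic histogram method
    ("otsu" or "triangle") or a fixed numeric value.  Area bounds default to
    calibration values in um^2 (converted per stack via its pixel size); set
    ``min_area_px`` / ``max_area_px`` to override in pixels directly.
    """

    threshold_method: str | float = "otsu"
    extent_min: float = 0.50
    eccentricity_max: float = 0.85
    solidity_min: float = 0.75
    opening_radius_px: int = 1
    min_area_um2: float = 4.0
    max_area_um2: float = 120.0
    min_area_px: int | None = None
    max_area_px: int | None = None
    dedup_tolerance_px: float = 4.0
    clip_negative: bool = True
    binary_subtract: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.extent_min <= 1):
            raise ValueError("extent_min must be in [0, 1]")
        if not (0 <= self.eccentricity_max < 1):
            raise ValueError("eccentricity_max must be in [0, 1)")
        if not (0 < self.solidity_min <= 1):
            raise ValueError("solidity_min must be in (0, 1]")
        if self.opening_radius_px < 0 or self.dedup_tolerance_px < 0:
            raise ValueError("radii/tolerances must be >= 0")
        lo, hi = self.area_bounds_px(1.0) if self.min_area_px is not None else (0, 1)
        if self.min_area_px is not None and lo >= hi:
            raise ValueError("min_area_px must be < max_area_px")
        if self.min_area_um2 >= self.max_area_um2:
            raise ValueError("min_area_um2 must be < max_area_um2")

    def area_bounds_px(self, pixel_size_um: float) -> tuple[int, int]:
        lo = self.min_area_px
        hi = self.max_area_px
        if lo is None:
            lo = int(math.ceil(self.min_area_um2 / pixel_size_um**2))
        if hi is None:
            hi = int(math.floor(self.max_area_um2 / pixel_size_um**2))
        return lo, hi


@dataclass
class NucleusObject:
    """One segmented nucleus (a single-slice connected component)."""

    slice_index: int
    centroid: tuple[float, float]  # (row, col), pixel units
    area_px: int
    eccentricity: float
    solidity: float
    extent: float
    equivalent_diameter_px: float
    total_intensity: float
    region_index: int = 0
    coords: np.ndarray | None = field(default=None, repr=False)
    tissue: str | None = None
    nucleolus_state: str | None = None
    nucleolus_ratio: float | None = None

    def to_record(self) -> dict:
        d = asdict(self)
        d.pop("coords")
        d["centroid_row"], d["centroid_col"] = d.pop("centroid")
        return d


@dataclass
class WormMeasurement:
    """Per-animal aggregate over the four deduplicated region stacks."""

    animal_id: str
    day: int | None
    regime_id: str | None
    nuclei: list[NucleusObject]

    @property
    def nuclei_count(self) -> int:
        return len(self.nuclei)

    @property
    def total_nuclear_intensity(self) -> float:
        # plain sequential sum over its own nuclei — the aggregation contract
        return sum(n.total_intensity for n in self.nuclei)


def subtract_channels(pair: StackPair, clip_negative: bool = True) -> np.ndarray:
    """Green minus red, slice-wise; negatives clipped to 0 when requested."""
    diff = pair.green.astype(np.float64) - pair.red.astype(np.float64)
    if clip_negative:
        np.maximum(diff, 0.0, out=diff)
    return diff


def _threshold_value(slice_values: np.ndarray, method: str | float) -> float:
    if isinstance(method, (int, float)) and not isinstance(method, bool):
        return float(method)
    if method == "otsu":
        return float(threshold_otsu(slice_values))
    if method == "triangle":
        return float(threshold_triangle(slice_values))
    raise ValueError(f"unknown threshold method {method!r}")


def binarize(
    stack: np.ndarray, threshold_method: str | float = "otsu"
) -> tuple[np.ndarray, list[float | None]]:
    """Per-slice binary mask plus the threshold used on each slice.

    A contrast-free (constant) slice yields an all-false mask and a logged
    warning rather than an error.
    """
    stack = np.asarray(stack)
    masks = np.zeros(stack.shape, dtype=bool)
    thresholds: list[float | None] = []
    for s in range(stack.shape[0]):
        sl = stack[s]
        if np.ptp(sl) == 0:
            if not isinstance(threshold_method, str):
                t = float(threshold_method)
                masks[s] = sl > t
                thresholds.append(t)
            else:
                log.warning("slice %d has no contrast; empty mask", s)
                thresholds.append(None)
            continue
        t = _threshold_value(sl, threshold_method)
        masks[s] = sl > t
        thresholds.append(t)
        log.debug("slice %d threshold %.4g", s, t)
    return masks, thresholds


def morphological_open(mask: np.ndarray, opening_radius_px: int = 1) -> np.ndarray:
    """Slice-wise binary opening with a disc; radius 0 is the identity.

    Out-of-image pixels count as background for both the erosion and the
    dilation, so the opened mask is always a subset of the input.
    """
    mask = np.asarray(mask, dtype=bool)
    if opening_radius_px == 0:
        return mask.copy()
    footprint = disk(opening_radius_px).astype(bool)
    out = np.zeros_like(mask)
    slices = mask[None] if mask.ndim == 2 else mask
    dest = out[None] if mask.ndim == 2 else out
    for s in range(slices.shape[0]):
        eroded = ndi.binary_erosion(slices[s], structure=footprint, border_value=0)
        dest[s] = ndi.binary_dilation(eroded, structure=footprint, border_value=0)
    return out


def label_slice(mask_slice: np.ndarray) -> tuple[np.ndarray, int]:
    """8-connected in-plane component labelling."""
    return ndi.label(mask_slice, structure=_STRUCT_8)


def compute_object_features(
    labeled_slice: np.ndarray,
    intensity_slice: np.ndarray,
    slice_index: int = 0,
    region_index: int = 0,
) -> list[NucleusObject]:
    """Extract one :class:`NucleusObject` per connected component.

    Area, centroid, extent, eccentricity and equivalent diameter follow the
    standard regionprops definitions; solidity uses the package's exact
    convex-image convention (see :mod:`wormquant._hull`); total intensity is
    the sum of the intensity image over the component's pixels.
    """
    objects: list[NucleusObject] = []
    for region in measure.regionprops(labeled_slice, intensity_image=intensity_slice):
        coords = region.coords
        total = float(intensity_slice[coords[:, 0], coords[:, 1]].sum())
        objects.append(
            NucleusObject(
                slice_index=slice_index,
                centroid=(float(region.centroid[0]), float(region.centroid[1])),
                area_px=int(region.area),
                eccentricity=float(region.eccentricity),
                solidity=_solidity(coords),
                extent=float(region.extent),
                equivalent_diameter_px=float(region.equivalent_diameter_area),
                total_intensity=total,
                region_index=region_index,
                coords=coords,
            )
        )
    return objects


def shape_filter(objects: list[NucleusObject], params: SegmentationParams) -> list[NucleusObject]:
    """Retain objects with extent >= min, eccentricity < max, solidity > min."""
    kept = []
    for obj in objects:
        if obj.extent < params.extent_min:
            log.debug("reject slice %d %s: extent %.3f", obj.slice_index, obj.centroid, obj.extent)
        elif obj.eccentricity >= params.eccentricity_max:
            log.debug("reject %s: eccentricity %.3f", obj.centroid, obj.eccentricity)
        elif obj.solidity <= params.solidity_min:
            log.debug("reject %s: solidity %.3f", obj.centroid, obj.solidity)
        else:
            kept.append(obj)
    return kept


def size_filter(
    objects: list[NucleusObject], min_area_px: int, max_area_px: int
) -> list[NucleusObject]:
    """Retain objects with min_area_px <= area <= max_area_px (inclusive)."""
    return [o for o in objects if min_area_px <= o.area_px <= max_area_px]


def deduplicate_across_slices(
    objects: list[NucleusObject], dedup_tolerance_px: float = 4.0
) -> list[NucleusObject]:
    """Collapse per-slice detections of the same nucleus to one object.

    Objects on *different* slices whose centroids agree within the tolerance
    in both row and col (Chebyshev box) are grouped by transitive closure;
    each group keeps only its largest-area member.  Area ties keep the lowest
    slice index, then the lexicographically smallest centroid.
    """
    n = len(objects)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = objects[i], objects[j]
            if a.slice_index == b.slice_index:
                continue
            if (
                abs(a.centroid[0] - b.centroid[0]) <= dedup_tolerance_px
                and abs(a.centroid[1] - b.centroid[1]) <= dedup_tolerance_px
            ):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    groups: dict[int, list[NucleusObject]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(objects[i])
    survivors = []
    for members in groups.values():
        members.sort(key=lambda o: (-o.area_px, o.slice_index, o.centroid))
        if len(members) > 1 and members[0].area_px == members[1].area_px:
            log.debug("dedup area tie resolved by slice order at %s", members[0].centroid)
        survivors.append(members[0])
    survivors.sort(key=lambda o: (o.slice_index, o.centroid))
    return survivors


def segment_region(
    pair: StackPair, params: SegmentationParams, collect_counts: dict | None = None
) -> tuple[list[NucleusObject], np.ndarray]:
    """Run the full per-region pipeline; returns (unique nuclei, difference stack)."""
    diff = subtract_channels(pair, clip_negative=True if params.binary_subtract else params.clip_negative)
    if params.binary_subtract:
        gmask, _ = binarize(pair.green.astype(np.float64), params.threshold_method)
        rmask, _ = binarize(pair.red.astype(np.float64), params.threshold_method)
        mask = gmask & ~rmask
    else:
        mask, _ = binarize(diff, params.threshold_method)
    mask = morphological_open(mask, params.opening_radius_px)
    lo, hi = params.area_bounds_px(pair.pixel_size_um)
    objects: list[NucleusObject] = []
    n_components = 0
    for s in range(mask.shape[0]):
        labeled, n_comp = label_slice(mask[s])
        if not n_comp:
            continue
        n_components += n_comp
        # delete out-of-size components on the mask first (bwareaopen style):
        # the shape and size filters are independent per-object predicates, so
        # this is equivalent to filtering after feature extraction but avoids
        # computing convex hulls for thousands of noise specks.
        counts = np.bincount(labeled.ravel())
        bad = (counts < lo) | (counts > hi)
        bad[0] = False
        if bad.any():
            labeled[bad[labeled]] = 0
        objects.extend(
            compute_object_features(labeled, diff[s], slice_index=s, region_index=pair.region_index)
        )
    shaped = shape_filter(objects, params)
    sized = size_filter(shaped, lo, hi)
    unique = deduplicate_across_slices(sized, params.dedup_tolerance_px)
    if collect_counts is not None:
        collect_counts.update(
            {
                "components": n_components,
                "in_size_bounds": len(objects),
                "after_shape_filter": len(shaped),
                "after_size_filter": len(sized),
                "after_dedup": len(unique),
            }
        )
    log.info(
        "region %d: %d components -> %d in size bounds -> %d shape -> %d unique",
        pair.region_index, n_components, len(objects), len(shaped), len(unique),
    )
    return unique, diff


def segment_worm(image_set: WormImageSet, params: SegmentationParams) -> WormMeasurement:
    """Segment all four regions of one animal and aggregate the unique nuclei."""
    nuclei: list[NucleusObject] = []
    for pair in image_set.regions:
        try:
            unique, _ = segment_region(pair, params)
        except Exception as exc:
            raise RuntimeError(
                f"segmentation failed in region {pair.region_index} of {image_set.animal_id}: {exc}"
            ) from exc
        nuclei.extend(unique)
    return WormMeasurement(
        animal_id=image_set.animal_id,
        day=image_set.day,
        regime_id=image_set.regime_id,
        nuclei=nuclei,
    )
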