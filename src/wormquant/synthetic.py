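"""Ground-truthed synthetic worm z-stacks.

The renderer emulates the statistical structure the segmentation pipeline
must cope with, not worm anatomy:

* **Nuclei** are dim, green-only ellipsoids.  Each nucleus spans 1-4
  consecutive slices with its largest cross-section on the central slice; the
  in-plane profile is a truncated anisotropic Gaussian (intensity falls to
  ~0.61 of the slice peak at the support boundary), so thresholding has a
  genuine edge to get wrong.  Intestinal nuclei may be rendered "hollow"
  (dark nucleolar core) to exercise the nucleolus scorer.
* **Autofluorescent blobs** are irregular unions of 2-4 overlapping discs
  planted at identical intensity in BOTH channels, mimicking lipid droplets
  and gut granules; the dual-channel subtraction must cancel them.
* **Background** is additive Gaussian noise on a constant offset, identical
  in law for both channels.  Intensity units are arbitrary (acquisition bit
  depth is not modelled).

Every planted object is recorded in a :class:`GroundTruth` so that any stage
of the analysis can be scored against the scene that generated it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .priors import TISSUE_CLASSES, tissue_shape_prior
from .stacks import StackPair

#: In-plane radial fall-off: intensity = peak * exp(-_BETA * r^2) with r = 1
#: at the support boundary, giving an edge value of exp(-0.35) ~ 0.70 * peak.
_BETA = 0.35
#: Hollow-core profile (nucleolus without reporter): multiplicative dip at the
#: centre, ~0.10 * peak at r = 0, recovering to ~0.9 by r ~ 0.5.
_CORE_DEPTH = 0.9
_CORE_SIGMA = 0.25

DEFAULT_N_NUCLEI: dict[str, int] = {
    "intestine": 3,
    "neuron": 12,
    "hypodermis": 5,
    "muscle": 5,
}


class PlacementError(RuntimeError):
    """An object could not be placed without overlap within the attempt budget."""


@dataclass
class ImageSimParams:
    """Scene parameters for one synthetic region stack.

    Defaults reflect the acquisition geometry of the study design (four
    z-stacks of 30 slices at 3 um spacing per animal) and a low-SNR single
    copy reporter: nucleus peak amplitudes of 70-120 a.u. over background
    noise of sd 12 per channel give a peak SNR of ~4-7 relative to the
    sd-sqrt(2) noise of the subtracted image.
    """

    stack_shape: tuple[int, int, int] = (30, 512, 512)
    pixel_size_um: float = 0.4
    slice_spacing_um: float = 3.0
    n_nuclei: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_N_NUCLEI))
    nucleus_intensity_range: tuple[float, float] = (70.0, 120.0)
    n_autofluorescent_blobs: int = 10
    blob_intensity_range: tuple[float, float] = (60.0, 140.0)
    background_mean: float = 100.0
    background_sd: float = 12.0
    prior_overlap: float = 0.0
    hollow_fraction: float = 0.5
    max_placement_attempts: int = 500
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if any(d < 1 for d in self.stack_shape) or len(self.stack_shape) != 3:
            raise ValueError("stack_shape must be three dims >= 1")
        if any(v < 0 for v in self.n_nuclei.values()) or self.n_autofluorescent_blobs < 0:
            raise ValueError("object counts must be >= 0")
        unknown = set(self.n_nuclei) - set(TISSUE_CLASSES)
        if unknown:
            raise ValueError(f"unknown tissue classes in n_nuclei: {sorted(unknown)}")
        for rng_ in (self.nucleus_intensity_range, self.blob_intensity_range):
            if rng_[0] < 0 or rng_[1] < rng_[0]:
                raise ValueError("intensity ranges must be non-negative and ordered")
        if self.background_sd < 0 or self.background_mean < 0:
            raise ValueError("background noise model must be non-negative")
        if not (0.0 <= self.hollow_fraction <= 1.0):
            raise ValueError("hollow_fraction must be in [0, 1]")


@dataclass
class PlantedNucleus:
    centroid: tuple[float, float, float]  # (slice, row, col)
    semi_axes_px: tuple[float, float]
    orientation_rad: float
    span_slices: int
    tissue_class: str
    peak_amplitude: float
    nucleolus_state: str  # "filled" | "empty"
    target_area_px: float
    target_eccentricity: float
    central_slice: int
    #: per-slice rendered pixels: list of (slice, rows, cols) index arrays
    footprint: list[tuple[int, np.ndarray, np.ndarray]] = field(default_factory=list)
    total_intensity: float = 0.0          # 3-D sum of rendered values
    central_slice_intensity: float = 0.0  # 2-D sum on the central slice


@dataclass
class PlantedBlob:
    centroid: tuple[float, float, float]
    amplitude: float
    footprint: list[tuple[int, np.ndarray, np.ndarray]] = field(default_factory=list)


@dataclass
class GroundTruth:
    params: ImageSimParams
    region_index: int
    nuclei: list[PlantedNucleus] = field(default_factory=list)
    blobs: list[PlantedBlob] = field(default_factory=list)


def _boxes_overlap(a: tuple, b: tuple) -> bool:
    return not (
        a[1] < b[0] or b[1] < a[0]
        or a[3] < b[2] or b[3] < a[2]
        or a[5] < b[4] or b[5] < a[4]
    )


def _ellipse_patch(
    a: float, b: float, theta: float, row: float, col: float, shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pixels inside the ellipse and their normalised squared radius r2 <= 1."""
    reach = max(a, b)
    r0 = max(0, int(math.floor(row - reach)))
    r1 = min(shape[0] - 1, int(math.ceil(row + reach)))
    c0 = max(0, int(math.floor(col - reach)))
    c1 = min(shape[1] - 1, int(math.ceil(col + reach)))
    rr, cc = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1), indexing="ij")
    dr, dc = rr - row, cc - col
    ct, st = math.cos(theta), math.sin(theta)
    u = dr * ct + dc * st
    v = -dr * st + dc * ct
    r2 = (u / a) ** 2 + (v / b) ** 2
    keep = r2 <= 1.0
    return rr[keep], cc[keep], r2[keep]


def _span_offsets(span: int) -> list[int]:
    # central slice at offset 0; e.g. span 4 -> [-1, 0, 1, 2]
    return [o - (span - 1) // 2 for o in range(span)]


def render_stack_pair(
    params: ImageSimParams, region_index: int = 0, animal_id: str = "worm-0",
    day: int | None = None, regime_id: str | None = None,
) -> tuple[StackPair, GroundTruth]:
    """Render one green/red stack pair plus the scene's ground truth.

    Deterministic given ``params.rng_seed`` and ``region_index`` (the region
    index is folded into the seed sequence so the four stacks of one animal
    differ).  Raises :class:`PlacementError` if any object cannot be placed
    without overlap within ``params.max_placement_attempts`` tries.
    """
    if not (0 <= region_index < 4):
        raise ValueError("region_index must be in 0..3")
    rng = np.random.default_rng(np.random.SeedSequence([int(params.rng_seed), region_index]))
    n_slices, n_rows, n_cols = params.stack_shape
    green = np.zeros(params.stack_shape, dtype=np.float64)
    red = np.zeros(params.stack_shape, dtype=np.float64)
    gt = GroundTruth(params=params, region_index=region_index)
    boxes: list[tuple] = []

    # --- nuclei (green channel only) -------------------------------------
    for tissue in TISSUE_CLASSES:
        prior = tissue_shape_prior(tissue, params.prior_overlap)
        for k in range(params.n_nuclei.get(tissue, 0)):
            for _ in range(params.max_placement_attempts):
                area = rng.uniform(*prior.area_range_px)
                ecc = rng.uniform(*prior.eccentricity_range)
                axis_ratio = math.sqrt(1.0 - ecc**2)
                a = math.sqrt(area / (math.pi * axis_ratio))
                b = a * axis_ratio
                theta = rng.uniform(0.0, math.pi)
                span = int(rng.integers(1, min(4, n_slices) + 1))
                offs = _span_offsets(span)
                z0 = int(rng.integers(-offs[0], n_slices - offs[-1]))
                margin = a + 2.0
                if 2 * margin >= min(n_rows, n_cols) - 2:
                    continue
                row = rng.uniform(margin, n_rows - 1 - margin)
                col = rng.uniform(margin, n_cols - 1 - margin)
                box = (z0 + offs[0], z0 + offs[-1],
                       row - margin, row + margin, col - margin, col + margin)
                if not any(_boxes_overlap(box, other) for other in boxes):
                    break
            else:
                raise PlacementError(
                    f"could not place {tissue} nucleus {k} in region {region_index} "
                    f"after {params.max_placement_attempts} attempts"
                )
            boxes.append(box)
            amp = rng.uniform(*params.nucleus_intensity_range)
            hollow = tissue == "intestine" and rng.random() < params.hollow_fraction
            nuc = PlantedNucleus(
                centroid=(float(z0), row, col),
                semi_axes_px=(a, b),
                orientation_rad=theta,
                span_slices=span,
                tissue_class=tissue,
                peak_amplitude=amp,
                nucleolus_state="empty" if hollow else "filled",
                target_area_px=area,
                target_eccentricity=ecc,
                central_slice=z0,
            )
            half = abs(offs[0]) if abs(offs[0]) >= abs(offs[-1]) else abs(offs[-1])
            for off in offs:
                f = math.sqrt(max(0.0, 1.0 - (off / (half + 1.0)) ** 2))
                rr, cc, r2 = _ellipse_patch(a * f, b * f, theta, row, col, (n_rows, n_cols))
                if rr.size == 0:
                    continue
                vals = amp * f**2 * np.exp(-_BETA * r2)
                if hollow:
                    vals = vals * (1.0 - _CORE_DEPTH * np.exp(-r2 / (2.0 * _CORE_SIGMA**2)))
                green[z0 + off, rr, cc] += vals
                nuc.footprint.append((z0 + off, rr, cc))
            gt.nuclei.append(nuc)

    # --- autofluorescent blobs (both channels, matched intensity) ---------
    for k in range(params.n_autofluorescent_blobs):
        for _ in range(params.max_placement_attempts):
            n_discs = int(rng.integers(2, 5))
            radii = rng.uniform(3.0, 8.0, size=n_discs)
            jitter = rng.uniform(-6.0, 6.0, size=(n_discs, 2))
            reach = float(np.max(radii + np.abs(jitter).max(axis=1)))
            margin = reach + 2.0
            if 2 * margin >= min(n_rows, n_cols) - 2:
                continue
            row = rng.uniform(margin, n_rows - 1 - margin)
            col = rng.uniform(margin, n_cols - 1 - margin)
            span = int(rng.integers(1, min(2, n_slices) + 1))
            z0 = int(rng.integers(0, n_slices - span + 1))
            box = (z0, z0 + span - 1, row - margin, row + margin, col - margin, col + margin)
            if not any(_boxes_overlap(box, other) for other in boxes):
                break
        else:
            raise PlacementError(
                f"could not place blob {k} in region {region_index} "
                f"after {params.max_placement_attempts} attempts"
            )
        boxes.append(box)
        amp = rng.uniform(*params.blob_intensity_range)
        r0, r1 = int(math.floor(row - reach)), int(math.ceil(row + reach))
        c0, c1 = int(math.floor(col - reach)), int(math.ceil(col + reach))
        rr, cc = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1), indexing="ij")
        mask = np.zeros(rr.shape, dtype=bool)
        for (dr, dc), rad in zip(jitter, radii):
            mask |= (rr - (row + dr)) ** 2 + (cc - (col + dc)) ** 2 <= rad**2
        frr, fcc = rr[mask], cc[mask]
        blob = PlantedBlob(centroid=(float(z0), row, col), amplitude=amp)
        for z in range(z0, z0 + span):
            green[z, frr, fcc] += amp
            red[z, frr, fcc] += amp
            blob.footprint.append((z, frr.copy(), fcc.copy()))
        gt.blobs.append(blob)

    # Ground-truth intensity sums, measured from the noiseless green stack so
    # that conservation against the rendered scene is exact.
    for nuc in gt.nuclei:
        total = 0.0
        for z, rr, cc in nuc.footprint:
            s = float(np.sum(green[z, rr, cc]))
            total += s
            if z == nuc.central_slice:
                nuc.central_slice_intensity = s
        nuc.total_intensity = total

    # --- background ------------------------------------------------------
    if params.background_sd > 0:
        green += rng.normal(params.background_mean, params.background_sd, size=params.stack_shape)
        red += rng.normal(params.background_mean, params.background_sd, size=params.stack_shape)
    else:
        green += params.background_mean
        red += params.background_mean
    np.maximum(green, 0.0, out=green)
    np.maximum(red, 0.0, out=red)

    pair = StackPair(
        green=green, red=red,
        pixel_size_um=params.pixel_size_um,
        slice_spacing_um=params.slice_spacing_um,
        animal_id=animal_id, region_index=region_index, day=day, regime_id=regime_id,
    )
    return pair, gt


def sim_params_to_manifest(params: ImageSimParams) -> dict:
    """JSON-serialisable record of every simulation parameter."""
    d = asdict(params)
    d["stack_shape"] = list(params.stack_shape)
    return d
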