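"""Nucleolar occupancy scoring for intestinal nuclei.

The reporter either fills the whole nucleus ("filled" nucleolus) or leaves a
dark central core ("empty" — a donut).  The automated rule compares the mean
intensity of a central disc (diameter = ``center_fraction`` x the nucleus'
equivalent diameter) with the mean over the remaining ring of the nucleus
mask: the call is *filled* when centre/ring >= tau, *empty* when below, and
*indeterminate* when the geometry degenerates (mask too small for a >= 1 px
centre disc, or an empty/zero ring).  Because the rule is a ratio it is
invariant to rescaling the intensity image.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .segmentation import NucleusObject

log = logging.getLogger(__name__)

DEFAULT_CENTER_FRACTION = 0.3
DEFAULT_TAU = 0.6


@dataclass
class NucleolusCall:
    nucleus_id: int
    state: str  # "filled" | "empty" | "indeterminate"
    center_mean: float
    ring_mean: float
    ratio: float | None


def score_nucleolus(
    nucleus: NucleusObject,
    intensity_slice: np.ndarray,
    center_fraction: float = DEFAULT_CENTER_FRACTION,
    tau: float = DEFAULT_TAU,
    nucleus_id: int = 0,
) -> NucleolusCall:
    """Call one intestinal nucleus filled/empty from its centre/ring ratio."""
    if not (0 < center_fraction < 1):
        raise ValueError("center_fraction must be in (0, 1)")
    if nucleus.coords is None:
        raise ValueError("nucleus pixel coordinates are required for scoring")
    coords = nucleus.coords
    radius = center_fraction * nucleus.equivalent_diameter_px / 2.0
    # centre disc is a region of the image (a hollow nucleus has no mask
    # pixels at its centre); the ring is the nucleus mask minus that disc
    r0, c0 = nucleus.centroid
    rr, cc = np.meshgrid(
        np.arange(max(0, int(np.floor(r0 - radius))), min(intensity_slice.shape[0], int(np.ceil(r0 + radius)) + 1)),
        np.arange(max(0, int(np.floor(c0 - radius))), min(intensity_slice.shape[1], int(np.ceil(c0 + radius)) + 1)),
        indexing="ij",
    )
    in_disc = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2
    center_px = np.column_stack([rr[in_disc], cc[in_disc]])
    ring_mask = (coords[:, 0] - r0) ** 2 + (coords[:, 1] - c0) ** 2 > radius**2
    if center_px.shape[0] == 0 or not ring_mask.any():
        log.debug("nucleus %d too small for a centre disc; indeterminate", nucleus_id)
        call = NucleolusCall(nucleus_id, "indeterminate", float("nan"), float("nan"), None)
    else:
        center_mean = float(intensity_slice[center_px[:, 0], center_px[:, 1]].mean())
        ring_vals = intensity_slice[coords[ring_mask, 0], coords[ring_mask, 1]].astype(float)
        ring_mean = float(ring_vals.mean())
        if ring_mean <= 0:
            call = NucleolusCall(nucleus_id, "indeterminate", center_mean, ring_mean, None)
        else:
            ratio = center_mean / ring_mean
            state = "filled" if ratio >= tau else "empty"
            call = NucleolusCall(nucleus_id, state, center_mean, ring_mean, ratio)
    nucleus.nucleolus_state = call.state
    nucleus.nucleolus_ratio = call.ratio
    return call


def filled_fraction(
    calls: list[NucleolusCall], alpha: float = 0.05
) -> tuple[float, tuple[float, float], int]:
    """Fraction of determinate calls that are filled, with a binomial CI.

    Returns ``(fraction, (ci_low, ci_high), n_indeterminate)``; indeterminate
    calls are excluded from the denominator and reported separately.  Raises
    when no determinate call exists.
    """
    filled = sum(c.state == "filled" for c in calls)
    empty = sum(c.state == "empty" for c in calls)
    n_ind = sum(c.state == "indeterminate" for c in calls)
    n = filled + empty
    if n == 0:
        raise ValueError("no determinate nucleolus calls")
    frac = filled / n
    lo, hi = proportion_confint(filled, n, alpha=alpha, method="beta")
    return frac, (float(lo), float(hi)), n_ind
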