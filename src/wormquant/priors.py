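"""Tissue-specific nucleus shape priors.

The four somatic tissue classes scored in the imaging pipeline differ mainly
in nuclear size: intestinal nuclei are by far the largest somatic nuclei in
the worm, neuronal nuclei the smallest, with hypodermal and body-wall-muscle
nuclei in between (muscle nuclei are the most elongated).  The priors below
encode those differences as uniform ranges over area (px), eccentricity and
equivalent diameter; they drive both the image simulator and the sampling of
labelled feature sets for classifier training.

At ``overlap = 0`` the class area ranges are pairwise disjoint with a gap
between adjacent classes, so an area-threshold classifier has zero Bayes
error.  An ``overlap > 0`` widens every range by ``overlap * width / 2`` on
each side; adjacent ranges start to intersect from overlap ~0.09-0.15
(pair-dependent), creating genuinely ambiguous nuclei whose Bayes error can
be estimated by Monte Carlo from the generative densities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

TISSUE_CLASSES: tuple[str, ...] = ("intestine", "neuron", "hypodermis", "muscle")

#: Base area ranges (pixels at 0.4 um/px), smallest to largest class, with an
#: 8 px gap between adjacent classes so the zero-overlap configuration is
#: genuinely separable (no probability mass between classes; an
#: area-threshold classifier has zero Bayes error).  The neuron lower bound
#: leaves margin above the segmentation size filter's default minimum
#: (25 px): "smaller than neurons" is the deletion rule, so neurons
#: themselves must clear it even after morphological opening.
_BASE_AREA_PX: dict[str, tuple[float, float]] = {
    "neuron": (36.0, 76.0),
    "muscle": (84.0, 156.0),
    "hypodermis": (164.0, 276.0),
    "intestine": (284.0, 620.0),
}

_ECC_RANGE: dict[str, tuple[float, float]] = {
    "neuron": (0.0, 0.55),
    "muscle": (0.45, 0.80),
    "hypodermis": (0.0, 0.50),
    "intestine": (0.0, 0.45),
}

FEATURE_NAMES: tuple[str, ...] = ("area", "eccentricity", "equivalent_diameter")


@dataclass(frozen=True)
class ShapePrior:
    tissue: str
    area_range_px: tuple[float, float]
    eccentricity_range: tuple[float, float]
    equivalent_diameter_range_px: tuple[float, float]


def _eqd(area: float) -> float:
    return math.sqrt(4.0 * area / math.pi)


def tissue_shape_prior(tissue_class: str, overlap: float = 0.0) -> ShapePrior:
    """Return the (area, eccentricity, equivalent-diameter) prior for a class."""
    if tissue_class not in TISSUE_CLASSES:
        raise ValueError(f"unknown tissue class {tissue_class!r}; expected one of {TISSUE_CLASSES}")
    if overlap < 0:
        raise ValueError("overlap must be >= 0")
    lo, hi = _BASE_AREA_PX[tissue_class]
    pad = overlap * (hi - lo) / 2.0
    lo, hi = max(1.0, lo - pad), hi + pad
    return ShapePrior(
        tissue=tissue_class,
        area_range_px=(lo, hi),
        eccentricity_range=_ECC_RANGE[tissue_class],
        equivalent_diameter_range_px=(_eqd(lo), _eqd(hi)),
    )


def sample_features(
    n_per_class: int | dict[str, int],
    overlap: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw labelled (area, eccentricity, equivalent_diameter) feature vectors.

    Returns ``(X, y)`` where ``X`` is ``(n, 3)`` float and ``y`` an array of
    tissue-class strings.  Equivalent diameter is the deterministic function
    of area, as it is for measured connected components.
    """
    rng = np.random.default_rng(rng)
    if isinstance(n_per_class, int):
        n_per_class = {t: n_per_class for t in TISSUE_CLASSES}
    rows, labels = [], []
    for tissue in TISSUE_CLASSES:
        prior = tissue_shape_prior(tissue, overlap)
        n = int(n_per_class.get(tissue, 0))
        area = rng.uniform(*prior.area_range_px, size=n)
        ecc = rng.uniform(*prior.eccentricity_range, size=n)
        eqd = np.sqrt(4.0 * area / math.pi)
        rows.append(np.column_stack([area, ecc, eqd]))
        labels.extend([tissue] * n)
    return np.vstack(rows), np.asarray(labels, dtype=object)


def bayes_accuracy(
    overlap: float,
    n_mc: int = 200_000,
    class_probs: dict[str, float] | None = None,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Monte-Carlo estimate of the Bayes accuracy under the generative priors.

    The Bayes rule assigns the class maximising ``P(class) * density(area,
    ecc | class)``; equivalent diameter is a deterministic function of area
    and carries no extra information.
    """
    rng = np.random.default_rng(rng)
    if class_probs is None:
        class_probs = {t: 1.0 / len(TISSUE_CLASSES) for t in TISSUE_CLASSES}
    priors = {t: tissue_shape_prior(t, overlap) for t in TISSUE_CLASSES}
    classes = list(TISSUE_CLASSES)
    probs = np.array([class_probs[t] for t in classes])
    probs = probs / probs.sum()
    counts = rng.multinomial(n_mc, probs)
    correct = 0
    for tissue, n in zip(classes, counts):
        prior = priors[tissue]
        area = rng.uniform(*prior.area_range_px, size=n)
        ecc = rng.uniform(*prior.eccentricity_range, size=n)
        post = np.zeros((n, len(classes)))
        for j, other in enumerate(classes):
            p = priors[other]
            (alo, ahi), (elo, ehi) = p.area_range_px, p.eccentricity_range
            dens = 1.0 / ((ahi - alo) * (ehi - elo))
            ok = (area >= alo) & (area <= ahi) & (ecc >= elo) & (ecc <= ehi)
            post[:, j] = np.where(ok, probs[j] * dens, 0.0)
        correct += int(np.sum(np.argmax(post, axis=1) == classes.index(tissue)))
    return correct / n_mc
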