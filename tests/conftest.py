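import numpy as np
import pytest

import wormquant as wq


@pytest.fixture(scope="session")
def small_scene():
    """One small rendered scene with nuclei + blobs + noise, segmented once."""
    params = wq.ImageSimParams(
        stack_shape=(8, 128, 128),
        n_nuclei={"intestine": 1, "neuron": 3, "hypodermis": 1, "muscle": 1},
        n_autofluorescent_blobs=2,
        rng_seed=11,
    )
    pair, gt = wq.render_stack_pair(params, region_index=0)
    return params, pair, gt


@pytest.fixture(scope="session")
def noiseless_scene():
    params = wq.ImageSimParams(
        stack_shape=(8, 96, 96),
        n_nuclei={"intestine": 1, "neuron": 2, "hypodermis": 1, "muscle": 1},
        n_autofluorescent_blobs=2,
        background_mean=0.0,
        background_sd=0.0,
        rng_seed=5,
    )
    pair, gt = wq.render_stack_pair(params, region_index=1)
    return params, pair, gt


def match_to_ground_truth(gt, detections):
    """Assign detections to planted objects by footprint membership.

    Returns (matched nucleus indices, per-detection tags, intensity relative
    errors for nucleus-matched detections against the planted central-slice
    sum).
    """
    lookup = {}
    for i, nuc in enumerate(gt.nuclei):
        for z, rr, cc in nuc.footprint:
            for r, c in zip(rr, cc):
                lookup[(z, int(r), int(c))] = ("nucleus", i)
    for i, blob in enumerate(gt.blobs):
        for z, rr, cc in blob.footprint:
            for r, c in zip(rr, cc):
                lookup.setdefault((z, int(r), int(c)), ("blob", i))
    matched, tags, errors = set(), [], []
    for det in detections:
        key = (det.slice_index, int(round(det.centroid[0])), int(round(det.centroid[1])))
        tag = lookup.get(key, ("background", None))
        tags.append(tag)
        if tag[0] == "nucleus":
            matched.add(tag[1])
            truth = gt.nuclei[tag[1]].central_slice_intensity
            errors.append(abs(det.total_intensity - truth) / truth)
    return matched, tags, np.asarray(errors)
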