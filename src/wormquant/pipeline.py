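"""End-to-end orchestration: simulate -> segment -> classify -> score ->
survival -> associate, with a strict config schema and a run manifest.

The imaging arm renders a small set of ground-truthed animals and carries them
through segmentation, tissue classification and nucleolus scoring; the cohort
arm simulates the full dietary-restriction study (per-day intensities and
survival scoring at lifespan-assay scale) and feeds the association analyses.
Every output is a text file (CSV/JSON/SVG) and every threshold, seed and
parameter is echoed into ``manifest.json``, so re-running a config reproduces
byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .association import build_summaries, regress_lifespan, summaries_to_frame
from .classify import aggregate_by_tissue, classify, evaluate, train_tree
from .cohort import (
    CohortSimParams,
    cohort_params_to_manifest,
    cohort_to_long_intensities,
    simulate_cohort,
)
from .nucleolus import filled_fraction, score_nucleolus
from .priors import sample_features
from .segmentation import SegmentationParams, segment_region
from .stacks import write_stack_pair
from .survival import default_regime_grid
from .synthetic import ImageSimParams, render_stack_pair, sim_params_to_manifest

log = logging.getLogger(__name__)

_STRICT = ConfigDict(extra="forbid")


class ImagingConfig(BaseModel):
    model_config = _STRICT
    n_worms: int = 2
    stack_shape: tuple[int, int, int] = (16, 256, 256)
    n_nuclei: dict[str, int] = Field(
        default_factory=lambda: {"intestine": 2, "neuron": 5, "hypodermis": 2, "muscle": 2}
    )
    n_autofluorescent_blobs: int = 4
    background_sd: float = 12.0
    prior_overlap: float = 0.0
    hollow_fraction: float = 0.5
    write_stacks: bool = False


class SegmentationConfig(BaseModel):
    model_config = _STRICT
    threshold_method: str | float = "otsu"
    extent_min: float = 0.50
    eccentricity_max: float = 0.85
    solidity_min: float = 0.75
    opening_radius_px: int = 1
    min_area_um2: float = 4.0
    max_area_um2: float = 120.0
    dedup_tolerance_px: float = 4.0
    binary_subtract: bool = False


class ClassifierConfig(BaseModel):
    model_config = _STRICT
    n_train: int = 600
    n_validation: int = 200
    overlap: float = 0.0
    max_splits: int = 100


class NucleolusConfig(BaseModel):
    model_config = _STRICT
    center_fraction: float = 0.3
    tau: float = 0.6


class CohortConfig(BaseModel):
    model_config = _STRICT
    animals_per_regime: int = 60
    intensity_noise_sd: float = 60.0
    lifespan_intercept_days: float = 14.0
    lifespan_slope_days_per_au: float = 0.003
    lifespan_noise_sd_days: float = 1.5
    censor_fraction: float = 0.05


class RunConfig(BaseModel):
    """Versioned pipeline configuration; unknown keys are rejected."""

    model_config = _STRICT
    version: int = 1
    seed: int = 0
    imaging: ImagingConfig = Field(default_factory=ImagingConfig)
    segmentation: SegmentationConfig = Field(default_factory=SegmentationConfig)
    classifier: ClassifierConfig = Field(default_factory=ClassifierConfig)
    nucleolus: NucleolusConfig = Field(default_factory=NucleolusConfig)
    cohort: CohortConfig = Field(default_factory=CohortConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})


def _seg_params(cfg: SegmentationConfig) -> SegmentationParams:
    return SegmentationParams(**cfg.model_dump())


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Run every stage and write manifests, CSVs, JSONs into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seed_classifier, seed_imaging, seed_cohort = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)
    )
    manifest: dict = {
        "wormquant_version": __version__,
        "config": config.model_dump(mode="json"),
        "derived_seeds": {
            "classifier": seed_classifier,
            "imaging": seed_imaging,
            "cohort": seed_cohort,
        },
        "stage_counts": {},
    }
    seg_params = _seg_params(config.segmentation)

    # --- classifier ------------------------------------------------------
    rng = np.random.default_rng(seed_classifier)
    n_tr = max(1, config.classifier.n_train // 4)
    n_va = max(1, config.classifier.n_validation // 4)
    X_tr, y_tr = sample_features(n_tr, config.classifier.overlap, rng)
    X_va, y_va = sample_features(n_va, config.classifier.overlap, rng)
    model = train_tree(X_tr, y_tr, max_splits=config.classifier.max_splits)
    accuracy, confusion = evaluate(model, X_va, y_va)
    model.to_json(out / "classifier_model.json")
    confusion.to_csv(out / "classifier_confusion.csv")
    (out / "classifier_metrics.json").write_text(
        json.dumps(
            {"validation_accuracy": accuracy, "n_train": len(y_tr), "n_validation": len(y_va),
             "n_splits": model.n_splits},
            indent=1,
        )
    )
    manifest["stage_counts"]["classifier"] = {"train": len(y_tr), "validation": len(y_va)}

    # --- imaging arm -------------------------------------------------------
    nuclei_rows, measurement_rows, nucleolus_calls = [], [], []
    counts_by_worm = {}
    for w in range(config.imaging.n_worms):
        animal_id = f"worm-{w:03d}"
        worm_nuclei = []
        stage_counts: dict = {}
        for region in range(4):
            params = ImageSimParams(
                stack_shape=config.imaging.stack_shape,
                n_nuclei=dict(config.imaging.n_nuclei),
                n_autofluorescent_blobs=config.imaging.n_autofluorescent_blobs,
                background_sd=config.imaging.background_sd,
                prior_overlap=config.imaging.prior_overlap,
                hollow_fraction=config.imaging.hollow_fraction,
                rng_seed=seed_imaging + w,
            )
            pair, _gt = render_stack_pair(params, region_index=region, animal_id=animal_id)
            if config.imaging.write_stacks:
                stacks_dir = out / "stacks"
                stacks_dir.mkdir(exist_ok=True)
                write_stack_pair(
                    pair,
                    stacks_dir / f"{animal_id}_r{region}_green.tif",
                    stacks_dir / f"{animal_id}_r{region}_red.tif",
                )
            region_counts: dict = {}
            unique, diff = segment_region(pair, seg_params, collect_counts=region_counts)
            stage_counts[f"region_{region}"] = region_counts
            classify(model, unique)
            for nuc in unique:
                if nuc.tissue == "intestine":
                    call = score_nucleolus(
                        nuc,
                        diff[nuc.slice_index],
                        center_fraction=config.nucleolus.center_fraction,
                        tau=config.nucleolus.tau,
                        nucleus_id=len(nucleolus_calls),
                    )
                    nucleolus_calls.append(call)
            worm_nuclei.extend(unique)
        counts_by_worm[animal_id] = stage_counts
        tissue_summary = aggregate_by_tissue(worm_nuclei)
        tissue_summary.insert(0, "animal_id", animal_id)
        measurement_rows.append(
            {
                "animal_id": animal_id,
                "nuclei_count": len(worm_nuclei),
                "total_nuclear_intensity": sum(n.total_intensity for n in worm_nuclei),
                "per_tissue": tissue_summary.drop(columns="animal_id").to_dict(orient="index"),
            }
        )
        for nuc in worm_nuclei:
            row = nuc.to_record()
            row["animal_id"] = animal_id
            nuclei_rows.append(row)
    pd.DataFrame(nuclei_rows).to_csv(out / "nuclei.csv", index=False)
    (out / "worm_measurements.json").write_text(json.dumps(measurement_rows, indent=1))
    manifest["stage_counts"]["imaging"] = counts_by_worm
    if nucleolus_calls:
        frac, ci, n_ind = filled_fraction(nucleolus_calls)
        (out / "nucleolus_fractions.json").write_text(
            json.dumps(
                {"filled_fraction": frac, "ci95": list(ci), "n_indeterminate": n_ind,
                 "n_calls": len(nucleolus_calls)},
                indent=1,
            )
        )

    # --- cohort arm --------------------------------------------------------
    cohort_params = CohortSimParams(
        regimes=default_regime_grid(),
        animals_per_regime=config.cohort.animals_per_regime,
        intensity_noise_sd=config.cohort.intensity_noise_sd,
        lifespan_intercept_days=config.cohort.lifespan_intercept_days,
        lifespan_slope_days_per_au=config.cohort.lifespan_slope_days_per_au,
        lifespan_noise_sd_days=config.cohort.lifespan_noise_sd_days,
        censor_fraction=config.cohort.censor_fraction,
        rng_seed=seed_cohort,
    )
    cohort = simulate_cohort(cohort_params)
    cohort.to_csv(out / "cohort.csv", index=False)
    manifest["cohort_params"] = cohort_params_to_manifest(cohort_params)
    records = cohort.rename(columns={"observed_day": "day"})[
        ["animal_id", "regime_id", "day", "status"]
    ]
    summaries = build_summaries(cohort_to_long_intensities(cohort), records, cohort_params.regimes)
    frame = summaries_to_frame(summaries)
    frame.to_csv(out / "cohort_summaries.csv", index=False)
    fits = {
        "lifespan_vs_cumulative_intensity": regress_lifespan(summaries).to_dict(),
        "lifespan_vs_food_availability_quadratic": regress_lifespan(
            summaries, predictor="food_availability", model="quadratic"
        ).to_dict(),
    }
    (out / "regressions.json").write_text(json.dumps(fits, indent=1))
    manifest["stage_counts"]["cohort"] = {
        "animals": int(cohort.shape[0]),
        "regimes": len(cohort_params.regimes),
    }

    manifest["imaging_params_example"] = sim_params_to_manifest(
        ImageSimParams(
            stack_shape=config.imaging.stack_shape,
            n_nuclei=dict(config.imaging.n_nuclei),
            n_autofluorescent_blobs=config.imaging.n_autofluorescent_blobs,
            background_sd=config.imaging.background_sd,
            prior_overlap=config.imaging.prior_overlap,
            hollow_fraction=config.imaging.hollow_fraction,
            rng_seed=seed_imaging,
        )
    )
    manifest["segmentation_params"] = {
        k: v for k, v in vars(seg_params).items()
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    log.info("pipeline complete: %s", out)
    return out
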