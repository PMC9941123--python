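"""Simulated dietary-restriction cohorts.

The generative model couples three ingredients:

1. A non-monotonic nuclear-reporter **response surface** over (food
   concentration, exposure time): the product of a log-concentration bump
   centred on 1e8 cells/ml and an exposure-time bump centred on 12 h, scaled
   by a per-adult-day attenuation that makes Day-10 responses collapse
   towards the well-fed baseline (responsiveness declines with age).
2. Per-animal, per-day **total nuclear intensity** draws: surface value plus
   additive Gaussian noise.
3. **Lifespan** linearly coupled to cumulative intensity over adult Days
   1, 4, 7, 10: ``lifespan = intercept + slope * cumulative + sd * z`` where
   ``z`` is a standardised Weibull(shape=4) deviate — worm-like mortality
   curvature, exactly linear in the noise-free limit.

Censoring models loss to manipulation: an independent Uniform handling-loss
time that censors the animal when it precedes death.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .survival import DRRegime, default_regime_grid

OBSERVATION_DAYS: tuple[int, ...] = (1, 4, 7, 10)

DEFAULT_ATTENUATION: dict[int, float] = {1: 1.0, 4: 0.70, 7: 0.35, 10: 0.03}


@dataclass
class CohortSimParams:
    regimes: list[DRRegime] = field(default_factory=default_regime_grid)
    animals_per_regime: int = 200
    baseline_intensity: float = 200.0       # a.u., ad libitum control level (> 0)
    response_amplitude: float = 800.0       # a.u. at the surface peak, Day 1
    log10_conc_peak: float = 8.0            # peak at 1e8 cells/ml
    log10_conc_sigma: float = 1.0
    conc_pseudocount: float = 1e6           # keeps log10 defined at 0 cells/ml
    exposure_peak_h: float = 12.0
    exposure_sigma_h: float = 8.0
    attenuation: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_ATTENUATION))
    intensity_noise_sd: float = 60.0        # a.u. per animal per day
    lifespan_intercept_days: float = 14.0
    lifespan_slope_days_per_au: float = 0.003
    lifespan_noise_sd_days: float = 1.5
    survival_family: str = "weibull"
    weibull_shape: float = 4.0
    censor_fraction: float = 0.05           # probability of a handling-loss hazard
    censor_window_days: tuple[float, float] = (3.0, 25.0)
    round_to_grid: bool = False             # snap observations to the 3-day scoring grid
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.animals_per_regime < 1:
            raise ValueError("animals_per_regime must be >= 1")
        if any(not (0 < a <= 1) for a in self.attenuation.values()):
            raise ValueError("attenuation factors must lie in (0, 1]")
        if self.intensity_noise_sd < 0 or self.lifespan_noise_sd_days < 0:
            raise ValueError("noise sds must be >= 0")
        if self.baseline_intensity <= 0:
            raise ValueError("baseline intensity must be > 0")
        if self.survival_family != "weibull":
            raise ValueError(f"unsupported survival family {self.survival_family!r}")


def simulate_response(
    concentration: float, exposure_h: float, day: int, params: CohortSimParams
) -> float:
    """Expected total nuclear intensity (a.u.) for one regime cell.

    ``exposure_h == 0`` is the ad libitum control and returns the baseline;
    otherwise baseline + amplitude * conc-bump * time-bump * day-attenuation.
    """
    if concentration < 0 or exposure_h < 0:
        raise ValueError("concentration and exposure must be >= 0")
    if day not in params.attenuation:
        raise ValueError(f"day {day} outside the sampled days {sorted(params.attenuation)}")
    if exposure_h == 0:
        return params.baseline_intensity
    lc = math.log10(concentration + params.conc_pseudocount)
    g_conc = math.exp(-((lc - params.log10_conc_peak) ** 2) / (2 * params.log10_conc_sigma**2))
    g_time = math.exp(
        -((exposure_h - params.exposure_peak_h) ** 2) / (2 * params.exposure_sigma_h**2)
    )
    return params.baseline_intensity + params.response_amplitude * g_conc * g_time * params.attenuation[day]


def expected_cumulative_intensity(regime: DRRegime, params: CohortSimParams) -> float:
    """Noise-free cumulative intensity over the four sampled adult days."""
    return sum(
        simulate_response(regime.food_concentration, regime.exposure_h, d, params)
        for d in OBSERVATION_DAYS
    )


def _standardised_weibull(rng: np.random.Generator, shape: float, size: int) -> np.ndarray:
    w = rng.weibull(shape, size=size)
    mu = math.gamma(1.0 + 1.0 / shape)
    sd = math.sqrt(math.gamma(1.0 + 2.0 / shape) - mu**2)
    return (w - mu) / sd


def _snap_to_grid(day: float) -> float:
    # scoring every 3rd day starting on adult Day 1
    return 1.0 + 3.0 * math.ceil(max(day - 1.0, 0.0) / 3.0)


def simulate_cohort(params: CohortSimParams) -> pd.DataFrame:
    """Simulate per-animal intensities, lifespans and survival scoring.

    Returns a tidy per-animal table with one row per animal: regime, per-day
    intensity draws, cumulative intensity, true lifespan, the observed day and
    its dead/censored status.  Deterministic given ``params.rng_seed``.
    """
    rng = np.random.default_rng(params.rng_seed)
    rows: list[dict] = []
    for regime in params.regimes:
        n = params.animals_per_regime
        means = {
            d: simulate_response(regime.food_concentration, regime.exposure_h, d, params)
            for d in OBSERVATION_DAYS
        }
        draws = {
            d: np.maximum(means[d] + rng.normal(0.0, params.intensity_noise_sd, size=n), 0.0)
            if params.intensity_noise_sd > 0
            else np.full(n, means[d])
            for d in OBSERVATION_DAYS
        }
        cumulative = sum(draws[d] for d in OBSERVATION_DAYS)
        z = _standardised_weibull(rng, params.weibull_shape, n)
        lifespan = (
            params.lifespan_intercept_days
            + params.lifespan_slope_days_per_au * cumulative
            + params.lifespan_noise_sd_days * z
        )
        lifespan = np.maximum(lifespan, 0.5)
        hazard = rng.random(n) < params.censor_fraction
        loss_time = rng.uniform(*params.censor_window_days, size=n)
        censored = hazard & (loss_time < lifespan)
        observed = np.where(censored, loss_time, lifespan)
        if params.round_to_grid:
            observed = np.array([_snap_to_grid(t) for t in observed])
        for i in range(n):
            rows.append(
                {
                    "animal_id": f"{regime.regime_id}-{i:04d}",
                    "regime_id": regime.regime_id,
                    "food_concentration": regime.food_concentration,
                    "exposure_h": regime.exposure_h,
                    **{f"intensity_day_{d}": float(draws[d][i]) for d in OBSERVATION_DAYS},
                    "cumulative_intensity": float(cumulative[i]),
                    "lifespan_days": float(lifespan[i]),
                    "observed_day": float(observed[i]),
                    "status": "censored" if censored[i] else "dead",
                }
            )
    return pd.DataFrame(rows)


def cohort_to_long_intensities(cohort: pd.DataFrame) -> pd.DataFrame:
    """Reshape a cohort table to tidy (animal, regime, day, total_intensity)."""
    frames = []
    for d in OBSERVATION_DAYS:
        frames.append(
            pd.DataFrame(
                {
                    "animal_id": cohort["animal_id"],
                    "regime_id": cohort["regime_id"],
                    "day": d,
                    "total_intensity": cohort[f"intensity_day_{d}"],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def calibrate_lifespan_noise(params: CohortSimParams, target_r2: float) -> float:
    """Lifespan noise sd giving an expected regime-level regression R^2.

    Regressing regime-mean lifespan on the *measured* regime-mean cumulative
    intensity leaves only the lifespan noise in the residual, so
    ``R^2 ~ b^2 Var(x) / (b^2 Var(x) + sd^2 / n)`` where Var(x) includes the
    sampling noise of the regime means.  Solving for sd gives the calibrated
    value.
    """
    if not (0 < target_r2 < 1):
        raise ValueError("target_r2 must be in (0, 1)")
    n = params.animals_per_regime
    x = np.array([expected_cumulative_intensity(r, params) for r in params.regimes])
    var_x = float(np.var(x, ddof=1)) + len(OBSERVATION_DAYS) * params.intensity_noise_sd**2 / n
    b = params.lifespan_slope_days_per_au
    return math.sqrt(n * b**2 * var_x * (1.0 / target_r2 - 1.0))


def cohort_params_to_manifest(params: CohortSimParams) -> dict:
    d = asdict(params)
    d["regimes"] = [asdict(r) for r in params.regimes]
    d["attenuation"] = {str(k): v for k, v in params.attenuation.items()}
    return d
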