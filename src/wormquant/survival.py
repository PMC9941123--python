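"""Kaplan-Meier survival summaries for dietary-restriction cohorts.

Animals in liquid culture are scored alive / dead / censored on a 3-day grid;
mean lifespan is the restricted mean survival time (area under the
product-limit curve up to the last observed death — identical to the
Kaplan-Meier mean whenever the curve reaches zero), and mortality quantiles
are the earliest times at which a stated fraction of the population has died.

The product-limit curve itself is fitted with :mod:`lifelines`; the restricted
mean is integrated directly from the step function so the no-censoring
identity (restricted mean == arithmetic mean of death times) holds to float
rounding.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

log = logging.getLogger(__name__)

AD_LIBITUM_CONCENTRATION = 1e10  # OP50 cells/ml
DR_CONCENTRATIONS = (1e9, 1e8, 0.0)
DR_EXPOSURES_H = (6.0, 12.0, 24.0)
DEFAULT_EXPOSURE_DAYS = (1, 4, 7, 10)


@dataclass(frozen=True)
class DRRegime:
    """One dietary-restriction regime: a food concentration held for a fixed
    number of hours on each listed adult day, ad libitum otherwise."""

    regime_id: str
    food_concentration: float  # OP50 cells/ml during exposure
    exposure_h: float          # 0 for the ad libitum control
    exposure_days: tuple[int, ...] = DEFAULT_EXPOSURE_DAYS

    def __post_init__(self) -> None:
        if self.food_concentration < 0:
            raise ValueError("food concentration must be >= 0")
        if not (0 <= self.exposure_h <= 24):
            raise ValueError("exposure_h must be within 0..24")
        days = self.exposure_days
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("exposure_days must be strictly increasing")

    @property
    def is_control(self) -> bool:
        return self.exposure_h == 0


def default_regime_grid() -> list[DRRegime]:
    """The 3 concentrations x 3 exposure times plus the ad libitum control."""
    regimes = [
        DRRegime(
            regime_id=f"c{conc:.0e}_h{int(h)}",
            food_concentration=conc,
            exposure_h=h,
        )
        for conc in DR_CONCENTRATIONS
        for h in DR_EXPOSURES_H
    ]
    regimes.append(
        DRRegime(regime_id="control", food_concentration=AD_LIBITUM_CONCENTRATION, exposure_h=0.0)
    )
    return regimes


@dataclass
class SurvivalRecord:
    animal_id: str
    regime_id: str
    day: float          # adult day of the observation
    status: str         # "dead" | "censored"

    def __post_init__(self) -> None:
        if self.status not in ("dead", "censored"):
            raise ValueError("status must be 'dead' or 'censored'")
        if self.day <= 0:
            raise ValueError("observation day must be > 0")


@dataclass
class SurvivalCurve:
    """Product-limit estimate with its event table."""

    times: np.ndarray        # distinct death times, ascending
    survival: np.ndarray     # S(t) just after each death time
    at_risk: np.ndarray
    deaths: np.ndarray
    n: int
    n_censored: int
    all_censored: bool = False
    kmf: KaplanMeierFitter | None = field(default=None, repr=False)


def km_curve(
    durations: np.ndarray | list[float] | pd.DataFrame,
    event_observed: np.ndarray | list[bool] | None = None,
) -> SurvivalCurve:
    """Kaplan-Meier curve from durations + event flags or a records table.

    A DataFrame input must carry ``day`` and ``status`` columns (the
    :class:`SurvivalRecord` layout).  Ties are handled with deaths occurring
    before censorings at equal times (the product-limit convention).
    """
    if isinstance(durations, pd.DataFrame):
        df = durations
        event_observed = (df["status"] == "dead").to_numpy()
        durations = df["day"].to_numpy(dtype=float)
    durations = np.asarray(durations, dtype=float)
    if event_observed is None:
        event_observed = np.ones_like(durations, dtype=bool)
    event_observed = np.asarray(event_observed, dtype=bool)
    if durations.size == 0:
        raise ValueError("at least one record is required")
    kmf = KaplanMeierFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        kmf.fit(durations, event_observed)
    table = kmf.event_table
    death_rows = table[table["observed"] > 0]
    times = death_rows.index.to_numpy(dtype=float)
    at_risk = death_rows["at_risk"].to_numpy(dtype=float)
    deaths = death_rows["observed"].to_numpy(dtype=float)
    # plain running product — keeps the telescoping no-censoring identity exact
    surv = np.empty_like(times)
    s = 1.0
    for i, (n_i, d_i) in enumerate(zip(at_risk, deaths)):
        s = s * (1.0 - d_i / n_i)
        surv[i] = s
    all_cens = not event_observed.any()
    if all_cens:
        log.warning("all observations censored: survival curve is uninformative")
    return SurvivalCurve(
        times=times, survival=surv, at_risk=at_risk, deaths=deaths,
        n=int(durations.size), n_censored=int((~event_observed).sum()),
        all_censored=all_cens, kmf=kmf,
    )


def mean_lifespan(curve: SurvivalCurve) -> float:
    """Restricted mean survival time: area under S(t) up to the last death.

    With no censoring this equals the arithmetic mean of the death times.
    """
    if curve.all_censored or curve.times.size == 0:
        log.warning("mean lifespan requested on a curve with no observed deaths")
        raise ValueError("mean lifespan undefined: no observed deaths")
    area = float(curve.times[0])  # S = 1 on [0, t_1)
    for i in range(1, len(curve.times)):
        area += float(curve.survival[i - 1]) * float(curve.times[i] - curve.times[i - 1])
    return area


def mortality_quantile(curve: SurvivalCurve, q: float) -> float | None:
    """Smallest observed death time t with S(t) <= 1 - q.

    Returns ``None`` (with a warning) when the curve never reaches the
    requested mortality level.
    """
    if not (0 < q < 1):
        raise ValueError("q must be in (0, 1)")
    target = 1.0 - q
    for t, s in zip(curve.times, curve.survival):
        if s <= target + 1e-12:
            return float(t)
    log.warning("curve never reaches %.0f%% mortality; quantile undefined", 100 * q)
    return None


def records_to_frame(records: list[SurvivalRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "animal_id": [r.animal_id for r in records],
            "regime_id": [r.regime_id for r in records],
            "day": [r.day for r in records],
            "status": [r.status for r in records],
        }
    )


def curve_to_frame(curve: SurvivalCurve, regime_id: str | None = None) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "time": curve.times,
            "survival": curve.survival,
            "at_risk": curve.at_risk,
            "deaths": curve.deaths,
        }
    )
    if regime_id is not None:
        df.insert(0, "regime_id", regime_id)
    return df
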