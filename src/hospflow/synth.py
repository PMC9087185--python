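"""Synthetic monthly visit series and the 2019 resource table.

The generator integrates the three-tier system and samples it the way
China's national health statistics report outpatient volumes: months
January through November of each calendar year, with no December
report.  Observation noise is multiplicative Gaussian — the three
tiers differ in scale by roughly an order of magnitude, so relative
noise is the natural error model — and an optional 12-month sinusoid
emulates the seasonal swing present in the real series but absent
from the model, so estimator robustness to unmodelled seasonality can
be tested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import REFERENCE_PARAMS, ModelParams, VisitState
from .simulate import integrate
from .fitting import ObservedSeries, TIERS

__all__ = [
    "GeneratorConfig",
    "generate_series",
    "table1_fixture",
    "TABLE1_2019",
    "DEFAULT_INITIAL_2011",
]

#: Starting state for the default generated series: monthly visit
#: volumes (units of 10,000) at the rough scale of the Chinese
#: three-tier system early in the 2011–2018 observation window, below
#: the long-run attractor of the reference parameters so the series
#: shows growth toward it.
DEFAULT_INITIAL_2011 = VisitState(1500.0, 8000.0, 12000.0)


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of the synthetic series generator.

    ``noise_sd`` is the relative standard deviation of multiplicative
    Gaussian observation noise; ``seasonal_amp`` the relative
    amplitude of a 12-month sinusoidal factor (phase fixed at zero).
    The defaults mirror the reference study window: eight years of
    January–November observations with a few percent of observation
    noise.
    """

    params: ModelParams = REFERENCE_PARAMS
    initial: VisitState = DEFAULT_INITIAL_2011
    years: int = 8
    noise_sd: float = 0.02
    seasonal_amp: float = 0.0
    seed: int = 0
    start_year: int = 2011

    def __post_init__(self) -> None:
        if self.years < 1:
            raise ValueError("years must be >= 1")
        if self.noise_sd < 0 or self.seasonal_amp < 0:
            raise ValueError("noise_sd and seasonal_amp must be >= 0")


def generate_series(config: GeneratorConfig) -> ObservedSeries:
    """Generate a monthly three-tier series with the reporting gaps.

    The system is integrated continuously over ``years * 12`` months
    from the initial state; observations are taken at months 1–11 of
    each year (December is simulated but not reported).  Each
    observation is scaled by ``(1 + seasonal_amp * sin(2 pi month/12))``
    and ``(1 + N(0, noise_sd^2))``, then truncated at zero.
    Deterministic given the seed.
    """
    cfg = config
    years_idx = np.repeat(np.arange(cfg.years), 11)
    months = np.tile(np.arange(1, 12), cfg.years)
    t_obs = 12.0 * years_idx + (months - 1)

    if cfg.noise_sd == 0.0 and cfg.seasonal_amp == 0.0:
        states = integrate(cfg.params, cfg.initial, t_obs).states
        counts = states
    else:
        states = integrate(cfg.params, cfg.initial, t_obs).states
        rng = np.random.default_rng(cfg.seed)
        seasonal = 1.0 + cfg.seasonal_amp * np.sin(2.0 * np.pi * months / 12.0)
        noise = 1.0 + rng.normal(0.0, cfg.noise_sd, size=states.shape)
        counts = np.maximum(states * seasonal[:, None] * noise, 0.0)

    return ObservedSeries(
        times=t_obs,
        counts=counts,
        years=cfg.start_year + years_idx,
        months=months,
    )


#: Medical resources and services of Chinese hospitals in 2019, by
#: tier: number of hospitals, certified doctors, beds, and annual
#: visits in units of 10,000.
TABLE1_2019: dict[str, dict[str, int]] = {
    "FLH": {"hospitals": 11_264, "doctors": 135_471, "beds": 651_045, "visits_10k": 22_965},
    "SLH": {"hospitals": 9_687, "doctors": 720_121, "beds": 2_665_974, "visits_10k": 134_343},
    "TLH": {"hospitals": 2_749, "doctors": 1_030_988, "beds": 2_777_932, "visits_10k": 205_701},
}


def table1_fixture(include_total: bool = True) -> pd.DataFrame:
    """The 2019 tier-level resource table as a DataFrame.

    Rows are the three tiers (plus a ``Total`` row by default);
    columns are hospital counts, certified doctors, beds and annual
    visits (10,000s).
    """
    df = pd.DataFrame.from_dict(TABLE1_2019, orient="index")
    df.index.name = "tier"
    if include_total:
        df.loc["Total"] = df.loc[list(TIERS)].sum()
    return df
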