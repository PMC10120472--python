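"""The canonical synthetic study design.

One place defines the conditions every driver, test, and reproduction run
shares: the synthetic city, the baseline Social-EPR behavior, a monthly
policy-stringency ramp for the pandemic year, and the mapping from
stringency to the three behavioral perturbations (activity cuts by income
quantile, distance-preference sharpening, reduced social exploration, and
subcategory preference shifts). Ground truth for every recovery test lives
here.
"""

from __future__ import annotations

import pandas as pd

from .synth import EprParams, ScenarioConfig, WorldConfig, days_in_month, generate_world, simulate_period

#: baseline Social-EPR behavior of the synthetic population
BASE_EPR = EprParams(rho=0.6, gamma=0.21, sigma_s=0.40, event_rate_per_quantile=(2.5, 2.5, 2.5, 2.5), beta=1.5)

#: monthly stringency index (0-100) of the synthetic pandemic year: a sharp
#: spring-2020 lockdown relaxing through autumn
STRINGENCY_BY_MONTH = {
    "2020-03": 65.0,
    "2020-04": 85.0,
    "2020-05": 72.0,
    "2020-06": 60.0,
    "2020-07": 48.0,
    "2020-08": 40.0,
    "2020-09": 34.0,
    "2020-10": 28.0,
}

#: subcategory preference shifts during the pandemic (routine/essential up,
#: social/discretionary down), scaled by stringency below
_PANDEMIC_SUBCAT_SHIFT = {
    "Grocery Store": 1.6,
    "Big Box Store": 1.5,
    "Hardware Store": 1.5,
    "Fast Food": 1.3,
    "Donut Shop": 1.2,
    "Gym": 0.45,
    "Movie Theater": 0.35,
    "American Restaurant": 0.6,
    "Art Museum": 0.5,
    "Coffee Shop": 0.7,
}


def default_world_config(seed: int, n_users: int = 800, n_pois: int = 1500, n_cbgs: int = 120) -> WorldConfig:
    return WorldConfig(n_users=n_users, n_pois=n_pois, n_cbgs=n_cbgs, seed=seed)


def pandemic_scenario(period_label: str, stringency: float, base: EprParams = BASE_EPR) -> ScenarioConfig:
    """Map a stringency level to the three behavioral perturbations.

    At SI = 85 (the lockdown peak) activity drops to ~71% (q1) .. ~65% (q4)
    of baseline — higher-income quantiles cut back more — social exploration
    falls to ~49% of its baseline value, and trips concentrate near home.
    """
    s = stringency / 100.0
    mult = tuple(1.0 - (0.25 + 0.04 * qk) * s for qk in range(1, 5))
    shift = {k: 1.0 + (w - 1.0) * s for k, w in _PANDEMIC_SUBCAT_SHIFT.items()}
    return ScenarioConfig(
        period_label=period_label,
        activity_multiplier_per_quantile=mult,
        distance_shrink_factor=1.0 - 0.40 * s,
        sigma_s_override=base.sigma_s * (1.0 - 0.60 * s),
        subcategory_preference_shift=shift,
    )


def simulate_study(seed: int, world=None, months=None, n_users: int = 800) -> tuple:
    """Simulate the full study panel: 2019 baseline + 2020 pandemic months.

    Returns ``(world, stays_by_period)`` where periods cover the 2019
    calendar months matching each pandemic month (for deseasonalized
    baselines) and the stringency-ramp months of 2020.
    """
    if world is None:
        world = generate_world(default_world_config(seed, n_users=n_users))
    months = list(months or STRINGENCY_BY_MONTH)
    stays = {}
    for i, label in enumerate(months):
        y, m = label.split("-")
        base_label = f"2019-{m}"
        stays[base_label] = simulate_period(
            world, BASE_EPR, ScenarioConfig.baseline(base_label), days_in_month(base_label), seed + 1000 + i
        )
        stays[label] = simulate_period(
            world,
            BASE_EPR,
            pandemic_scenario(label, STRINGENCY_BY_MONTH[label]),
            days_in_month(label),
            seed + 2000 + i,
        )
    return world, stays


def stringency_series() -> pd.Series:
    return pd.Series(STRINGENCY_BY_MONTH, name="si")
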