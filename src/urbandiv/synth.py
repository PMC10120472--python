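"""Synthetic city and Social-EPR visit-panel generator.

Generates a self-contained synthetic metropolitan area — census block groups
(CBGs) with lognormal median incomes, points of interest (POIs) with a fixed
major-category/subcategory vocabulary, and users with home CBGs — and then
simulates multi-period stay panels from a social exploration and preferential
return (Social-EPR) process. Every downstream analysis stage (filtering,
diversity metrics, counterfactual downsampling, behavioral estimation,
area-level regression) can therefore be exercised against known ground truth.

The generative mechanics per user and visit event:

* events arrive as a homogeneous Poisson process at a per-income-quantile
  daily rate, modulated by a scenario's activity multiplier;
* at each event the user *explores* with probability ``rho * S**(-gamma)``
  (``S`` = number of distinct POIs visited so far; exploration is forced at
  ``S = 0``), otherwise *returns* to a known POI with probability
  proportional to its past visit count;
* an exploration is *social* with probability ``sigma_s``: the new POI is
  drawn from POIs whose dominant income quantile differs from the user's
  own, otherwise from same-quantile POIs; within the chosen pool POIs are
  weighted by a power-law kernel of home-to-POI distance and by scenario
  subcategory preference weights;
* dwell time is lognormal, truncated to (10, 240) minutes so synthetic
  stays pass the ingest filters unchanged.

Pandemic "scenarios" perturb the baseline behavior along the three axes the
analysis later tries to recover: per-quantile activity reduction, shorter
trips (distance-preference sharpening), and reduced social exploration plus
subcategory preference shifts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._geo import haversine_km, offset_to_lonlat

logger = logging.getLogger(__name__)

#: Major category -> subcategories. The majors mirror the vocabulary used in
#: the category-level diversity breakdown (grocery, museums, leisure,
#: transportation, coffee, ...); subcategories give the popularity analysis
#: something to rank.
CATEGORY_VOCABULARY: dict[str, list[str]] = {
    "Grocery": ["Grocery Store", "Supermarket", "Big Box Store"],
    "Food": ["American Restaurant", "Fast Food", "Donut Shop", "Pizza Place"],
    "Coffee": ["Coffee Shop", "Cafe"],
    "Leisure": ["Gym", "Movie Theater", "Park"],
    "Museums": ["Art Museum", "Science Museum"],
    "Transportation": ["Bus Station", "Train Station"],
    "Shops": ["Hardware Store", "Clothing Store", "Bookstore"],
    "Services": ["Bank", "Salon", "Pharmacy"],
}

_CATEGORY_WEIGHTS = {
    "Grocery": 0.15,
    "Food": 0.25,
    "Coffee": 0.11,
    "Leisure": 0.12,
    "Museums": 0.04,
    "Transportation": 0.06,
    "Shops": 0.15,
    "Services": 0.12,
}

_CITY_CENTER = (-71.06, 42.36)  # lon, lat of the synthetic downtown


@dataclass(frozen=True)
class WorldConfig:
    """Static configuration of the synthetic city."""

    n_users: int = 1000
    n_pois: int = 2000
    n_cbgs: int = 120
    city_radius_km: float = 20.0
    #: (mu, sigma) of log median household income in USD; the default gives a
    #: median around $60k with realistic inter-CBG spread.
    income_lognormal_params: tuple[float, float] = (11.0, 0.5)
    quantile_count: int = 4
    #: (mu, sigma) of log dwell minutes; median ~45 min before truncation.
    dwell_lognormal_params: tuple[float, float] = (math.log(45.0), 0.75)
    seed: int = 0

    def __post_init__(self):
        if min(self.n_users, self.n_pois, self.n_cbgs) <= 0:
            raise ValueError("all counts must be positive")
        if self.quantile_count < 2:
            raise ValueError("quantile_count must be >= 2")
        if self.city_radius_km <= 0:
            raise ValueError("city_radius_km must be positive")


@dataclass(frozen=True)
class EprParams:
    """Behavioral parameters of the Social-EPR process.

    ``rho`` and ``gamma`` set the exploration probability ``rho * S**-gamma``;
    ``sigma_s`` is the social-exploration probability (new place whose
    dominant income quantile differs from the visitor's); ``beta`` is the
    exponent of the home-to-POI distance kernel ``d**-beta``.
    """

    rho: float = 0.6
    gamma: float = 0.21
    sigma_s: float = 0.40
    event_rate_per_quantile: tuple[float, ...] = (2.5, 2.5, 2.5, 2.5)
    beta: float = 1.5

    def __post_init__(self):
        if not (0.0 < self.rho <= 1.0):
            raise ValueError("rho must be in (0, 1]")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if not (0.0 <= self.sigma_s <= 1.0):
            raise ValueError("sigma_s must be in [0, 1]")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if any(r <= 0 for r in self.event_rate_per_quantile):
            raise ValueError("event rates must be positive")


@dataclass(frozen=True)
class ScenarioConfig:
    """Behavioral perturbation of one simulated period.

    ``period_label`` is ``"YYYY-MM"``; events are spread uniformly over the
    simulated days starting on the first of that month.
    """

    period_label: str
    activity_multiplier_per_quantile: tuple[float, ...] | None = None
    distance_shrink_factor: float = 1.0
    sigma_s_override: float | None = None
    subcategory_preference_shift: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.activity_multiplier_per_quantile is not None and any(
            m <= 0 for m in self.activity_multiplier_per_quantile
        ):
            raise ValueError("activity multipliers must be positive")
        if not (0.0 < self.distance_shrink_factor <= 1.0):
            raise ValueError("distance_shrink_factor must be in (0, 1]")
        if self.sigma_s_override is not None and not (0.0 <= self.sigma_s_override <= 1.0):
            raise ValueError("sigma_s_override must be in [0, 1]")
        if any(w <= 0 for w in self.subcategory_preference_shift.values()):
            raise ValueError("subcategory preference weights must be positive")

    @classmethod
    def baseline(cls, period_label: str) -> "ScenarioConfig":
        return cls(period_label=period_label)


def rank_quantiles(values, q: int) -> np.ndarray:
    """Equal-count quantile labels 1..q from ranked values, ties sharing a label.

    Ties receive the label implied by their average rank, so a block of equal
    values never straddles a quantile boundary; group sizes are equal up to
    the size of boundary tie groups.
    """
    s = pd.Series(np.asarray(values, dtype=float))
    ranks = s.rank(method="average").to_numpy()
    labels = np.ceil(ranks * q / len(s)).astype(int)
    return np.clip(labels, 1, q)


def generate_world(config: WorldConfig):
    """Generate (cbg_table, poi_table, user_table) for the synthetic city.

    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    q_count = config.quantile_count
    lon0, lat0 = _CITY_CENTER

    # --- CBGs: centroids uniform in the city disc, lognormal incomes ---
    r = config.city_radius_km * np.sqrt(rng.random(config.n_cbgs))
    theta = rng.uniform(0.0, 2.0 * np.pi, config.n_cbgs)
    lon, lat = offset_to_lonlat(lon0, lat0, r * np.cos(theta), r * np.sin(theta))
    mu, sigma = config.income_lognormal_params
    income = rng.lognormal(mu, sigma, config.n_cbgs)
    if np.unique(income).size < q_count:
        raise ValueError("cannot form Q nonempty quantiles")
    n_pumas = max(2, config.n_cbgs // 30)
    puma = (theta / (2.0 * np.pi) * n_pumas).astype(int) % n_pumas
    cbg_table = pd.DataFrame(
        {
            "cbg_id": [f"C{i:05d}" for i in range(config.n_cbgs)],
            "lon": lon,
            "lat": lat,
            "median_income": income,
            "income_quantile": rank_quantiles(income, q_count),
            "puma_id": [f"P{p:03d}" for p in puma],
            "cbsa_id": "SYN",
        }
    )

    # --- POIs: scattered around CBG centroids, categorized ---
    cats = list(_CATEGORY_WEIGHTS)
    cat_p = np.array([_CATEGORY_WEIGHTS[c] for c in cats])
    cat_p = cat_p / cat_p.sum()
    poi_cbg = rng.integers(0, config.n_cbgs, config.n_pois)
    jitter = rng.normal(0.0, 0.4, size=(config.n_pois, 2))  # km around the centroid
    base_x = r[poi_cbg] * np.cos(theta[poi_cbg]) + jitter[:, 0]
    base_y = r[poi_cbg] * np.sin(theta[poi_cbg]) + jitter[:, 1]
    poi_lon, poi_lat = offset_to_lonlat(lon0, lat0, base_x, base_y)
    cat_idx = rng.choice(len(cats), size=config.n_pois, p=cat_p)
    category = [cats[i] for i in cat_idx]
    subcategory = [
        CATEGORY_VOCABULARY[c][k]
        for c, k in zip(category, (rng.random(config.n_pois) * [len(CATEGORY_VOCABULARY[c]) for c in category]).astype(int))
    ]
    poi_table = pd.DataFrame(
        {
            "poi_id": [f"V{i:06d}" for i in range(config.n_pois)],
            "lon": poi_lon,
            "lat": poi_lat,
            "category": category,
            "subcategory": subcategory,
            "cbg_id": cbg_table["cbg_id"].to_numpy()[poi_cbg],
            "dominant_quantile": cbg_table["income_quantile"].to_numpy()[poi_cbg],
        }
    )

    # --- Users: random home CBGs; quantile from home-CBG income rank ---
    home_idx = rng.integers(0, config.n_cbgs, config.n_users)
    user_table = pd.DataFrame(
        {
            "user_id": [f"U{i:05d}" for i in range(config.n_users)],
            "home_cbg": cbg_table["cbg_id"].to_numpy()[home_idx],
            "income_quantile": rank_quantiles(income[home_idx], q_count),
            "weight": 1.0,
        }
    )
    return cbg_table, poi_table, user_table


def _period_start(period_label: str) -> pd.Timestamp:
    return pd.Timestamp(f"{period_label}-01", tz="UTC")


def days_in_month(period_label: str) -> int:
    return _period_start(period_label).days_in_month


def _truncated_lognormal(rng, mu, sigma, n, lo=10.0, hi=240.0):
    """Rejection-sample lognormal values into the open interval (lo, hi)."""
    out = rng.lognormal(mu, sigma, n)
    bad = (out <= lo) | (out >= hi)
    while bad.any():
        out[bad] = rng.lognormal(mu, sigma, int(bad.sum()))
        bad = (out <= lo) | (out >= hi)
    return out


class _Pool:
    """A candidate POI pool with fixed weights, sampled by inverse CDF."""

    __slots__ = ("ids", "cum", "total")

    def __init__(self, ids: np.ndarray, weights: np.ndarray):
        self.ids = ids
        self.cum = np.cumsum(weights)
        self.total = float(self.cum[-1]) if len(ids) else 0.0

    def draw_new(self, rng, visited: set, max_tries: int = 40):
        if self.total <= 0.0:
            return None
        for _ in range(max_tries):
            j = int(np.searchsorted(self.cum, rng.random() * self.total))
            poi = int(self.ids[min(j, len(self.ids) - 1)])
            if poi not in visited:
                return poi
        # pool nearly exhausted for this user: scan for any unvisited member
        for poi in self.ids:
            if int(poi) not in visited:
                return int(poi)
        return None


def simulate_period(
    world,
    epr: EprParams,
    scenario: ScenarioConfig,
    n_days: int,
    seed: int,
    dwell_lognormal_params: tuple[float, float] = WorldConfig.dwell_lognormal_params,
) -> pd.DataFrame:
    """Simulate one period's stay table from the Social-EPR process.

    Returns a DataFrame with columns ``user_id, t_start, dwell_min, poi_id,
    lon, lat`` sorted by user then time. Per-user randomness comes from
    substreams spawned off ``seed`` keyed by user index, so a user's
    trajectory is reproducible independently of user ordering.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    cbg_table, poi_table, user_table = world
    q_count = int(poi_table["dominant_quantile"].max())
    if len(epr.event_rate_per_quantile) != q_count:
        raise ValueError("event_rate_per_quantile length must equal the quantile count")

    mult = scenario.activity_multiplier_per_quantile or (1.0,) * q_count
    sigma_s = epr.sigma_s if scenario.sigma_s_override is None else scenario.sigma_s_override
    beta_eff = epr.beta / scenario.distance_shrink_factor

    poi_lon = poi_table["lon"].to_numpy()
    poi_lat = poi_table["lat"].to_numpy()
    poi_q = poi_table["dominant_quantile"].to_numpy()
    sub_w = np.array(
        [scenario.subcategory_preference_shift.get(s, 1.0) for s in poi_table["subcategory"]]
    )
    cbg_lon = dict(zip(cbg_table["cbg_id"], cbg_table["lon"]))
    cbg_lat = dict(zip(cbg_table["cbg_id"], cbg_table["lat"]))
    q_masks = {q: poi_q == q for q in range(1, q_count + 1)}

    # Distance kernels are shared by all users of a home CBG; cache pools per
    # (home CBG, user quantile, social?) key.
    pool_cache: dict[tuple, _Pool] = {}
    kernel_cache: dict[str, np.ndarray] = {}

    def pools_for(home: str, uq: int) -> tuple[_Pool, _Pool]:
        key = (home, uq)
        if key not in pool_cache:
            if home not in kernel_cache:
                d = haversine_km(cbg_lon[home], cbg_lat[home], poi_lon, poi_lat)
                kernel_cache[home] = (d + 0.05) ** (-beta_eff) * sub_w
            w = kernel_cache[home]
            same = q_masks[uq]
            pool_cache[key] = (_Pool(np.flatnonzero(same), w[same]), _Pool(np.flatnonzero(~same), w[~same]))
        return pool_cache[key]

    start = _period_start(scenario.period_label)
    fallback_warned = False

    users = user_table["user_id"].to_numpy()
    homes = user_table["home_cbg"].to_numpy()
    uqs = user_table["income_quantile"].to_numpy()

    mu_d, sigma_d = dwell_lognormal_params
    out_user, out_poi, out_t, out_dwell = [], [], [], []
    for ui in range(len(users)):
        uq = int(uqs[ui])
        rng = np.random.default_rng(np.random.SeedSequence([seed, ui]))
        rate = epr.event_rate_per_quantile[uq - 1]
        n_events = int(rng.poisson(rate * n_days))
        if n_events == 0:
            continue
        same_pool, other_pool = pools_for(homes[ui], uq)
        u_explore = rng.random(n_events)
        u_social = rng.random(n_events)
        u_pick = rng.random(n_events)
        dwell = _truncated_lognormal(rng, mu_d, sigma_d, n_events)
        t_offsets = np.sort(rng.random(n_events)) * n_days

        history: list[int] = []
        visited: set[int] = set()
        s_count = 0
        pois = np.empty(n_events, dtype=np.int64)
        for k in range(n_events):
            explore = s_count == 0 or u_explore[k] < epr.rho * s_count ** (-epr.gamma)
            poi = None
            if explore:
                first = other_pool if u_social[k] < sigma_s else same_pool
                second = same_pool if first is other_pool else other_pool
                poi = first.draw_new(rng, visited)
                if poi is None:
                    if not fallback_warned and first.total > 0.0:
                        logger.warning(
                            "empty candidate POI subset during exploration; "
                            "falling back to the complementary subset"
                        )
                        fallback_warned = True
                    poi = second.draw_new(rng, visited)
                if poi is not None:
                    visited.add(poi)
                    s_count += 1
            if poi is None:
                # preferential return: uniform over past visit events is
                # equivalent to sampling a POI with prob proportional to its
                # past visit count
                poi = history[int(u_pick[k] * len(history))]
            history.append(poi)
            pois[k] = poi

        # Activity reduction thins realized visits from the unchanged latent
        # routine (a thinned Poisson process is a Poisson process at the
        # reduced rate), so a multiplier-only scenario changes how often
        # people go out without also perturbing their exploration behavior.
        m = mult[uq - 1]
        if m < 1.0:
            keep = rng.random(n_events) < m
            if not keep.any():
                continue
            pois, t_offsets, dwell = pois[keep], t_offsets[keep], dwell[keep]
            n_events = int(keep.sum())
        out_user.append(np.repeat(users[ui], n_events))
        out_poi.append(pois)
        out_t.append(t_offsets)
        out_dwell.append(dwell)

    if not out_user:
        return pd.DataFrame(columns=["user_id", "t_start", "dwell_min", "poi_id", "lon", "lat"])
    poi_idx = np.concatenate(out_poi)
    stays = pd.DataFrame(
        {
            "user_id": np.concatenate(out_user),
            "t_start": start + pd.to_timedelta(np.concatenate(out_t), unit="D"),
            "dwell_min": np.concatenate(out_dwell),
            "poi_id": poi_table["poi_id"].to_numpy()[poi_idx],
            "lon": poi_lon[poi_idx],
            "lat": poi_lat[poi_idx],
        }
    )
    return stays.reset_index(drop=True)


def seasonal_multiplier(period_label: str, amplitude: float = 0.0) -> float:
    """Sinusoidal month-of-year activity modulation (peak in June)."""
    month = int(period_label.split("-")[1])
    return 1.0 + amplitude * math.sin(2.0 * math.pi * (month - 3) / 12.0)


# ---------------------------------------------------------------------------
# fixture I/O


def _geojson_points(df: pd.DataFrame, id_col: str, props: list[str]) -> dict:
    feats = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        feats.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [d["lon"], d["lat"]]},
                "properties": {c: d[c] for c in [id_col] + props},
            }
        )
    return {"type": "FeatureCollection", "features": feats}


def write_fixtures(world, stays_by_period: dict[str, pd.DataFrame], out_dir, config: WorldConfig | None = None):
    """Write the synthetic tables to ``out_dir``.

    Stay tables go out as both CSV (ISO-8601 UTC timestamps) and Parquet;
    POI and CBG centroids as GeoJSON; users as CSV; the world config is
    echoed as YAML for provenance.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cbg_table, poi_table, user_table = world[:3]
    cbg_table.to_csv(out / "cbgs.csv", index=False)
    user_table.to_csv(out / "users.csv", index=False)
    poi_table.to_csv(out / "pois.csv", index=False)
    with open(out / "pois.geojson", "w") as f:
        json.dump(_geojson_points(poi_table, "poi_id", ["category", "subcategory", "cbg_id", "dominant_quantile"]), f)
    with open(out / "cbgs.geojson", "w") as f:
        json.dump(_geojson_points(cbg_table, "cbg_id", ["median_income", "puma_id", "cbsa_id"]), f)
    for label, stays in stays_by_period.items():
        s = stays.copy()
        s["t_start"] = s["t_start"].dt.strftime("%Y-%m-%dT%H:%M:%S.%f%z")
        s.to_csv(out / f"stays_{label}.csv", index=False)
        stays.to_parquet(out / f"stays_{label}.parquet", index=False)
    if config is not None:
        with open(out / "world_config.yaml", "w") as f:
            yaml.safe_dump(dataclasses.asdict(config), f)


def read_fixtures(out_dir):
    """Round-trip reader for :func:`write_fixtures` output."""
    out = Path(out_dir)
    cbg_table = pd.read_csv(out / "cbgs.csv")
    poi_table = pd.read_csv(out / "pois.csv")
    user_table = pd.read_csv(out / "users.csv")
    stays = {}
    for p in sorted(out.glob("stays_*.parquet")):
        label = p.stem.replace("stays_", "")
        stays[label] = pd.read_parquet(p)
    return (cbg_table, poi_table, user_table), stays
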