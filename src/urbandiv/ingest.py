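"""Stay filtering, POI attribution, SES quantile assignment, and windowing.

Reproduces the preprocessing contract of the encounter-diversity analysis:
stays strictly between 10 minutes and 4 hours, user-days with more than
300 observed minutes, nearest-POI attribution within a 100 m great-circle
radius, equal-count income quantiles from home-CBG median household income,
and 2-month moving analysis windows labelled by their last month.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import BallTree

from ._geo import EARTH_RADIUS_KM, haversine_km
from .synth import rank_quantiles

logger = logging.getLogger(__name__)

DWELL_MIN_MINUTES = 10.0
DWELL_MAX_MINUTES = 240.0
ATTRIBUTION_RADIUS_M = 100.0
MIN_DAILY_OBSERVED_MIN = 300.0


def filter_stays(stays: pd.DataFrame) -> pd.DataFrame:
    """Keep stays with dwell strictly between 10 and 240 minutes."""
    keep = (stays["dwell_min"] > DWELL_MIN_MINUTES) & (stays["dwell_min"] < DWELL_MAX_MINUTES)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("filter_stays dropped %d of %d stays", dropped, len(stays))
    return stays.loc[keep].copy()


def filter_users_by_observation(
    stays: pd.DataFrame,
    ping_log: pd.DataFrame | None = None,
    min_daily_min: float = MIN_DAILY_OBSERVED_MIN,
    strict: bool = False,
) -> pd.DataFrame:
    """Keep stays on user-days observed for more than ``min_daily_min`` minutes.

    ``ping_log`` carries columns ``user_id, date, observed_min``. Synthetic
    panels have no observation gaps, so a missing ping log keeps every
    user-day (with a warning) unless ``strict`` is set.
    """
    if ping_log is None:
        if strict:
            raise ValueError("observation filter requires a ping log in strict mode")
        logger.warning("no ping log supplied; assuming complete observation for all user-days")
        return stays.copy()
    ok = ping_log.loc[ping_log["observed_min"] > min_daily_min, ["user_id", "date"]]
    dates = stays["t_start"].dt.date.astype(str)
    key = pd.MultiIndex.from_arrays([stays["user_id"], dates])
    keep_set = pd.MultiIndex.from_frame(ok.astype({"date": str}))
    return stays.loc[key.isin(keep_set)].copy()


def attribute_pois(
    stays: pd.DataFrame,
    poi_table: pd.DataFrame,
    radius_m: float = ATTRIBUTION_RADIUS_M,
) -> pd.DataFrame:
    """Attribute each stay to the nearest POI within ``radius_m`` (great circle).

    Adds ``poi_id``, ``match_distance_m`` and ``matched`` columns; unmatched
    stays keep ``poi_id = NA`` and are meant to be excluded from diversity
    computations (but retained for total-dwell accounting). Distance ties are
    broken toward the smallest ``poi_id``.
    """
    if len(poi_table) == 0:
        raise ValueError("empty POI table")
    pois = poi_table.sort_values("poi_id").reset_index(drop=True)
    tree = BallTree(np.radians(pois[["lat", "lon"]].to_numpy()), metric="haversine")
    k = min(4, len(pois))
    dist, idx = tree.query(np.radians(stays[["lat", "lon"]].to_numpy()), k=k)
    dist_m = dist * EARTH_RADIUS_KM * 1000.0

    # tie-break: among candidates within float tolerance of the minimum
    # distance, take the smallest poi_id (pois are sorted by id, so the
    # smallest index among tied candidates wins)
    best = idx[:, 0].copy()
    if k > 1:
        has_tie = np.flatnonzero(dist_m[:, 1] <= dist_m[:, 0] + 1e-6)
        for i in has_tie:
            tied = idx[i][dist_m[i] <= dist_m[i, 0] + 1e-6]
            best[i] = tied.min()
    matched = dist_m[:, 0] <= radius_m
    out = stays.copy()
    out["poi_id"] = pois["poi_id"].to_numpy()[best]
    out.loc[~matched, "poi_id"] = pd.NA
    out["match_distance_m"] = dist_m[:, 0]
    out["matched"] = matched
    if (~matched).any():
        logger.info("attribute_pois left %d of %d stays unmatched", int((~matched).sum()), len(stays))
    return out


def assign_quantiles(
    user_table: pd.DataFrame,
    cbg_income_table: pd.DataFrame,
    q: int = 4,
    group_col: str | None = "cbsa_id",
) -> pd.DataFrame:
    """Assign equal-count income quantiles from home-CBG median income.

    Quantile thresholds are taken separately within each ``group_col`` city
    (CBSA) when that column is available, since income distributions differ
    across cities. Users whose home CBG lacks an income are excluded with a
    warning. Returns a profile table ``user_id, home_cbg, income_quantile,
    weight``.
    """
    cols = ["cbg_id", "median_income"] + ([group_col] if group_col and group_col in cbg_income_table else [])
    merged = user_table.merge(
        cbg_income_table[cols], left_on="home_cbg", right_on="cbg_id", how="left"
    )
    missing = merged["median_income"].isna()
    if missing.any():
        logger.warning("excluding %d users whose home CBG has no median income", int(missing.sum()))
        merged = merged.loc[~missing]
    if group_col and group_col in merged:
        quant = merged.groupby(group_col, group_keys=False)["median_income"].transform(
            lambda s: rank_quantiles(s.to_numpy(), q)
        )
    else:
        quant = pd.Series(rank_quantiles(merged["median_income"].to_numpy(), q), index=merged.index)
    out = pd.DataFrame(
        {
            "user_id": merged["user_id"],
            "home_cbg": merged["home_cbg"],
            "income_quantile": quant.astype(int),
            "weight": merged["weight"] if "weight" in merged else 1.0,
        }
    )
    return out.reset_index(drop=True)


@dataclass(frozen=True)
class AnalysisWindow:
    """A 2-month moving window labelled by its last month.

    Window ``"2020-04"`` spans 2020-03-01 (inclusive) to 2020-05-01
    (exclusive); consecutive windows overlap by one month.
    """

    label: str

    @property
    def start(self) -> pd.Timestamp:
        return pd.Timestamp(f"{self.label}-01", tz="UTC") - pd.DateOffset(months=1)

    @property
    def end(self) -> pd.Timestamp:
        return pd.Timestamp(f"{self.label}-01", tz="UTC") + pd.DateOffset(months=1)

    def contains(self, t: pd.Series) -> pd.Series:
        return (t >= self.start) & (t < self.end)


def make_windows(labels) -> list[AnalysisWindow]:
    labels = list(labels)
    if len(set(labels)) != len(labels):
        raise ValueError("window labels must be unique")
    return [AnalysisWindow(l) for l in labels]


def window_assign(stays: pd.DataFrame, windows) -> pd.DataFrame:
    """Key stays by analysis window; a stay lands in every window containing it."""
    parts = []
    for w in windows:
        part = stays.loc[w.contains(stays["t_start"])].copy()
        part["window"] = w.label
        parts.append(part)
    if not parts:
        return stays.iloc[0:0].assign(window=pd.Series(dtype=str))
    return pd.concat(parts, ignore_index=True)


def add_home_distance(
    visits: pd.DataFrame,
    profiles: pd.DataFrame,
    cbg_table: pd.DataFrame,
    poi_table: pd.DataFrame,
) -> pd.DataFrame:
    """Add ``distance_from_home_km``: home-CBG centroid to visited POI."""
    out = visits.merge(profiles[["user_id", "home_cbg"]], on="user_id", how="left")
    out = out.merge(
        cbg_table[["cbg_id", "lon", "lat"]].rename(
            columns={"cbg_id": "home_cbg", "lon": "home_lon", "lat": "home_lat"}
        ),
        on="home_cbg",
        how="left",
    )
    out = out.merge(
        poi_table[["poi_id", "lon", "lat"]].rename(columns={"lon": "poi_lon", "lat": "poi_lat"}),
        on="poi_id",
        how="left",
    )
    out["distance_from_home_km"] = haversine_km(
        out["home_lon"], out["home_lat"], out["poi_lon"], out["poi_lat"]
    )
    return out.drop(columns=["home_lon", "home_lat", "poi_lon", "poi_lat"])
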