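"""Exposure vectors, encounter-diversity statistics, and mobility metrics.

The central objects are *exposure vectors* τ over Q income quantiles:

* place exposure τ_qα — the share of total (post-stratification-weighted)
  dwell time at place α contributed by quantile q;
* individual exposure τ_iq = Σ_α τ_iα τ_qα — individual i's relative
  exposure to quantile q, the place exposures convolved with i's own time
  shares τ_iα.

Diversity is the *evenness* of an exposure vector,

    D = 1 − Q/(2(Q−1)) · Σ_q |τ_q − 1/Q|,

which is 1 when all quantiles contribute equally and 0 when a single
quantile contributes everything; at the default Q = 4 the normalization is
the familiar 2/3. A normalized Shannon-entropy variant is provided as a
robustness alternative. Period-over-baseline changes are reported as
ΔD(t) = 100% · (D̄(t) − D̄(2019, same month)) / D̄(2019, same month), which
doubles as the deseasonalization convention.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._geo import haversine_km

#: minimum support for a place's diversity to be reported
MIN_SUPPORT_USERS = 2
MIN_SUPPORT_DWELL_MIN = 30.0

_SUM_TOL = 1e-6


def _tau_cols(q: int) -> list[str]:
    return [f"tau_{k}" for k in range(1, q + 1)]


def place_exposure(
    visits: pd.DataFrame,
    profiles: pd.DataFrame,
    q: int = 4,
    min_users: int = MIN_SUPPORT_USERS,
    min_dwell_min: float = MIN_SUPPORT_DWELL_MIN,
) -> pd.DataFrame:
    """Compute τ_qα per place from attributed, windowed visits.

    Returns a frame indexed by ``poi_id`` with columns ``tau_1..tau_Q``,
    ``support_dwell_min``, ``support_visits``, ``support_users`` and a
    ``qualifies`` flag for the minimum-support rule. Places with zero dwell
    are simply absent.
    """
    v = visits.drop(columns=["income_quantile", "weight"], errors="ignore").merge(
        profiles[["user_id", "income_quantile", "weight"]], on="user_id", how="inner"
    )
    v["wdwell"] = v["dwell_min"] * v["weight"]
    pivot = v.pivot_table(index="poi_id", columns="income_quantile", values="wdwell", aggfunc="sum", fill_value=0.0)
    pivot = pivot.reindex(columns=range(1, q + 1), fill_value=0.0)
    total = pivot.sum(axis=1)
    tau = pivot.div(total, axis=0)
    tau.columns = _tau_cols(q)
    support = v.groupby("poi_id").agg(
        support_dwell_min=("dwell_min", "sum"),
        support_visits=("dwell_min", "size"),
        support_users=("user_id", "nunique"),
    )
    out = tau.join(support)
    out["qualifies"] = (out["support_users"] >= min_users) & (out["support_dwell_min"] >= min_dwell_min)
    return out


def _check_tau(tau: np.ndarray):
    if np.any(tau < -_SUM_TOL):
        raise ValueError("exposure shares must be nonnegative")
    sums = tau.sum(axis=-1)
    if np.any(np.abs(sums - 1.0) > _SUM_TOL):
        raise ValueError("exposure shares must sum to 1")


def evenness_diversity(tau, q: int | None = None) -> np.ndarray | float:
    """Evenness diversity D = 1 − Q/(2(Q−1)) Σ|τ_q − 1/Q|, clipped to [0, 1].

    ``tau`` is one exposure vector or an array of them (last axis = Q). At
    Q = 4 the normalization constant is 2/3; the general form maps the
    single-quantile vector to exactly 0 and the uniform vector to exactly 1.
    """
    arr = np.asarray(tau, dtype=float)
    scalar = arr.ndim == 1
    arr = np.atleast_2d(arr)
    q = q or arr.shape[-1]
    _check_tau(arr)
    # grouping (q * sum) / (2(q-1)) keeps the boundary cases exact in floats
    d = 1.0 - (q * np.abs(arr - 1.0 / q).sum(axis=-1)) / (2.0 * (q - 1.0))
    d = np.clip(d, 0.0, 1.0)
    return float(d[0]) if scalar else d


def entropy_diversity(tau, q: int | None = None) -> np.ndarray | float:
    """Normalized Shannon entropy −Σ τ ln τ / ln Q with 0·ln 0 = 0."""
    arr = np.asarray(tau, dtype=float)
    scalar = arr.ndim == 1
    arr = np.atleast_2d(arr)
    q = q or arr.shape[-1]
    _check_tau(arr)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(arr > 0.0, arr * np.log(arr), 0.0)
    d = np.clip(-terms.sum(axis=-1) / np.log(q), 0.0, 1.0)
    return float(d[0]) if scalar else d


_DIVERSITY = {"evenness": evenness_diversity, "entropy": entropy_diversity}


def place_diversity(exposures: pd.DataFrame, q: int = 4, metric: str = "evenness") -> pd.Series:
    """Diversity D_α per place from a :func:`place_exposure` table."""
    tau = exposures[_tau_cols(q)].to_numpy()
    return pd.Series(_DIVERSITY[metric](tau, q), index=exposures.index, name="D")


def time_shares(visits: pd.DataFrame) -> pd.DataFrame:
    """τ_iα: the share of individual i's dwell spent at place α."""
    g = visits.groupby(["user_id", "poi_id"], as_index=False)["dwell_min"].sum()
    g["share"] = g["dwell_min"] / g.groupby("user_id")["dwell_min"].transform("sum")
    return g[["user_id", "poi_id", "share"]]


def individual_exposure(shares: pd.DataFrame, exposures: pd.DataFrame, q: int = 4) -> pd.DataFrame:
    """τ_iq = Σ_α τ_iα τ_qα per individual.

    Individuals whose visited places all lack exposures are omitted; shares
    are renormalized over the places that do have exposures so that every
    returned vector sums to 1.
    """
    cols = _tau_cols(q)
    m = shares.merge(exposures[cols], left_on="poi_id", right_index=True, how="inner")
    if m.empty:
        return pd.DataFrame(columns=cols)
    for c in cols:
        m[c] = m[c] * m["share"]
    out = m.groupby("user_id")[cols].sum()
    out = out.div(out.sum(axis=1), axis=0)
    return out


def individual_diversity(
    visits: pd.DataFrame,
    profiles: pd.DataFrame,
    q: int = 4,
    metric: str = "evenness",
    min_users: int = MIN_SUPPORT_USERS,
    min_dwell_min: float = MIN_SUPPORT_DWELL_MIN,
) -> pd.DataFrame:
    """D_i per individual on one window: exposure convolution end to end.

    Place exposures use all places; the support flag only gates which places
    enter the reported place-level mean, not the individual convolution.
    Returns a frame indexed by user_id with τ_iq columns and ``D``.
    """
    expo = place_exposure(visits, profiles, q, min_users, min_dwell_min)
    tau_iq = individual_exposure(time_shares(visits), expo, q)
    tau_iq["D"] = _DIVERSITY[metric](tau_iq[_tau_cols(q)].to_numpy(), q)
    return tau_iq


def mean_place_diversity(visits, profiles, q: int = 4, metric: str = "evenness", **support) -> float:
    """Unweighted mean D̄_α over qualifying places."""
    expo = place_exposure(visits, profiles, q, **support)
    d = place_diversity(expo.loc[expo["qualifies"]], q, metric)
    return float(d.mean())


def mean_individual_diversity(visits, profiles, q: int = 4, metric: str = "evenness") -> float:
    """Unweighted mean D̄_i over individuals with matched visits."""
    return float(individual_diversity(visits, profiles, q, metric)["D"].mean())


def aggregate_cbg(d_i: pd.DataFrame, profiles: pd.DataFrame, min_residents: int = 1) -> pd.DataFrame:
    """D_CBG: unweighted mean of resident D_i per home CBG."""
    m = d_i[["D"]].merge(profiles[["user_id", "home_cbg"]], left_index=True, right_on="user_id")
    g = m.groupby("home_cbg").agg(D=("D", "mean"), n_residents=("user_id", "nunique"))
    g["qualifies"] = g["n_residents"] >= min_residents
    return g


def delta_percent(value, baseline):
    """ΔD(t) = 100% · (D̄(t) − D̄_baseline) / D̄_baseline."""
    baseline = np.asarray(baseline, dtype=float)
    if np.any(baseline == 0.0):
        raise ValueError("zero baseline mean")
    return (np.asarray(value, dtype=float) - baseline) / baseline * 100.0


def deseasonalize(series: pd.Series, baseline_by_month: dict[int, float] | pd.Series) -> pd.Series:
    """Divide each period's value by the same-calendar-month 2019 baseline.

    ``series`` is indexed by period labels ``"YYYY-MM"``; ``baseline_by_month``
    maps calendar month (1..12) to the 2019 mean for that month.
    """
    base = dict(baseline_by_month)
    months = [int(str(lbl).split("-")[1]) for lbl in series.index]
    missing = sorted({m for m in months if m not in base or base[m] == 0})
    if missing:
        raise ValueError(f"missing or zero baseline for months {missing}")
    return series / pd.Series([base[m] for m in months], index=series.index)


def mobility_metrics(
    visits: pd.DataFrame,
    profiles: pd.DataFrame | None = None,
    cbg_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-user mobility metrics on one window of attributed visits.

    ``visits_per_day`` and ``dwell_min_per_day`` divide by the number of
    distinct days on which the user has visits; ``radius_of_gyration_km`` is
    the visit-weighted RMS great-circle distance of visit locations from the
    visit-weighted centroid; ``mean_home_distance_km`` needs ``profiles``
    and ``cbg_table`` for home centroids.
    """
    v = visits.copy()
    v["date"] = v["t_start"].dt.date
    g = v.groupby("user_id")
    out = pd.DataFrame(
        {
            "n_visits": g.size(),
            "n_days": g["date"].nunique(),
            "total_dwell_min": g["dwell_min"].sum(),
            "mean_dwell_per_visit_min": g["dwell_min"].mean(),
            "n_unique_pois": g["poi_id"].nunique(),
        }
    )
    out["visits_per_day"] = out["n_visits"] / out["n_days"]
    out["dwell_min_per_day"] = out["total_dwell_min"] / out["n_days"]

    cen_lon = g["lon"].mean()
    cen_lat = g["lat"].mean()
    v = v.merge(cen_lon.rename("cen_lon"), left_on="user_id", right_index=True)
    v = v.merge(cen_lat.rename("cen_lat"), left_on="user_id", right_index=True)
    v["d2"] = haversine_km(v["lon"], v["lat"], v["cen_lon"], v["cen_lat"]) ** 2
    out["radius_of_gyration_km"] = np.sqrt(v.groupby("user_id")["d2"].mean())

    if profiles is not None and cbg_table is not None:
        hv = visits.merge(profiles[["user_id", "home_cbg"]], on="user_id")
        hv = hv.merge(
            cbg_table[["cbg_id", "lon", "lat"]].rename(
                columns={"cbg_id": "home_cbg", "lon": "hlon", "lat": "hlat"}
            ),
            on="home_cbg",
        )
        hv["hd"] = haversine_km(hv["lon"], hv["lat"], hv["hlon"], hv["hlat"])
        out["mean_home_distance_km"] = hv.groupby("user_id")["hd"].mean()
    return out
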