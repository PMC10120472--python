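"""Social-EPR behavioral parameter estimation from visit panels.

Three estimators drive the behavioral analysis:

* the exploration law: the probability that a visit is to a *new* place
  decays as ρS^(−γ) in the number S of distinct places already visited;
  ρ and γ are fit by count-weighted least squares on the log–log scale;
* social exploration σ_s: among explorations (first visits to a place),
  the fraction landing where the visitor's income quantile is not the
  place's majority quantile, with a binomial confidence interval;
* subcategory popularity f_r: the share of individuals whose top-r most
  frequently visited places include a given POI subcategory, and its
  change relative to the 2019 baseline.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.proportion import proportion_confint

logger = logging.getLogger(__name__)


def label_explorations(visits: pd.DataFrame) -> pd.DataFrame:
    """Flag each visit as exploration (first visit to its POI by its user).

    Visits are time-sorted per user within the estimation window; history
    before the window is unknown, so "new" means new within the window (an
    upper bound on true exploration). ``S_before`` is the user's distinct-POI
    count before the visit; it increments by exactly 1 on explorations.
    """
    v = visits.sort_values(["user_id", "t_start"], kind="mergesort").copy()
    v["is_exploration"] = ~v.duplicated(subset=["user_id", "poi_id"])
    v["S_before"] = v.groupby("user_id")["is_exploration"].cumsum() - v["is_exploration"]
    return v[["user_id", "t_start", "poi_id", "S_before", "is_exploration"]]


def fit_exploration_law(events: pd.DataFrame, min_events_per_s: int = 1) -> dict:
    """Fit p(S) = ρS^(−γ) to empirical exploration fractions.

    S = 0 is excluded (exploration is forced there), as are S cells with an
    empirical fraction of 0 or 1 (log-undefined). The fit is weighted least
    squares of log p on log S with event-count weights; confidence intervals
    use heteroskedasticity-robust (HC1) standard errors, since the binomial
    variance of log p̂_S is not proportional to 1/n_S.

    Returns rho, gamma, their 95% CIs, and the per-S empirical table.
    """
    g = events.loc[events["S_before"] >= 1].groupby("S_before")["is_exploration"].agg(["mean", "size"])
    g = g.loc[(g["size"] >= min_events_per_s) & (g["mean"] > 0.0) & (g["mean"] < 1.0)]
    if len(g) < 2:
        raise ValueError("no informative states")
    log_s = np.log(g.index.to_numpy(dtype=float))
    log_p = np.log(g["mean"].to_numpy())
    x = sm.add_constant(log_s)
    res = sm.WLS(log_p, x, weights=g["size"].to_numpy()).fit(cov_type="HC1")
    ci = res.conf_int()
    out = {
        "rho": float(np.exp(res.params[0])),
        "gamma": float(-res.params[1]),
        "rho_ci": (float(np.exp(ci[0, 0])), float(np.exp(ci[0, 1]))),
        "gamma_ci": (float(-ci[1, 1]), float(-ci[1, 0])),
        "n_states": int(len(g)),
        "empirical": g.rename(columns={"mean": "p_explore", "size": "n_events"}),
    }
    return out


def majority_labels(place_exposures: pd.DataFrame, q: int = 4) -> pd.DataFrame:
    """Majority income quantile per place: argmax_q τ_qα on the baseline.

    Ties go to the lowest quantile and are flagged; labels are computed once
    on a 2019 baseline window and held fixed across periods, so σ_s tracks
    choice behavior rather than pandemic-era re-labelling.
    """
    cols = [f"tau_{k}" for k in range(1, q + 1)]
    tau = place_exposures[cols].to_numpy()
    best = tau.argmax(axis=1)
    n_max = (tau >= tau[np.arange(len(tau)), best][:, None] - 1e-12).sum(axis=1)
    return pd.DataFrame(
        {"majority_quantile": best + 1, "tie_flag": n_max > 1}, index=place_exposures.index
    )


def estimate_social_exploration(
    events: pd.DataFrame,
    labels: pd.DataFrame,
    profiles: pd.DataFrame,
    exclude_ties: bool = True,
) -> dict:
    """σ̂_s: share of explorations into places of a different majority quantile.

    Only explorations at labelled places count; tie-flagged places are
    excluded by default. Returns the estimate, a binomial (Wilson) 95% CI,
    and the exploration count.
    """
    e = events.loc[events["is_exploration"]].merge(
        labels, left_on="poi_id", right_index=True, how="inner"
    )
    if exclude_ties:
        e = e.loc[~e["tie_flag"]]
    e = e.merge(profiles[["user_id", "income_quantile"]], on="user_id", how="inner")
    n = len(e)
    if n == 0:
        raise ValueError("zero labelled explorations")
    k = int((e["majority_quantile"] != e["income_quantile"]).sum())
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    return {"sigma_s": k / n, "ci": (float(lo), float(hi)), "n_explorations": n}


def subcategory_popularity(
    visits: pd.DataFrame,
    poi_table: pd.DataFrame,
    r: int = 5,
) -> pd.DataFrame:
    """f_r per subcategory: share of individuals whose top-r places include it.

    A user's top r is by visit count, ties broken by higher total dwell then
    lower poi_id. Subcategories never appearing in any top-r set are listed
    with f_r = 0.
    """
    if r < 1:
        raise ValueError("r must be >= 1")
    per = visits.groupby(["user_id", "poi_id"], as_index=False).agg(
        n_visits=("dwell_min", "size"), dwell=("dwell_min", "sum")
    )
    per = per.sort_values(
        ["user_id", "n_visits", "dwell", "poi_id"], ascending=[True, False, False, True], kind="mergesort"
    )
    top = per.groupby("user_id").head(r)
    top = top.merge(poi_table[["poi_id", "subcategory"]], on="poi_id", how="left")
    n_users = visits["user_id"].nunique()
    counts = top.groupby("subcategory")["user_id"].nunique()
    all_subs = poi_table["subcategory"].unique()
    f = counts.reindex(all_subs, fill_value=0) / n_users
    return f.rename("f_r").rename_axis("subcategory").reset_index().sort_values("f_r", ascending=False, ignore_index=True)


def popularity_shift(f_now: pd.DataFrame, f_base: pd.DataFrame) -> pd.DataFrame:
    """Δf_r per subcategory vs the baseline table, most-gained first."""
    m = f_now.merge(f_base, on="subcategory", suffixes=("", "_2019"), how="outer").fillna(0.0)
    m["delta_f_r"] = m["f_r"] - m["f_r_2019"]
    return m.sort_values("delta_f_r", ascending=False, ignore_index=True)
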