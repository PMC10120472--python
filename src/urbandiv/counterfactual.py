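"""Counterfactual visit panels by stratified random removal, and the
decomposition of the diversity drop into behavioral factors.

To ask "how would encounter diversity have changed if people had only
reduced *how much* they go out, not *where* they go?", visits are removed
uniformly at random from the pre-pandemic (2019, month m) panel until its
dwell time matches the pandemic (y, m) panel:

* scenario (i): one global dwell target — total activity reduction only;
* scenario (ii): targets per income quantile × 7-bin home-to-POI distance
  ladder [0,1), [1,3), [3,5), [5,10), [10,20), [20,40), [40,∞) km —
  additionally matching who travels how far;
* scenario (ii+cat): targets per quantile × distance bin × major place
  category (a robustness variant).

Whatever diversity gap the scenario-(ii) counterfactual cannot reproduce is
attributed to factor (iii): microscopic changes in place preferences and
exploration behavior. The decomposition telescopes exactly:

    D̄(2019) − D̄(actual) = [D̄(2019) − D̄_cf(i)] + [D̄_cf(i) − D̄_cf(ii)]
                           + [D̄_cf(ii) − D̄(actual)].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics

logger = logging.getLogger(__name__)

#: left-closed, right-open distance ladder in km
DISTANCE_BIN_EDGES = (0.0, 1.0, 3.0, 5.0, 10.0, 20.0, 40.0, np.inf)

SCENARIOS = ("i", "ii", "ii_cat")


def assign_distance_bins(d_km) -> np.ndarray:
    """Bin distances into the 7-bin ladder; returns indices 0..6."""
    return np.digitize(np.asarray(d_km, dtype=float), DISTANCE_BIN_EDGES[1:-1], right=False)


def _strata(visits: pd.DataFrame, scenario: str) -> pd.Series:
    if scenario == "i":
        return pd.Series(0, index=visits.index)
    if scenario == "ii":
        return pd.Series(
            list(zip(visits["income_quantile"], assign_distance_bins(visits["distance_from_home_km"]))),
            index=visits.index,
        )
    if scenario == "ii_cat":
        return pd.Series(
            list(
                zip(
                    visits["income_quantile"],
                    assign_distance_bins(visits["distance_from_home_km"]),
                    visits["category"],
                )
            ),
            index=visits.index,
        )
    raise ValueError(f"unknown scenario {scenario!r}")


def dwell_targets(actual_visits: pd.DataFrame, scenario: str) -> dict:
    """Total dwell minutes per stratum in the pandemic-month panel.

    Scenario (ii)/(ii_cat) inputs must carry ``income_quantile`` and
    ``distance_from_home_km`` (and ``category``) columns — see
    :func:`ingest.add_home_distance`.
    """
    strata = _strata(actual_visits, scenario)
    return actual_visits.groupby(strata)["dwell_min"].sum().to_dict()


def downsample(source_visits: pd.DataFrame, targets: dict, scenario: str, seed: int) -> pd.DataFrame:
    """Remove visits uniformly at random per stratum until dwell ≤ target.

    Removal stops at the first crossing below the target, so the remaining
    dwell is within one visit's dwell (≤ 240 min) of the target. Strata
    absent from ``targets`` get target 0; strata whose target exceeds the
    source dwell keep all source visits (visits are never added). The output
    is a subset of ``source_visits`` rows (original index preserved);
    deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    strata = _strata(source_visits, scenario)
    keep_idx = []
    for key, idx in source_visits.groupby(strata).groups.items():
        idx = np.asarray(idx)
        dwell = source_visits.loc[idx, "dwell_min"].to_numpy()
        total = dwell.sum()
        target = float(targets.get(key, 0.0))
        if target >= total:
            if target > total:
                logger.warning(
                    "stratum %s shortfall: target %.0f min exceeds source %.0f min; keeping all",
                    key, target, total,
                )
            keep_idx.append(idx)
            continue
        order = rng.permutation(len(idx))
        cum = np.cumsum(dwell[order])
        # remove the first k (in removal order) with k minimal s.t. total - cum_k <= target
        k = int(np.searchsorted(cum, total - target, side="left")) + 1
        keep_idx.append(idx[order[k:]])
    if not keep_idx:
        return source_visits.iloc[0:0]
    kept = np.concatenate(keep_idx)
    return source_visits.loc[np.sort(kept)]


@dataclass
class CounterfactualResult:
    """Replicate-level counterfactual diversity and its summary."""

    scenario: str
    n_reps: int
    place_diversity: np.ndarray = field(repr=False)
    individual_diversity: np.ndarray = field(repr=False)

    @property
    def mean_place(self) -> float:
        return float(np.mean(self.place_diversity))

    @property
    def se_place(self) -> float:
        return float(np.std(self.place_diversity, ddof=1) / np.sqrt(self.n_reps))

    @property
    def mean_individual(self) -> float:
        return float(np.mean(self.individual_diversity))

    @property
    def se_individual(self) -> float:
        return float(np.std(self.individual_diversity, ddof=1) / np.sqrt(self.n_reps))


def run_counterfactual(
    visits_2019m: pd.DataFrame,
    visits_ym: pd.DataFrame,
    profiles: pd.DataFrame,
    scenario: str = "ii",
    n_reps: int = 10,
    seed: int = 0,
    q: int = 4,
    metric: str = "evenness",
) -> CounterfactualResult:
    """Downsample the baseline panel ``n_reps`` times and measure diversity.

    Both inputs must have passed identical ingest filters; per-replicate
    seeds are ``seed + replicate_index``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    targets = dwell_targets(visits_ym, scenario)
    d_place = np.empty(n_reps)
    d_indiv = np.empty(n_reps)
    for rep in range(n_reps):
        cf = downsample(visits_2019m, targets, scenario, seed + rep)
        d_place[rep] = metrics.mean_place_diversity(cf, profiles, q, metric)
        d_indiv[rep] = metrics.mean_individual_diversity(cf, profiles, q, metric)
    return CounterfactualResult(scenario, n_reps, d_place, d_indiv)


def decompose(d_2019: float, d_cf_i: float, d_cf_ii: float, d_actual: float) -> dict:
    """Split D̄(2019) − D̄(actual) into factor contributions and shares.

    contribution_i   = D̄(2019) − D̄_cf(i)      (total activity reduction)
    contribution_ii  = D̄_cf(i) − D̄_cf(ii)     (per-quantile distance shifts)
    contribution_iii = D̄_cf(ii) − D̄(actual)   (residual preference changes)

    Shares are contributions divided by the total decrease and sum to 1;
    they are omitted (None) when the total decrease is zero.
    """
    contributions = {
        "i": d_2019 - d_cf_i,
        "ii": d_cf_i - d_cf_ii,
        "iii": d_cf_ii - d_actual,
    }
    total = d_2019 - d_actual
    shares = {k: v / total for k, v in contributions.items()} if total != 0.0 else None
    return {"contributions": contributions, "shares": shares, "total_decrease": total}
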