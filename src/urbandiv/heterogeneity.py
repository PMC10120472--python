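"""Area-level heterogeneity regression and the stringency trade-off.

CBG-level diversity D_CBG (or its percentage change ΔD_CBG) is modelled as
a linear function of standardized covariate blocks — residential census
variables {R_CBG}, a place-visit profile {P_CBG} built from 2019 visit
subcategory shares, and mobility covariates {M_CBG} — with geographic fixed
effects at the PUMA level absorbed by within-group demeaning. Classical
standard errors are the default (robust errors behind a flag), with degrees
of freedom corrected for the absorbed group means.

The policy trade-off is quantified as the per-CBSA Pearson correlation
between monthly ΔD_CBSA and the policy stringency index (0–100), with a
companion OLS slope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)


def build_place_vector(
    visits_2019: pd.DataFrame,
    poi_table: pd.DataFrame,
    profiles: pd.DataFrame,
    min_venues: int = 100,
    share_threshold: float = 0.003,
) -> pd.DataFrame:
    """{P_CBG}: per-CBG share of residents frequenting each subcategory.

    A subcategory qualifies if it has at least ``min_venues`` venues; an
    individual "frequents" it if more than ``share_threshold`` (0.3%) of
    their dwell time is spent there. The CBG row is the mean of resident
    indicators. Returns a CBG × subcategory frame in [0, 1].
    """
    venue_counts = poi_table.groupby("subcategory")["poi_id"].nunique()
    qualifying = venue_counts.index[venue_counts >= min_venues]
    if len(qualifying) == 0:
        logger.warning("no subcategory has >= %d venues; empty place vector", min_venues)
        return pd.DataFrame(index=pd.Index([], name="home_cbg"))
    v = visits_2019.merge(poi_table[["poi_id", "subcategory"]], on="poi_id", how="left")
    dwell = v.pivot_table(index="user_id", columns="subcategory", values="dwell_min", aggfunc="sum", fill_value=0.0)
    shares = dwell.div(dwell.sum(axis=1), axis=0)
    indicators = (shares.reindex(columns=qualifying, fill_value=0.0) > share_threshold).astype(float)
    merged = indicators.merge(profiles[["user_id", "home_cbg"]], left_index=True, right_on="user_id")
    return merged.drop(columns="user_id").groupby("home_cbg").mean()


def standardize(x: pd.DataFrame) -> pd.DataFrame:
    """Zero-mean, unit-variance columns (population std); constant columns error."""
    std = x.std(ddof=0)
    if (std == 0).any():
        raise ValueError(f"constant columns cannot be standardized: {list(std.index[std == 0])}")
    return (x - x.mean()) / std


@dataclass
class RegressionResult:
    params: pd.Series
    bse: pd.Series
    conf_int: pd.DataFrame
    pvalues: pd.Series
    r2: float
    adj_r2: float
    n: int
    n_groups: int
    dropped: list
    vif: pd.Series

    def summary_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {"coef": self.params, "se": self.bse, "p": self.pvalues}
        )
        out[["ci_low", "ci_high"]] = self.conf_int
        return out


def _drop_collinear(x: pd.DataFrame, cond_threshold: float = 1e8) -> tuple[pd.DataFrame, list]:
    """Drop columns via pivoted QR until the design is numerically full rank."""
    from scipy.linalg import qr as scipy_qr

    a = x.to_numpy()
    scale = np.linalg.norm(a, axis=0)
    scale[scale == 0] = 1.0
    _, r, piv = scipy_qr(a / scale, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    keep_rank = int((diag > diag[0] / cond_threshold).sum()) if diag[0] > 0 else 0
    keep = sorted(piv[:keep_rank])
    dropped = [x.columns[j] for j in sorted(piv[keep_rank:])]
    if dropped:
        logger.warning("dropping collinear columns: %s", dropped)
    return x.iloc[:, keep], dropped


def fit_fe_ols(
    y: pd.Series,
    features: pd.DataFrame,
    groups: pd.Series,
    robust: bool = False,
    cond_threshold: float = 1e8,
) -> RegressionResult:
    """OLS with absorbed group fixed effects (within-group demeaning).

    Equivalent to dummy-variable OLS: coefficients, classical standard
    errors, t-tests and adjusted R² all match the model with an intercept
    and G−1 group dummies. R² is computed about the overall mean of ``y``,
    so it is the dummy-model R², not the within-R².
    """
    idx = y.index
    g = groups.loc[idx]
    if g.nunique() < 2:
        raise ValueError("need at least 2 fixed-effect groups")
    x = features.loc[idx]
    x, dropped = _drop_collinear(x, cond_threshold)
    xd = x - x.groupby(g).transform("mean")
    yd = y - y.groupby(g).transform("mean")

    n, k = xd.shape
    n_groups = g.nunique()
    df_resid = n - k - n_groups
    if df_resid <= 0:
        raise ValueError("insufficient degrees of freedom after absorbing fixed effects")
    res = sm.OLS(yd.to_numpy(), xd.to_numpy()).fit()
    ssr = float(res.ssr)
    sst = float(((y - y.mean()) ** 2).sum())
    # rescale classical covariance to the fixed-effects residual dof
    scale = np.sqrt((n - k) / df_resid)
    if robust:
        bse = pd.Series(res.get_robustcov_results("HC1").bse, index=x.columns)
    else:
        bse = pd.Series(res.bse * scale, index=x.columns)
    params = pd.Series(res.params, index=x.columns)
    tvals = params / bse
    pvalues = 2.0 * stats.t.sf(np.abs(tvals), df_resid)
    tcrit = stats.t.ppf(0.975, df_resid)
    ci = pd.DataFrame(
        {"ci_low": params - tcrit * bse, "ci_high": params + tcrit * bse}, index=x.columns
    )
    r2 = 1.0 - ssr / sst
    adj_r2 = 1.0 - (ssr / df_resid) / (sst / (n - 1))

    with np.errstate(divide="ignore"):
        xc = xd.to_numpy()
        vif_vals = []
        for j in range(k):
            others = np.delete(xc, j, axis=1)
            rj = sm.OLS(xc[:, j], others).fit().rsquared if k > 1 else 0.0
            vif_vals.append(1.0 / (1.0 - rj) if rj < 1.0 else np.inf)
    return RegressionResult(
        params=params,
        bse=bse,
        conf_int=ci,
        pvalues=pd.Series(pvalues, index=x.columns),
        r2=r2,
        adj_r2=adj_r2,
        n=n,
        n_groups=n_groups,
        dropped=dropped,
        vif=pd.Series(vif_vals, index=x.columns),
    )


@dataclass
class TradeoffResult:
    pearson_r: float
    p_value: float
    slope: float
    slope_ci: tuple
    n_months: int
    lag1_autocorr: float


def stringency_tradeoff(delta_d: pd.Series, stringency: pd.Series) -> TradeoffResult:
    """Correlation between monthly ΔD and the stringency index for one CBSA.

    Inputs are aligned on their (month-label) index; requires ≥ 3 common
    months and a non-constant index. A lag-1 autocorrelation of ΔD is
    reported as a temporal-dependence diagnostic.
    """
    joined = pd.concat([delta_d.rename("dd"), stringency.rename("si")], axis=1).dropna()
    if len(joined) < 3:
        raise ValueError("need at least 3 aligned months")
    if joined["si"].nunique() == 1:
        raise ValueError("stringency index is constant; correlation undefined")
    r, p = stats.pearsonr(joined["si"], joined["dd"])
    ols = sm.OLS(joined["dd"].to_numpy(), sm.add_constant(joined["si"].to_numpy())).fit()
    ci = ols.conf_int()[1]
    dd = joined["dd"].to_numpy()
    lag1 = float(np.corrcoef(dd[:-1], dd[1:])[0, 1]) if len(dd) > 3 else np.nan
    return TradeoffResult(
        pearson_r=float(r),
        p_value=float(p),
        slope=float(ols.params[1]),
        slope_ci=(float(ci[0]), float(ci[1])),
        n_months=len(joined),
        lag1_autocorr=lag1,
    )
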