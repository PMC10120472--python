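"""Exposure and diversity statistics against closed forms and brute force."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from urbandiv import metrics
from urbandiv._geo import haversine_km

from conftest import random_profiles, random_visits


def _visits(rows):
    df = pd.DataFrame(rows, columns=["user_id", "poi_id", "dwell_min"])
    df["t_start"] = pd.Timestamp("2019-04-10", tz="UTC")
    return df


def _profiles(quantiles, weights=None):
    return pd.DataFrame(
        {
            "user_id": list(quantiles),
            "income_quantile": list(quantiles.values()),
            "weight": [1.0] * len(quantiles) if weights is None else [weights[u] for u in quantiles],
            "home_cbg": "C0",
        }
    )


class TestPlaceExposure:
    def test_equal_dwell_gives_uniform_tau(self):
        v = _visits([(f"u{q}", "p", 30.0) for q in range(1, 5)])
        prof = _profiles({f"u{q}": q for q in range(1, 5)})
        expo = metrics.place_exposure(v, prof)
        assert np.allclose(expo.loc["p", ["tau_1", "tau_2", "tau_3", "tau_4"]], 0.25)

    def test_single_quantile_point_mass(self):
        v = _visits([("a", "p", 50.0), ("b", "p", 10.5)])
        prof = _profiles({"a": 2, "b": 2})
        expo = metrics.place_exposure(v, prof)
        assert expo.loc["p", ["tau_1", "tau_2", "tau_3", "tau_4"]].tolist() == [0.0, 1.0, 0.0, 0.0]

    def test_mixed_dwell_shares(self):
        v = _visits([("a", "p", 60.0), ("b", "p", 20.0), ("c", "p", 20.0)])
        prof = _profiles({"a": 1, "b": 2, "c": 3})
        expo = metrics.place_exposure(v, prof)
        assert np.allclose(expo.loc["p", ["tau_1", "tau_2", "tau_3", "tau_4"]], [0.6, 0.2, 0.2, 0.0])

    def test_weights_scale_invariance_and_unit_weights(self):
        v = random_visits(seed=3)
        prof = random_profiles(v, seed=4)
        base = metrics.place_exposure(v, prof)
        doubled = metrics.place_exposure(v, prof.assign(weight=2.0))
        cols = ["tau_1", "tau_2", "tau_3", "tau_4"]
        pd.testing.assert_frame_equal(base[cols], doubled[cols])

    def test_support_flag(self):
        v = _visits([("a", "p", 15.0), ("a", "q", 45.0), ("b", "q", 45.0)])
        prof = _profiles({"a": 1, "b": 2})
        expo = metrics.place_exposure(v, prof)
        assert not expo.loc["p", "qualifies"]  # one user, 15 min
        assert expo.loc["q", "qualifies"]

    def test_exposure_conservation(self, base_panel, profiles):
        expo = metrics.place_exposure(base_panel, profiles)
        sums = expo[["tau_1", "tau_2", "tau_3", "tau_4"]].sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)


class TestDiversity:
    def test_uniform_is_one_and_point_mass_is_zero(self):
        assert metrics.evenness_diversity([0.25, 0.25, 0.25, 0.25]) == 1.0
        assert metrics.evenness_diversity([1.0, 0.0, 0.0, 0.0]) == 0.0
        assert metrics.entropy_diversity([0.25] * 4) == 1.0
        assert metrics.entropy_diversity([1.0, 0.0, 0.0, 0.0]) == 0.0

    def test_half_split_closed_forms(self):
        assert metrics.evenness_diversity([0.5, 0.5, 0.0, 0.0]) == pytest.approx(1.0 / 3.0)
        assert metrics.entropy_diversity([0.5, 0.5, 0.0, 0.0]) == pytest.approx(0.5)

    def test_generalized_q_boundaries(self):
        assert metrics.evenness_diversity([1.0, 0.0], q=2) == 0.0
        assert metrics.evenness_diversity([0.5, 0.5], q=2) == 1.0
        assert metrics.evenness_diversity([1 / 3] * 3, q=3) == 1.0

    def test_invalid_tau_raises(self):
        with pytest.raises(ValueError):
            metrics.evenness_diversity([0.5, 0.2, 0.1, 0.1])
        with pytest.raises(ValueError):
            metrics.entropy_diversity([0.7, 0.5, -0.2, 0.0])

    def test_bounds_and_extremes_on_random_vectors(self):
        rng = np.random.default_rng(0)
        tau = rng.dirichlet(np.ones(4), size=10_000)
        d_even = metrics.evenness_diversity(tau)
        d_ent = metrics.entropy_diversity(tau)
        assert ((d_even >= 0) & (d_even <= 1)).all()
        assert ((d_ent >= 0) & (d_ent <= 1)).all()
        rho = stats.spearmanr(d_even, d_ent).statistic
        assert rho > 0.9

    def test_merging_places_with_identical_tau_preserves_diversity(self):
        v = _visits(
            [("a", "p1", 60.0), ("b", "p1", 20.0), ("a", "p2", 30.0), ("b", "p2", 10.0)]
        )
        prof = _profiles({"a": 1, "b": 2})
        expo = metrics.place_exposure(v, prof)
        merged = _visits([("a", "p", 90.0), ("b", "p", 30.0)])
        expo_m = metrics.place_exposure(merged, prof)
        cols = ["tau_1", "tau_2", "tau_3", "tau_4"]
        assert np.allclose(
            expo.loc["p1", cols].to_numpy(dtype=float), expo_m.loc["p", cols].to_numpy(dtype=float)
        )
        assert np.allclose(
            expo.loc["p2", cols].to_numpy(dtype=float), expo_m.loc["p", cols].to_numpy(dtype=float)
        )


class TestIndividualExposure:
    def test_single_place_individual_inherits_place_vector(self):
        v = _visits([("a", "p", 60.0), ("b", "p", 20.0), ("b", "q", 40.0)])
        prof = _profiles({"a": 1, "b": 3})
        expo = metrics.place_exposure(v, prof)
        tau_iq = metrics.individual_exposure(metrics.time_shares(v), expo)
        cols = ["tau_1", "tau_2", "tau_3", "tau_4"]
        assert np.allclose(
            tau_iq.loc["a", cols].to_numpy(dtype=float), expo.loc["p", cols].to_numpy(dtype=float)
        )

    def test_convolution_matches_triple_loop_oracle(self):
        v = random_visits(n_users=50, n_pois=20, n_visits=600, seed=8)
        prof = random_profiles(v, seed=9)
        expo = metrics.place_exposure(v, prof)
        shares = metrics.time_shares(v)
        got = metrics.individual_exposure(shares, expo)

        cols = ["tau_1", "tau_2", "tau_3", "tau_4"]
        for uid in got.index:
            srow = shares.loc[shares["user_id"] == uid]
            expected = np.zeros(4)
            for _, r in srow.iterrows():
                for k in range(4):
                    expected[k] += r["share"] * expo.loc[r["poi_id"], cols[k]]
            assert np.allclose(got.loc[uid, cols].to_numpy(), expected, atol=1e-12)

    def test_individual_exposure_sums_to_one(self, base_panel, profiles):
        d = metrics.individual_diversity(base_panel, profiles)
        sums = d[["tau_1", "tau_2", "tau_3", "tau_4"]].sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)
        assert d["D"].between(0, 1).all()


class TestAggregationAndDeltas:
    def test_cbg_mean(self):
        d_i = pd.DataFrame({"D": [0.4, 0.6, 0.8]}, index=["a", "b", "c"])
        prof = _profiles({"a": 1, "b": 1, "c": 1})
        prof["home_cbg"] = ["X", "X", "Y"]
        out = metrics.aggregate_cbg(d_i, prof)
        assert out.loc["X", "D"] == pytest.approx(0.5)
        assert out.loc["Y", "D"] == pytest.approx(0.8)
        assert out.loc["Y", "n_residents"] == 1

    def test_delta_percent(self):
        assert metrics.delta_percent(0.45, 0.50) == pytest.approx(-10.0)
        assert metrics.delta_percent(0.5, 0.5) == 0.0
        with pytest.raises(ValueError):
            metrics.delta_percent(0.5, 0.0)

    def test_deseasonalize_identities(self):
        base = {4: 2.0, 5: 4.0}
        s = pd.Series({"2020-04": 2.0, "2020-05": 4.0})
        assert np.allclose(metrics.deseasonalize(s, base), 1.0)
        assert np.allclose(metrics.deseasonalize(2 * s, base), 2.0)
        with pytest.raises(ValueError):
            metrics.deseasonalize(pd.Series({"2020-06": 1.0}), base)


class TestMobilityMetrics:
    def test_single_poi_user_has_zero_gyration(self):
        v = pd.DataFrame(
            {
                "user_id": ["u"] * 3,
                "poi_id": ["p"] * 3,
                "t_start": pd.to_datetime(["2019-04-01", "2019-04-02", "2019-04-03"], utc=True),
                "dwell_min": [30.0] * 3,
                "lon": [-71.0] * 3,
                "lat": [42.0] * 3,
            }
        )
        out = metrics.mobility_metrics(v)
        assert out.loc["u", "radius_of_gyration_km"] == pytest.approx(0.0)

    def test_visits_per_day(self):
        v = pd.DataFrame(
            {
                "user_id": ["u"] * 6,
                "poi_id": list("pqpqpq"),
                "t_start": pd.to_datetime(
                    ["2019-04-01T08:00", "2019-04-01T12:00", "2019-04-02T08:00",
                     "2019-04-02T12:00", "2019-04-03T08:00", "2019-04-03T12:00"], utc=True
                ),
                "dwell_min": [30.0] * 6,
                "lon": [-71.0] * 6,
                "lat": [42.0] * 6,
            }
        )
        out = metrics.mobility_metrics(v)
        assert out.loc["u", "visits_per_day"] == pytest.approx(2.0)
        assert out.loc["u", "n_unique_pois"] == 2

    def test_gyration_matches_two_pass_oracle(self, base_panel):
        v = base_panel.groupby("user_id").head(20).groupby("user_id").filter(lambda g: len(g) >= 5)
        out = metrics.mobility_metrics(v)
        for uid, g in list(v.groupby("user_id"))[:20]:
            clon, clat = g["lon"].mean(), g["lat"].mean()
            rg = np.sqrt((haversine_km(g["lon"], g["lat"], clon, clat) ** 2).mean())
            assert out.loc[uid, "radius_of_gyration_km"] == pytest.approx(rg, abs=1e-9)
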