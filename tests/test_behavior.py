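"""Exploration labelling, law fitting, social exploration, popularity."""

import numpy as np
import pandas as pd
import pytest

from urbandiv import behavior, metrics

from conftest import random_visits


def _events(seq, user="u"):
    return pd.DataFrame(
        {
            "user_id": user,
            "poi_id": list(seq),
            "t_start": pd.to_datetime(
                [f"2019-04-{d+1:02d}" for d in range(len(seq))], utc=True
            ),
            "dwell_min": 30.0,
        }
    )


class TestLabelExplorations:
    def test_abac_sequence(self):
        ev = behavior.label_explorations(_events("ABAC"))
        assert ev["is_exploration"].tolist() == [True, True, False, True]
        assert ev["S_before"].tolist() == [0, 1, 2, 2]

    def test_single_visit(self):
        ev = behavior.label_explorations(_events("A"))
        assert ev["is_exploration"].tolist() == [True]
        assert ev["S_before"].tolist() == [0]

    def test_matches_seen_set_oracle(self):
        v = random_visits(n_users=40, n_pois=25, n_visits=10_000, seed=13)
        ev = behavior.label_explorations(v)
        seen = {}
        for row in ev.itertuples():
            s = seen.setdefault(row.user_id, set())
            assert row.is_exploration == (row.poi_id not in s)
            assert row.S_before == len(s)
            s.add(row.poi_id)

    def test_total_explorations_equal_distinct_poi_count(self, base_panel):
        ev = behavior.label_explorations(base_panel)
        per_user = base_panel.groupby("user_id")["poi_id"].nunique().sum()
        assert ev["is_exploration"].sum() == per_user


class TestFitExplorationLaw:
    def _exact_events(self, rho=0.5, gamma=1.0):
        # exact binomial fractions on the curve: p(S) = rho * S^-gamma
        rows = []
        for s, n in [(1, 16), (2, 16), (4, 16), (8, 16)]:
            k = int(round(rho * s ** (-gamma) * n))
            assert abs(k - rho * s ** (-gamma) * n) < 1e-12
            rows += [(s, True)] * k + [(s, False)] * (n - k)
        return pd.DataFrame(rows, columns=["S_before", "is_exploration"])

    def test_noiseless_identity_recovery(self):
        fit = behavior.fit_exploration_law(self._exact_events())
        assert fit["rho"] == pytest.approx(0.5, abs=1e-9)
        assert fit["gamma"] == pytest.approx(1.0, abs=1e-9)

    def test_flat_law_gives_zero_gamma(self):
        rows = []
        for s in (1, 2, 4, 8):
            rows += [(s, True)] * 8 + [(s, False)] * 8
        fit = behavior.fit_exploration_law(pd.DataFrame(rows, columns=["S_before", "is_exploration"]))
        assert fit["gamma"] == pytest.approx(0.0, abs=1e-9)
        assert fit["rho"] == pytest.approx(0.5, abs=1e-9)

    def test_uninformative_stream_raises(self):
        ev = pd.DataFrame({"S_before": [0, 0, 0], "is_exploration": [True, True, True]})
        with pytest.raises(ValueError, match="no informative states"):
            behavior.fit_exploration_law(ev)


class TestMajorityLabels:
    def test_argmax_and_tie_rule(self):
        expo = pd.DataFrame(
            {
                "tau_1": [0.6, 0.5],
                "tau_2": [0.2, 0.5],
                "tau_3": [0.2, 0.0],
                "tau_4": [0.0, 0.0],
            },
            index=["p", "q"],
        )
        ml = behavior.majority_labels(expo)
        assert ml.loc["p", "majority_quantile"] == 1 and not ml.loc["p", "tie_flag"]
        assert ml.loc["q", "majority_quantile"] == 1 and ml.loc["q", "tie_flag"]

    def test_labels_track_generator_ground_truth_at_scale(self, big_panel):
        world, stays = big_panel
        cbg, poi, users = world
        expo = metrics.place_exposure(stays, users)
        ml = behavior.majority_labels(expo)
        dq = poi.set_index("poi_id")["dominant_quantile"]
        hi = (expo["support_users"] >= 10) & (~ml["tie_flag"])
        agree = (ml.loc[hi, "majority_quantile"].to_numpy() == dq.loc[ml.index[hi]].to_numpy()).mean()
        assert agree >= 0.90


class TestSocialExploration:
    def _setup(self, majorities, user_q, seq="ABC"):
        events = behavior.label_explorations(_events(seq))
        labels = pd.DataFrame(
            {"majority_quantile": majorities, "tie_flag": False}, index=list(seq)
        )
        profiles = pd.DataFrame({"user_id": ["u"], "income_quantile": [user_q]})
        return events, labels, profiles

    def test_all_own_majority_gives_zero(self):
        e, l, p = self._setup([2, 2, 2], 2)
        assert behavior.estimate_social_exploration(e, l, p)["sigma_s"] == 0.0

    def test_all_other_majority_gives_one(self):
        e, l, p = self._setup([1, 3, 4], 2)
        assert behavior.estimate_social_exploration(e, l, p)["sigma_s"] == 1.0

    def test_no_labelled_explorations_raises(self):
        e, l, p = self._setup([2, 2, 2], 2)
        with pytest.raises(ValueError):
            behavior.estimate_social_exploration(e, l.iloc[0:0], p)

    def test_invariant_to_relabelling_and_revisit_order(self):
        v = random_visits(n_users=30, n_pois=15, n_visits=2000, seed=21)
        ev = behavior.label_explorations(v)
        rng = np.random.default_rng(3)
        labels = pd.DataFrame(
            {"majority_quantile": rng.integers(1, 5, 15), "tie_flag": False},
            index=[str(i) for i in range(15)],
        )
        prof = pd.DataFrame(
            {"user_id": sorted(v["user_id"].unique()), "income_quantile": rng.integers(1, 5, 30)}
        )
        base = behavior.estimate_social_exploration(ev, labels, prof)["sigma_s"]
        # shuffle revisit order within each (user, poi) after the first visit:
        # permuting rows and re-labelling explorations must not change sigma_s
        v2 = v.sample(frac=1.0, random_state=7).sort_values(["user_id", "t_start"], kind="mergesort")
        got = behavior.estimate_social_exploration(behavior.label_explorations(v2), labels, prof)["sigma_s"]
        assert got == pytest.approx(base)

    def test_empirical_pipeline_recovers_sigma_s(self, big_panel):
        world, stays = big_panel
        cbg, poi, users = world
        ev = behavior.label_explorations(stays)
        expo = metrics.place_exposure(stays, users)
        ml = behavior.majority_labels(expo)
        got = behavior.estimate_social_exploration(ev, ml, users)["sigma_s"]
        assert got == pytest.approx(0.40, abs=0.03)


class TestSubcategoryPopularity:
    def _poi_table(self):
        return pd.DataFrame(
            {
                "poi_id": ["g", "c", "m"],
                "subcategory": ["Grocery Store", "Coffee Shop", "Movie Theater"],
            }
        )

    def test_top_one_grocery(self):
        v = _events("ggc")
        v["poi_id"] = ["g", "g", "c"]
        out = behavior.subcategory_popularity(v, self._poi_table(), r=1)
        f = out.set_index("subcategory")["f_r"]
        assert f["Grocery Store"] == 1.0
        assert f["Coffee Shop"] == 0.0

    def test_r_larger_than_repertoire_includes_everything(self):
        v = _events("gcm")
        out = behavior.subcategory_popularity(v, self._poi_table(), r=10)
        assert (out["f_r"] == 1.0).all()

    def test_invalid_r(self):
        with pytest.raises(ValueError):
            behavior.subcategory_popularity(_events("g"), self._poi_table(), r=0)

    def test_monotone_in_r(self, big_panel):
        world, stays = big_panel
        poi = world[1]
        sub = stays.loc[stays["user_id"].isin(stays["user_id"].unique()[:300])]
        prev = None
        for r in (1, 3, 5, 10):
            f = behavior.subcategory_popularity(sub, poi, r=r).set_index("subcategory")["f_r"]
            if prev is not None:
                assert (f.reindex(prev.index) >= prev - 1e-12).all()
            prev = f

    def test_matches_per_user_sort_oracle(self):
        v = random_visits(n_users=200, n_pois=40, n_visits=5000, seed=31)
        rng = np.random.default_rng(1)
        subs = [f"sub{j}" for j in range(8)]
        poi = pd.DataFrame(
            {
                "poi_id": [str(i) for i in range(40)],
                "subcategory": rng.choice(subs, 40),
            }
        )
        got = behavior.subcategory_popularity(v, poi, r=5).set_index("subcategory")["f_r"]
        sub_of = dict(zip(poi["poi_id"], poi["subcategory"]))
        hits = {s: 0 for s in subs}
        users = v["user_id"].unique()
        for u in users:
            g = v.loc[v["user_id"] == u].groupby("poi_id")["dwell_min"].agg(["size", "sum"])
            ranked = sorted(
                g.itertuples(), key=lambda t: (-t.size, -t.sum, t.Index)
            )[:5]
            for s in {sub_of[t.Index] for t in ranked}:
                hits[s] += 1
        for s in subs:
            assert got.get(s, 0.0) == pytest.approx(hits[s] / len(users))

    def test_popularity_shift_ordering(self):
        now = pd.DataFrame({"subcategory": ["a", "b"], "f_r": [0.9, 0.1]})
        base = pd.DataFrame({"subcategory": ["a", "b"], "f_r": [0.5, 0.4]})
        out = behavior.popularity_shift(now, base)
        assert out.iloc[0]["subcategory"] == "a"
        assert out.iloc[0]["delta_f_r"] == pytest.approx(0.4)
        assert out.iloc[1]["delta_f_r"] == pytest.approx(-0.3)
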