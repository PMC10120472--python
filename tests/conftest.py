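import numpy as np
import pandas as pd
import pytest

from urbandiv import behavior, metrics, study, synth


@pytest.fixture(scope="session")
def small_world():
    cfg = synth.WorldConfig(n_users=600, n_pois=1000, n_cbgs=80, seed=11)
    return synth.generate_world(cfg)


@pytest.fixture(scope="session")
def base_panel(small_world):
    """One baseline month of Social-EPR stays on the small world."""
    return synth.simulate_period(
        small_world, study.BASE_EPR, synth.ScenarioConfig.baseline("2019-04"), 30, 101
    )


@pytest.fixture(scope="session")
def big_panel():
    """A large panel (≈7.5e5 events) for estimator-accuracy checks."""
    world = synth.generate_world(synth.WorldConfig(n_users=5000, n_pois=2000, n_cbgs=120, seed=42))
    stays = synth.simulate_period(
        world, study.BASE_EPR, synth.ScenarioConfig.baseline("2019-04"), 60, 77
    )
    return world, stays


@pytest.fixture(scope="session")
def profiles(small_world):
    return small_world[2]


def random_visits(n_users=50, n_pois=30, n_visits=400, seed=0):
    """A small random attributed-visit table (not EPR; for oracle tests)."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "user_id": rng.integers(0, n_users, n_visits).astype(str),
            "poi_id": rng.integers(0, n_pois, n_visits).astype(str),
            "t_start": pd.Timestamp("2019-04-01", tz="UTC")
            + pd.to_timedelta(rng.random(n_visits) * 30, unit="D"),
            "dwell_min": rng.uniform(10.5, 239.5, n_visits),
        }
    )


def random_profiles(visits, q=4, seed=1):
    rng = np.random.default_rng(seed)
    users = np.sort(visits["user_id"].unique())
    return pd.DataFrame(
        {
            "user_id": users,
            "home_cbg": [f"C{rng.integers(0, 10):02d}" for _ in users],
            "income_quantile": rng.integers(1, q + 1, len(users)),
            "weight": 1.0,
        }
    )
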