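"""Shared plumbing for the analysis drivers: one cached study simulation."""

from pathlib import Path

import pandas as pd

from urbandiv import study, synth

SEED = 7
N_USERS = 800
SCRATCH = Path(__file__).resolve().parents[1] / "scratch" / "panels"
RESULTS = Path(__file__).resolve().parents[1] / "results"


def load_or_simulate():
    """Return (world, stays_by_period), simulating and caching on first use."""
    RESULTS.mkdir(exist_ok=True)
    if (SCRATCH / "users.csv").exists():
        return synth.read_fixtures(SCRATCH)
    world, stays = study.simulate_study(seed=SEED, n_users=N_USERS)
    synth.write_fixtures(world, stays, SCRATCH, config=study.default_world_config(SEED, n_users=N_USERS))
    return world, stays
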