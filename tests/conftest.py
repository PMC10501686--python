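"""Shared fixtures.

The desk-scale replicate study (10 replicates each of obligate outcrossing
and obligate selfing at the scaled landscape preset) is expensive, so it is
computed once per session and shared by every test that consumes end-state
or trajectory summaries.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from expansionload import make_sim_fixture, run_replicate
from expansionload.simstats import (
    deme_site_counts,
    load_proxies,
    neutral_pi,
    realized_dfe_bins,
)

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")

DESK_REPLICATES = 10
DESK_BASE_SEED = 1000


@pytest.fixture(scope="session")
def desk_runs():
    """{sigma: [(cfg, trajectory, state), ...]} for sigma in {0, 1}."""
    out = {}
    for sigma in (0.0, 1.0):
        runs = []
        for rep in range(DESK_REPLICATES):
            cfg = make_sim_fixture("desk", sigma=sigma, seed=DESK_BASE_SEED + rep, replicate_id=rep)
            traj, state = run_replicate(cfg)
            assert state.status == "complete"
            runs.append((cfg, traj, state))
        out[sigma] = runs
    return out


@pytest.fixture(scope="session")
def desk_end_summaries(desk_runs):
    """Per-replicate end-state summaries of the desk study: pi, mean
    fitness, DFE-bin proportions and load proxies for every occupied deme."""
    out = {}
    for sigma, runs in desk_runs.items():
        rows = []
        for cfg, traj, state in runs:
            G = cfg.mutation_model.G
            per_deme = {}
            for d in state.demes:
                if d.census() == 0:
                    continue
                counts, nh = deme_site_counts(d, state.table)
                per_deme[d.index] = {
                    "pi": neutral_pi(d, state.table, G=G, counts=counts, n_hap=nh),
                    "mean_fitness": float(np.mean([i.fitness for i in d.individuals])),
                    "dfe": realized_dfe_bins(d, state.table, counts=counts, n_hap=nh),
                    "load": load_proxies(d, state.table, counts=counts),
                    "census": d.census(),
                }
            rows.append(per_deme)
        out[sigma] = rows
    return out


@pytest.fixture()
def tiny_cfg():
    """A seconds-scale configuration for structural/determinism tests."""
    from expansionload import MutationModelConfig, SimulationConfig

    return SimulationConfig(
        n_demes=3,
        K_core=50,
        K_deme=30,
        shift_deme=2,
        sigma=0.5,
        burn_in_generations=60,
        stop_extra_generations=20,
        record_interval=5,
        mutation_model=MutationModelConfig(G=100_000),
        seed=42,
    )
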