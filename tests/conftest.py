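"""Shared fixtures: small simulated datasets and fitted states.

Everything is generated programmatically at session scope so the expensive
variational fits run once and are reused across test modules.
"""

import numpy as np
import pytest

import circaphase as cp


@pytest.fixture(scope="session")
def disp():
    return cp.DispersionModel.constant(0.15)


@pytest.fixture(scope="session")
def clock_table():
    return cp.default_clock_table()


@pytest.fixture(scope="session")
def clock_genes(clock_table):
    return list(clock_table["gene"])


@pytest.fixture(scope="session")
def small_sim(disp):
    """500 cells, 4 phases, 12 clock + 10 CCG + 60 flat genes."""
    cfg = cp.SimConfig(n_cells=500, n_flat_genes=60, n_ccgs=10, seed=1)
    cm, phases, params = cp.simulate_counts(cfg, disp)
    prior = cp.jittered_acrophase_priors(cfg.clock_table, seed=2)
    return {"cfg": cfg, "cm": cm, "phases": phases, "params": params, "prior": prior}


@pytest.fixture(scope="session")
def fitted_state(small_sim, clock_genes, disp):
    """Clock-only Step-1 fit of the small simulation."""
    fc = cp.FitConfig(seed=3)
    state = cp.initialize_state(
        small_sim["prior"], clock_genes, small_sim["cm"], seed=3, config=fc
    )
    return cp.optimize_step1(state, small_sim["cm"], small_sim["prior"], disp, fc)


@pytest.fixture(scope="session")
def flat_sim(disp, clock_table):
    """Same design but all clock amplitudes zero: the negative control."""
    tab = clock_table.copy()
    tab["amplitude"] = 0.0
    cfg = cp.SimConfig(n_cells=400, n_flat_genes=60, n_ccgs=0, clock_table=tab, seed=7)
    cm, phases, params = cp.simulate_counts(cfg, disp)
    prior = cp.jittered_acrophase_priors(tab, seed=8)
    return {"cm": cm, "phases": phases, "prior": prior}


@pytest.fixture()
def rng():
    # function-scoped so every test sees the same fresh stream regardless
    # of execution order
    return np.random.default_rng(0)
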