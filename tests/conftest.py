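"""Shared fixtures: seeded scenarios, trained index models, population run.

The heavy session fixtures (index training, the 3x3x3 transfer-learning
sub-population) are built lazily on first use so unit-test-only runs stay
fast.  All randomness is derived from one base seed.
"""

from __future__ import annotations

import numpy as np
import pytest

import hemnarx as hx
from hemnarx.interface import RunConfig, child_seed

BASE_SEED = 1


@pytest.fixture(scope="session")
def run_config() -> RunConfig:
    return RunConfig(seed=BASE_SEED)


@pytest.fixture(scope="session")
def scenarios(run_config):
    return hx.generate_scenarios(seed=child_seed(BASE_SEED, "scenarios"))


@pytest.fixture(scope="session")
def index_setup(run_config, scenarios):
    """Simulated and scaled series of the index patient (no training)."""
    from hemnarx.interface import simulate_patient_scenarios
    from hemnarx.training import prepare_patient_data

    ib = run_config.index_patient
    params = hx.PatientParameters(gamma=ib.gamma, mtt=ib.mtt, emax=ib.emax,
                                  circ0=run_config.population.circ0)
    series = simulate_patient_scenarios(params, scenarios, pk=run_config.pk)
    scaled, scaler = prepare_patient_data(series, scenarios, params.emax)
    return {"params": params, "series": series, "scaled": scaled, "scaler": scaler}


@pytest.fixture(scope="session")
def index_runs(run_config, scenarios):
    """Index patient trained from random init under three seeds."""
    from hemnarx.interface import prepare_and_train_index

    return [prepare_and_train_index(scenarios, run_config, seed=s)
            for s in (0, 1, 2)]


@pytest.fixture(scope="session")
def population_run(index_runs, run_config, scenarios):
    """Transfer learning over the 3x3x3 sub-grid, seeded; shared by tests."""
    from hemnarx.interface import transfer_population

    index_model = index_runs[0][0]
    ids = hx.subgrid_indices(per_axis=3)
    return transfer_population(index_model, run_config, patient_ids=ids,
                               scenarios=scenarios)


@pytest.fixture(scope="session")
def toy_planted():
    return hx.make_fixture("toy-narx-planted", seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(BASE_SEED)
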