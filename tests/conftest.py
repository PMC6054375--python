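"""Shared fixtures.

Everything is generated programmatically from the shipped geometries
and the synthetic-data generators with a fixed seed; the expensive
60-year scenario projections are session-scoped and shared between the
directionality, diagnostics, and economics tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from baltisim.ecosystem import EcosystemParams, Simulation
from baltisim.groups import default_availability, default_groups
from baltisim.model_domain import load_builtin_geometry
from baltisim.scenario_engine import (
    ExperimentConfig,
    applicable_scenarios,
    run_projection,
    setup_simulation,
)
from baltisim.synthetic_forcing import (
    DepositionParams,
    InitialConditionParams,
    LoadParams,
    PhysicsParams,
    deposition_flux,
    generate_initial_conditions,
    generate_loads,
    generate_physics,
)

SEED = 1


@pytest.fixture(scope="session")
def mini8():
    return load_builtin_geometry("mini8")


@pytest.fixture(scope="session")
def baltic29():
    return load_builtin_geometry("baltic29")


@pytest.fixture(scope="session")
def groups():
    return default_groups()


@pytest.fixture(scope="session")
def avail():
    return default_availability()


@pytest.fixture(scope="session")
def forcing(mini8):
    return generate_physics(mini8, PhysicsParams(), SEED)


@pytest.fixture(scope="session")
def load_table(mini8):
    return generate_loads(mini8, LoadParams(), SEED)


@pytest.fixture(scope="session")
def dep_flux(mini8):
    return deposition_flux(mini8, DepositionParams())


@pytest.fixture(scope="session")
def initial_conditions(mini8, groups, forcing):
    return generate_initial_conditions(
        mini8, groups, InitialConditionParams(), SEED, physics=forcing
    )


@pytest.fixture(scope="session")
def experiment_config(mini8, groups, avail):
    return ExperimentConfig(geometry=mini8, groups=groups, avail=avail, seed=SEED)


@pytest.fixture(scope="session")
def scenario_specs(mini8):
    return applicable_scenarios(mini8)


@pytest.fixture(scope="session")
def scenario_runs(experiment_config, scenario_specs):
    """The exemplar scenario suite: status quo plus the directionality set.

    Six 60-year projections sharing one forcing seed; by far the most
    expensive fixture, so it is computed once per session.
    """
    sim_ic = setup_simulation(experiment_config)
    names = [
        "status_quo",
        "s2_denmark",
        "s3_dk_se_de",
        "s5_pan_baltic",
        "s6_cod_half_f",
        "s10_max_f",
    ]
    return {
        name: run_projection(experiment_config, scenario_specs[name], sim_ic)
        for name in names
    }


@pytest.fixture(scope="session")
def closed_system_run(mini8, groups, avail, forcing, load_table, dep_flux):
    """Ten years with every external nitrogen source and sink disabled."""
    params = EcosystemParams(
        rivers_enabled=False,
        deposition_enabled=False,
        boundary_open=False,
        fishing_enabled=False,
    )
    params.sinks.burial_fraction = 0.0
    params.sinks.denit_rate = 0.0
    ic = generate_initial_conditions(
        mini8, groups, InitialConditionParams(), SEED, physics=forcing
    )
    sim = Simulation(mini8, groups, avail, forcing, load_table, dep_flux, params)
    result = sim.run(ic, 10, track_daily=True)
    return sim, ic, result
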