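"""Shared fixtures: study systems reused across the suite.

The oracle-validation fluid is a single-species Lennard-Jones solvent at
moderate density (rho sigma^3 ~ 0.28), where both the Widom and BAR
estimators converge quickly and serve as ground truth for the ER functional.
Expensive Monte Carlo runs are session-scoped.
"""

from __future__ import annotations

import numpy as np
import pytest

from ersolv import (
    SoluteSite,
    SoluteSpec,
    SpeciesSpec,
    SystemSpec,
    build_configuration,
    build_mesh,
    histogram_reference,
    histogram_solution,
    run_sampling,
    sample_insertions,
    sample_solution_energies,
)

TEMPERATURE = 298.15


def make_fluid_spec(box_length=22.0, n_water=110, solute=None, r_cut=8.0,
                    coulomb="none"):
    return SystemSpec(
        box_length=box_length,
        temperature=TEMPERATURE,
        species=(SpeciesSpec("water", n_water, 0.0, 3.0, 0.5),),
        solute=solute,
        r_cut=r_cut,
        coulomb_scheme=coulomb,
    )


@pytest.fixture(scope="session")
def fluid_spec():
    return make_fluid_spec()


@pytest.fixture(scope="session")
def lj_solute():
    return SoluteSpec(sites=(SoluteSite((0.0, 0.0, 0.0), 0.0, 3.3, 0.3),))


@pytest.fixture(scope="session")
def reference_traj(fluid_spec):
    """Equilibrated reference-system (no solute) trajectory."""
    traj = build_configuration(fluid_spec, seed=101)
    traj = run_sampling(traj, 400, 400, seed=102)
    return run_sampling(traj, 2500, 10, seed=103)


@pytest.fixture(scope="session")
def solution_traj(fluid_spec, lj_solute):
    """Equilibrated solution-system trajectory (LJ solute at full coupling)."""
    spec = fluid_spec.with_solute(lj_solute)
    traj = build_configuration(spec, seed=201)
    traj = run_sampling(traj, 400, 400, seed=202)
    return run_sampling(traj, 3000, 10, seed=203)


@pytest.fixture(scope="session")
def energy_mesh():
    return build_mesh(-12.0, 20.0, 150, 40)


@pytest.fixture(scope="session")
def moderate_data(reference_traj, solution_traj, lj_solute, energy_mesh):
    """Histograms + samples for the moderately coupled LJ solute."""
    ins = sample_insertions(reference_traj, lj_solute, 60, seed=301)
    sol = sample_solution_energies(solution_traj)
    return {
        "insertions": ins,
        "solution": sol,
        "ref_stats": histogram_reference(ins, energy_mesh),
        "sol_dist": histogram_solution(sol, energy_mesh),
        "mesh": energy_mesh,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
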