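"""Energy sampling: solution pair energies, test insertions, RDF."""

import numpy as np
import pytest

from ersolv import (
    SoluteSite,
    SoluteSpec,
    SpeciesSpec,
    SystemSpec,
    build_configuration,
    radial_distribution,
    run_sampling,
    sample_insertions,
    sample_solution_energies,
)
from ersolv.constants import COULOMB_K, R_KCAL
from ersolv.system import Trajectory

from conftest import TEMPERATURE


def brute_force_solute_energy(pos, species, spec, solute_sites, L, rc, coulomb):
    """Independent plain-python oracle for the total solute-solvent energy."""
    total = 0.0
    for j in range(len(pos)):
        sp = spec.species[species[j]]
        for site in solute_sites:
            d = pos[j] - site["pos"]
            d = d - L * np.floor(d / L + 0.5)
            r = float(np.sqrt((d**2).sum()))
            if r >= rc:
                continue
            sig = 0.5 * (sp.lj_sigma + site["sigma"])
            eps = np.sqrt(sp.lj_epsilon * site["epsilon"])
            sr6 = (sig / r) ** 6
            sr6c = (sig / rc) ** 6
            total += 4 * eps * (sr6**2 - sr6) - 4 * eps * (sr6c**2 - sr6c)
            if coulomb:
                qq = COULOMB_K * sp.charge * site["charge"]
                total += qq * (1 / r - 1 / rc + (r - rc) / rc**2)
    return total


def two_species_system(coulomb="shifted-force"):
    solute = SoluteSpec(sites=(
        SoluteSite((0.0, 0.0, 0.0), 0.2, 3.4, 0.3),
        SoluteSite((1.2, 0.0, 0.0), -0.2, 3.0, 0.2),
    ))
    return SystemSpec(
        box_length=14.0, temperature=TEMPERATURE,
        species=(
            SpeciesSpec("cation", 3, 0.3, 2.8, 0.2),
            SpeciesSpec("anion", 3, -0.3, 3.6, 0.2),
        ),
        solute=solute, r_cut=6.0, coulomb_scheme=coulomb,
    )


class TestSolutionEnergies:
    def test_bookkeeping_two_species(self):
        spec = two_species_system()
        traj = run_sampling(build_configuration(spec, 1), 40, 10, seed=2)
        s = sample_solution_energies(traj)
        assert s.energies["cation"].shape == (4, 3)
        assert s.energies["anion"].shape == (4, 3)

    def test_totals_match_brute_force_oracle(self):
        spec = two_species_system()
        traj = run_sampling(build_configuration(spec, 1), 30, 10, seed=2)
        s = sample_solution_energies(traj)
        centre = spec.box_length / 2
        sites = [
            {"pos": np.array(st.offset) + centre, "charge": st.charge,
             "sigma": st.lj_sigma, "epsilon": st.lj_epsilon}
            for st in spec.solute.sites
        ]
        for f in range(traj.n_frames):
            ref = brute_force_solute_energy(
                traj.positions(f), traj.species_index, spec, sites,
                spec.box_length, spec.r_cut, True)
            assert s.totals[f] == pytest.approx(ref, abs=1e-9)

    def test_species_sums_equal_total(self):
        spec = two_species_system()
        traj = run_sampling(build_configuration(spec, 1), 40, 10, seed=3)
        s = sample_solution_energies(traj)
        summed = sum(a.sum(axis=1) for a in s.energies.values())
        np.testing.assert_allclose(summed, s.totals, atol=1e-9)

    def test_distant_single_solvent_gives_zero(self):
        spec = SystemSpec(
            box_length=20.0, temperature=TEMPERATURE,
            species=(SpeciesSpec("water", 1, 0.0, 3.0, 0.5),),
            solute=SoluteSpec(sites=(SoluteSite((0.0, 0.0, 0.0), 0.0, 3.0, 0.5),)),
            r_cut=5.0,
        )
        # place the lone solvent particle in a corner, > r_cut from the centre
        pos = np.array([[0.5, 0.5, 0.5]])
        traj = Trajectory(spec=spec, frames=[pos],
                          species_index=np.zeros(1, np.int64))
        s = sample_solution_energies(traj)
        assert s.totals[0] == 0.0

    def test_requires_solute(self, reference_traj):
        with pytest.raises(ValueError, match="without a solute"):
            sample_solution_energies(reference_traj)


class TestInsertions:
    def test_empty_box_all_zero(self):
        spec = SystemSpec(
            box_length=12.0, temperature=TEMPERATURE,
            species=(SpeciesSpec("water", 0, 0.0, 3.0, 0.5),), r_cut=5.0,
        )
        traj = run_sampling(build_configuration(spec, 1), 10, 5, seed=2)
        ins = sample_insertions(
            traj, SoluteSpec(sites=(SoluteSite((0, 0, 0), 0.0, 3.0, 0.5),)),
            20, seed=3)
        assert np.all(ins.totals == 0.0)

    def test_ideal_gas_widom_factor_is_one(self):
        """Non-interacting points: <exp(-beta nu)> = 1 exactly."""
        spec = SystemSpec(
            box_length=12.0, temperature=TEMPERATURE,
            species=(SpeciesSpec("water", 30, 0.0, 3.0, 0.0),), r_cut=5.0,
        )
        traj = run_sampling(build_configuration(spec, 1), 20, 5, seed=2)
        ins = sample_insertions(
            traj, SoluteSpec(sites=(SoluteSite((0, 0, 0), 0.0, 3.0, 0.5),)),
            50, seed=3)
        beta = 1.0 / (R_KCAL * TEMPERATURE)
        assert np.exp(-beta * ins.totals).mean() == pytest.approx(1.0)

    def test_overlap_fraction_positive_in_dense_fluid(self, reference_traj, lj_solute):
        ins = sample_insertions(reference_traj, lj_solute, 20, seed=5)
        assert (ins.totals > 20.0).mean() > 0.0

    def test_deterministic_given_seed(self, reference_traj, lj_solute):
        a = sample_insertions(reference_traj, lj_solute, 5, seed=9)
        b = sample_insertions(reference_traj, lj_solute, 5, seed=9)
        np.testing.assert_array_equal(a.totals, b.totals)
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_rejects_solution_trajectory(self, solution_traj, lj_solute):
        with pytest.raises(ValueError, match="without the solute"):
            sample_insertions(solution_traj, lj_solute, 5, seed=1)


class TestRadialDistribution:
    def test_ideal_gas_is_flat(self):
        spec = SystemSpec(
            box_length=14.0, temperature=TEMPERATURE,
            species=(SpeciesSpec("water", 60, 0.0, 3.0, 0.0),), r_cut=6.0,
        )
        # all-relocation moves make ideal-gas frames independent draws, so
        # the per-bin counting error really is binomial
        traj = run_sampling(build_configuration(spec, 1), 500, 5, seed=2,
                            max_disp=2.0, jump_fraction=1.0)
        r, g = radial_distribution(traj, "water", "water", 0.35, 7.0)
        # each bin within 3x its binomial error of unity
        rho = 59 / spec.box_length**3
        shell = 4 / 3 * np.pi * ((r + 0.175) ** 3 - (r - 0.175) ** 3)
        n_pairs = traj.n_frames * 60 * rho * shell
        sel = n_pairs > 25
        assert np.all(np.abs(g[sel] - 1.0) < 3.5 / np.sqrt(n_pairs[sel]))

    def test_hard_core_region_empty(self, reference_traj):
        r, g = radial_distribution(reference_traj, "water", "water", 0.2, 8.0)
        assert np.all(g[r < 2.4] == 0.0)

    def test_swapped_selections_identical(self):
        spec = SystemSpec(
            box_length=14.0, temperature=TEMPERATURE,
            species=(
                SpeciesSpec("water", 40, 0.0, 3.0, 0.3),
                SpeciesSpec("anion", 10, 0.0, 3.4, 0.3),
            ),
            r_cut=6.0,
        )
        traj = run_sampling(build_configuration(spec, 1), 100, 20, seed=2)
        r1, g1 = radial_distribution(traj, "water", "anion", 0.25, 6.0)
        r2, g2 = radial_distribution(traj, "anion", "water", 0.25, 6.0)
        np.testing.assert_allclose(g1, g2, rtol=1e-12)

    def test_invalid_inputs(self, reference_traj):
        with pytest.raises(ValueError, match="dr"):
            radial_distribution(reference_traj, "water", "water", -0.1, 5.0)
        with pytest.raises(ValueError, match="r_max"):
            radial_distribution(reference_traj, "water", "water", 0.1, 50.0)
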