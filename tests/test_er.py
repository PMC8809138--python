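"""ER functional limits, corrections, and decomposition invariants."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import erfc

from ersolv import (
    build_mesh,
    dispersion_tail_correction,
    er_free_energy,
    self_energy_correction,
)
from ersolv.constants import COULOMB_K, R_KCAL, WIGNER_XI
from ersolv.distributions import EnergyMesh, ReferenceStatistics, SpeciesDistribution
from ersolv.er import EmptyReferenceBinError

from conftest import TEMPERATURE

RT = R_KCAL * TEMPERATURE
BETA = 1.0 / RT


def gaussian_pair(mesh, mu_sol, mu_ref, sigma, mass):
    sol = {"water": SpeciesDistribution.from_gaussian(mesh, "water", mu_sol, sigma, mass)}
    ref = {"water": ReferenceStatistics.from_gaussian(mesh, "water", mu_ref, sigma, mass)}
    return sol, ref


class TestFunctionalLimits:
    def test_null_solute_gives_only_corrections(self):
        mesh = build_mesh(-5.0, 20.0, 100, 10)
        b = mesh.assign(np.array([0.0]))[0]
        dens = np.zeros(mesh.n_bins)
        dens[b] = 6.0 / mesh.widths[b]
        sol = SpeciesDistribution(mesh, "water", dens, 0.0, 1,
                                  np.zeros(mesh.n_bins + 1))
        ref = ReferenceStatistics(mesh, "water", dens.copy(), 0.0, 50,
                                  np.zeros(mesh.n_bins + 1), second_moment=None)
        res = er_free_energy({"water": sol}, {"water": ref}, TEMPERATURE,
                             self_energy=0.25, tail_correction=-0.4)
        assert res.dG_total == pytest.approx(0.25 - 0.4, abs=1e-12)

    def test_identical_distributions_reduce_to_mean_energy(self):
        """rho = rho0 means no solvent reorganization: dG_i = <nu>_i exactly."""
        mesh = build_mesh(-30.0, 20.0, 1500, 40)
        sol, ref = gaussian_pair(mesh, -2.0, -2.0, 0.5, 8.0)
        res = er_free_energy(sol, ref, TEMPERATURE)
        t = res.species_terms["water"]
        assert t.reorganization == pytest.approx(0.0, abs=1e-12)
        assert res.dG_total == pytest.approx(t.mean_interaction, abs=1e-12)
        assert np.all((t.f_profile == 0) | np.isnan(t.f_profile))

    def test_gaussian_linear_response_limit(self):
        """Equal-variance Gaussians: dG equals (<nu> + <nu>0)/2 (LRA)."""
        mesh = build_mesh(-30.0, 20.0, 3000, 40)
        n, sigma, mu0 = 8.0, 0.6, -2.0
        mu1 = mu0 - BETA * sigma**2
        sol, ref = gaussian_pair(mesh, mu1, mu0, sigma, n)
        res = er_free_energy(sol, ref, TEMPERATURE)
        lra = 0.5 * (n * mu1 + n * mu0)
        assert res.dG_total == pytest.approx(lra, abs=5e-3)

    @pytest.mark.parametrize("lam", [0.1, 0.05])
    def test_weak_coupling_first_order_exact(self, lam):
        """dG(lambda)/lambda -> integral eps rho0 as the coupling vanishes."""
        mesh = build_mesh(-30.0, 20.0, 3000, 40)
        n, sigma, mu0 = 8.0, 0.8, -1.5
        # linear-response solution distribution for a coupling-scaled field
        sol, ref = gaussian_pair(mesh, lam * mu0 - lam**2 * BETA * sigma**2,
                                 lam * mu0, lam * sigma, n)
        res = er_free_energy(sol, ref, TEMPERATURE)
        mean_ref = n * lam * mu0
        # first-order term dominates; remainder is O(lambda^2)
        assert abs(res.dG_total - mean_ref) < 1.2 * lam**2 * BETA * sigma**2 * n

    def test_additivity_machine_precision(self, moderate_data):
        res = er_free_energy(
            moderate_data["sol_dist"], moderate_data["ref_stats"], TEMPERATURE,
            self_energy=0.123, tail_correction=-0.456,
            regularize_empty_reference=True)
        total = sum(t.dG for t in res.species_terms.values()) + 0.123 - 0.456
        assert res.dG_total == pytest.approx(total, abs=1e-12)
        for t in res.species_terms.values():
            assert t.dG == pytest.approx(
                t.mean_interaction + t.reorganization, abs=1e-12)


class TestFunctionalErrors:
    def test_species_mismatch(self):
        mesh = build_mesh(-5.0, 20.0, 10, 5)
        sol, _ = gaussian_pair(mesh, -1.0, -1.0, 0.3, 2.0)
        _, ref = gaussian_pair(mesh, -1.0, -1.0, 0.3, 2.0)
        ref = {"anion": ref["water"]}
        with pytest.raises(ValueError, match="species mismatch"):
            er_free_energy(sol, ref, TEMPERATURE)

    def test_mesh_mismatch(self):
        sol, _ = gaussian_pair(build_mesh(-5.0, 20.0, 10, 5), -1.0, -1.0, 0.3, 2.0)
        _, ref = gaussian_pair(build_mesh(-5.0, 20.0, 12, 5), -1.0, -1.0, 0.3, 2.0)
        with pytest.raises(ValueError, match="mesh"):
            er_free_energy(sol, ref, TEMPERATURE)

    def test_empty_reference_bin_names_bin_and_regularization_works(self):
        mesh = EnergyMesh(edges=np.array([-4.0, -2.0, 0.0, 20.0]))
        dens = np.array([1.0, 0.0, 0.0])
        sol = SpeciesDistribution(mesh, "water", dens, 0.0, 1,
                                  np.array([-3.0 * 2.0, 0.0, 0.0, 0.0]))
        ref_dens = np.array([0.0, 1.0, 0.0])
        ref = ReferenceStatistics(mesh, "water", ref_dens, 0.0, 100,
                                  np.array([0.0, -1.0 * 2.0, 0.0, 0.0]),
                                  second_moment=None)
        with pytest.raises(EmptyReferenceBinError, match=r"\[-4, -2\)"):
            er_free_energy({"water": sol}, {"water": ref}, TEMPERATURE)
        res = er_free_energy({"water": sol}, {"water": ref}, TEMPERATURE,
                             regularize_empty_reference=True)
        assert res.regularized_bins["water"] == 1
        assert np.isfinite(res.dG_total)


class TestSelfEnergy:
    def test_neutral_solute_is_zero(self):
        assert self_energy_correction(0.0, 32.5) == 0.0

    def test_vanishes_for_large_box(self):
        assert self_energy_correction(1.0, 1e9) == pytest.approx(0.0, abs=1e-5)

    def test_against_ewald_lattice_sum_oracle(self):
        """Wigner constant from a direct Ewald summation at convergence."""
        alpha = 3.0
        n = np.arange(-6, 7)
        X, Y, Z = np.meshgrid(n, n, n, indexing="ij")
        r = np.sqrt(X**2 + Y**2 + Z**2).ravel()
        r = r[r > 0]
        k2 = (X**2 + Y**2 + Z**2).ravel().astype(float)
        k2 = k2[k2 > 0]
        xi = (
            np.sum(erfc(alpha * r) / r)
            + np.sum(np.exp(-np.pi**2 * k2 / alpha**2) / (np.pi * k2))
            - 2 * alpha / np.sqrt(np.pi)
            - np.pi / alpha**2
        )
        assert xi == pytest.approx(WIGNER_XI, abs=1e-6)
        q, L = 1.0, 32.5
        expected = xi * COULOMB_K * q**2 / (2 * L)
        assert self_energy_correction(q, L) == pytest.approx(expected, rel=1e-6)

    def test_external_mode(self):
        assert self_energy_correction(0.5, 30.0, mode="external", value=-0.017) == -0.017
        with pytest.raises(ValueError):
            self_energy_correction(0.5, 30.0, mode="external")


class TestDispersionTail:
    def test_zero_density_zero(self):
        assert dispersion_tail_correction({"w": 0.0}, {"w": [3.0]}, {"w": [0.5]}, 9.0) == 0.0

    def test_vanishes_for_large_cutoff(self):
        v = dispersion_tail_correction({"w": 0.03}, {"w": [3.0]}, {"w": [0.5]}, 1e4)
        assert v == pytest.approx(0.0, abs=1e-9)

    def test_closed_form_matches_quadrature(self):
        rho, sigma, eps, rc = 0.0267, 3.1, 0.45, 8.0
        closed = dispersion_tail_correction({"w": rho}, {"w": [sigma]}, {"w": [eps]}, rc)
        integrand = lambda r: 4 * eps * ((sigma / r) ** 12 - (sigma / r) ** 6) * r**2
        val, _ = quad(integrand, rc, np.inf)
        assert closed == pytest.approx(4 * np.pi * rho * val, rel=1e-10)
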