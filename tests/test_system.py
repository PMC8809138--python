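"""Monte Carlo engine: spec validation, packing, pair energies, sampling."""

import numpy as np
import pytest

from ersolv import (
    SiteGroup,
    SpeciesSpec,
    SystemSpec,
    build_configuration,
    pair_energy,
    run_sampling,
)
from ersolv.constants import COULOMB_K, R_KCAL
from ersolv.engine import PackingError

from conftest import TEMPERATURE, make_fluid_spec


def ideal_gas_spec(n=20, box=12.0):
    return SystemSpec(
        box_length=box, temperature=TEMPERATURE,
        species=(SpeciesSpec("water", n, 0.0, 3.0, 0.0),),
        r_cut=5.0,
    )


class TestSpecValidation:
    def test_r_cut_beyond_half_box_rejected(self):
        with pytest.raises(ValueError, match="r_cut"):
            make_fluid_spec(box_length=10.0, r_cut=6.0)

    def test_charged_system_must_be_neutral_with_electrostatics(self):
        with pytest.raises(ValueError, match="charge"):
            SystemSpec(
                box_length=20.0, temperature=300.0,
                species=(SpeciesSpec("cation", 3, 1.0, 3.0, 0.1),),
                r_cut=8.0, coulomb_scheme="shifted-force",
            )

    def test_unknown_style_rejected(self):
        with pytest.raises(ValueError, match="style"):
            SpeciesSpec("x", 1, style="soft")

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError, match="count"):
            SpeciesSpec("x", -1)


class TestBuildConfiguration:
    def test_empty_spec_gives_empty_frame(self):
        spec = ideal_gas_spec(n=0)
        traj = build_configuration(spec, seed=1)
        assert traj.positions(0).shape == (0, 3)

    def test_deterministic_for_seed(self):
        spec = make_fluid_spec(n_water=50)
        a = build_configuration(spec, seed=5)
        b = build_configuration(spec, seed=5)
        np.testing.assert_array_equal(a.positions(0), b.positions(0))

    def test_no_hard_overlaps_exhaustive_pair_scan(self):
        spec = SystemSpec(
            box_length=30.0, temperature=TEMPERATURE,
            species=(SpeciesSpec("water", 100, 0.0, 3.0, 0.5),),
            r_cut=9.0,
        )
        pos = build_configuration(spec, seed=7).positions(0)
        L = spec.box_length
        d = pos[:, None, :] - pos[None, :, :]
        d -= L * np.floor(d / L + 0.5)
        r = np.sqrt((d**2).sum(-1))
        iu = np.triu_indices(len(pos), k=1)
        assert r[iu].min() >= 0.7 * 3.0

    def test_overpacked_system_raises(self):
        spec = SystemSpec(
            box_length=8.0, temperature=TEMPERATURE,
            species=(SpeciesSpec("water", 300, 0.0, 3.0, 0.5),),
            r_cut=4.0,
        )
        with pytest.raises(PackingError, match="density"):
            build_configuration(spec, seed=1)


class TestPairEnergy:
    def test_lj_zero_crossing_at_sigma(self):
        a = SiteGroup.single([0.0, 0.0, 0.0], sigma=3.0, epsilon=0.5)
        b = SiteGroup.single([3.0, 0.0, 0.0], sigma=3.0, epsilon=0.5)
        # at r = sigma the bare LJ vanishes; only the (tiny) cutoff shift remains
        e = pair_energy(a, b, box_length=40.0, r_cut=12.0)
        assert abs(e) < 1e-3

    def test_lj_minimum_matches_closed_form(self):
        sigma, eps, rc = 3.0, 0.5, 12.0
        r = 2 ** (1 / 6) * sigma
        a = SiteGroup.single([0.0, 0.0, 0.0], sigma=sigma, epsilon=eps)
        b = SiteGroup.single([r, 0.0, 0.0], sigma=sigma, epsilon=eps)
        sr6 = (sigma / rc) ** 6
        expected = -eps - 4 * eps * (sr6**2 - sr6)
        assert pair_energy(a, b, 40.0, rc) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("r", [12.0, 15.0, 19.0])
    def test_exactly_zero_beyond_cutoff(self, r):
        a = SiteGroup.single([0.0, 0.0, 0.0], charge=1.0, sigma=3.0, epsilon=0.5)
        b = SiteGroup.single([r, 0.0, 0.0], charge=-1.0, sigma=3.0, epsilon=0.5)
        assert pair_energy(a, b, 40.0, 12.0, "shifted-force") == 0.0

    def test_coincident_sites_raise(self):
        a = SiteGroup.single([1.0, 1.0, 1.0])
        with pytest.raises(ValueError, match="coincident"):
            pair_energy(a, a, 40.0, 12.0)

    def test_shifted_force_coulomb_value(self):
        rc, r = 10.0, 4.0
        a = SiteGroup.single([0.0, 0.0, 0.0], charge=0.5, epsilon=0.0)
        b = SiteGroup.single([r, 0.0, 0.0], charge=-1.0, epsilon=0.0)
        expected = COULOMB_K * (-0.5) * (1 / r - 1 / rc + (r - rc) / rc**2)
        assert pair_energy(a, b, 30.0, rc, "shifted-force") == pytest.approx(
            expected, rel=1e-12)

    def test_repulsive_style_has_no_attraction(self):
        r = 2 ** (1 / 6) * 3.0
        a = SiteGroup.single([0.0, 0.0, 0.0], sigma=3.0, epsilon=0.5, style="repulsive")
        b = SiteGroup.single([r, 0.0, 0.0], sigma=3.0, epsilon=0.5)
        assert pair_energy(a, b, 40.0, 12.0) > 0.0

    def test_hard_style_is_step_function(self):
        a = SiteGroup.single([0.0, 0.0, 0.0], sigma=3.0, style="hard")
        inside = SiteGroup.single([2.5, 0.0, 0.0], sigma=3.0)
        outside = SiteGroup.single([3.5, 0.0, 0.0], sigma=3.0)
        assert pair_energy(a, inside, 40.0, 12.0) >= 1e5
        assert pair_energy(a, outside, 40.0, 12.0) == 0.0


class TestRunSampling:
    def test_ideal_gas_accepts_every_move(self):
        traj = build_configuration(ideal_gas_spec(), seed=3)
        out = run_sampling(traj, 50, 10, seed=4)
        assert out.acceptance_rate == 1.0

    def test_bit_identical_for_same_seed(self, fluid_spec):
        start = build_configuration(fluid_spec, seed=9)
        a = run_sampling(start, 100, 20, seed=10)
        b = run_sampling(start, 100, 20, seed=10)
        assert a.n_frames == b.n_frames
        for fa, fb in zip(a.frames, b.frames):
            np.testing.assert_array_equal(fa, fb)

    def test_nonpositive_sweeps_rejected(self):
        traj = build_configuration(ideal_gas_spec(), seed=3)
        with pytest.raises(ValueError):
            run_sampling(traj, 0, 1, seed=1)

    def test_ideal_gas_positions_uniform(self):
        """Long ideal-gas run: coordinates uniform over the box (chi-square)."""
        from scipy.stats import chisquare

        spec = ideal_gas_spec(n=20, box=12.0)
        traj = build_configuration(spec, seed=11)
        out = run_sampling(traj, 2000, 5, seed=12, max_disp=2.0)
        xs = np.concatenate([f[:, 0] for f in out.frames])
        counts, _ = np.histogram(xs, bins=8, range=(0.0, spec.box_length))
        stat, p = chisquare(counts)
        assert p > 0.01

    def test_two_particle_boltzmann_distribution(self):
        """Sampled pair distances follow exp(-beta u(r)) r^2 (KS at alpha=0.01)."""
        sigma, eps, rc, L = 3.0, 0.5, 5.0, 11.0
        spec = SystemSpec(
            box_length=L, temperature=TEMPERATURE,
            species=(SpeciesSpec("water", 2, 0.0, sigma, eps),),
            r_cut=rc,
        )
        traj = build_configuration(spec, seed=21)
        out = run_sampling(traj, 130000, 6, seed=22, max_disp=1.5)
        d = np.array([f[0] - f[1] for f in out.frames])
        d -= L * np.floor(d / L + 0.5)
        r = np.sqrt((d**2).sum(axis=1))
        r = r[r < L / 2]
        assert len(r) >= 1e4
        # independent model: truncated-shifted LJ Boltzmann density on [0, L/2]
        beta = 1.0 / (R_KCAL * TEMPERATURE)
        grid = np.linspace(1e-3, L / 2, 4000)
        sr6 = (sigma / grid) ** 6
        shift = 4 * eps * ((sigma / rc) ** 12 - (sigma / rc) ** 6)
        u = np.where(grid < rc, 4 * eps * (sr6**2 - sr6) - shift, 0.0)
        pdf = grid**2 * np.exp(-beta * np.clip(u, -50, 50))
        cdf = np.cumsum(pdf)
        cdf /= cdf[-1]
        emp = np.searchsorted(np.sort(r), grid, side="right") / len(r)
        ks = np.abs(emp - cdf).max()
        assert ks < 1.628 / np.sqrt(len(r))
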