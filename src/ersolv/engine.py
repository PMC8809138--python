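"""Configuration building, pair energies and Metropolis Monte Carlo sampling.

The engine samples the canonical (NVT) ensemble by single-particle
displacement Metropolis moves.  A solute, when present, is rigid and fixed at
the box centre, which matches the fixed-solute definition of the solvation
free energy used throughout the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .constants import COULOMB_K, beta as _beta
from .system import (
    STYLE_CODE,
    SoluteSpec,
    SystemSpec,
    Trajectory,
    mix_styles,
    solute_site_positions,
)

__all__ = [
    "SiteGroup",
    "pair_energy",
    "build_configuration",
    "run_sampling",
    "PackingError",
]

#: Hard-overlap exclusion used when packing initial configurations, as a
#: fraction of the mixed Lennard-Jones sigma.
OVERLAP_FRACTION = 0.7


class PackingError(RuntimeError):
    pass


def _coul_flag(scheme: str) -> int:
    return _kernels.COUL_SHIFTED_FORCE if scheme == "shifted-force" else _kernels.COUL_NONE


def _mixed_tables(sig_a, eps_a, q_a, style_a, sig_b, eps_b, q_b, style_b, r_cut):
    """Lorentz-Berthelot mixed pair tables plus style codes and cutoff shifts."""
    sig_mix = 0.5 * (sig_a[:, None] + sig_b[None, :])
    eps_mix = np.sqrt(eps_a[:, None] * eps_b[None, :])
    qq = COULOMB_K * q_a[:, None] * q_b[None, :]
    style = mix_styles(style_a, style_b)
    sr6 = (sig_mix / r_cut) ** 6
    shift = np.where(
        style == STYLE_CODE["repulsive"],
        4.0 * eps_mix * sr6 * sr6,
        4.0 * eps_mix * (sr6 * sr6 - sr6),
    )
    shift[style == STYLE_CODE["hard"]] = 0.0
    return sig_mix**2, eps_mix, qq, shift, style


def _species_arrays(spec: SystemSpec):
    sig = np.array([s.lj_sigma for s in spec.species], dtype=float)
    eps = np.array([s.lj_epsilon for s in spec.species], dtype=float)
    q = np.array([s.charge for s in spec.species], dtype=float)
    style = np.array([STYLE_CODE[s.style] for s in spec.species], dtype=np.int64)
    return sig, eps, q, style


def _species_tables(spec: SystemSpec):
    """Mixed pair-parameter lookup tables for solvent-solvent interactions."""
    sig, eps, q, style = _species_arrays(spec)
    return _mixed_tables(sig, eps, q, style, sig, eps, q, style, spec.r_cut)


def _solute_tables(spec: SystemSpec, solute: SoluteSpec):
    """Mixed pair-parameter tables indexed (species, solute site)."""
    sig, eps, q, style = _species_arrays(spec)
    _, sq, ssig, seps = solute.site_arrays()
    sstyle = solute.site_styles()
    return _mixed_tables(sig, eps, q, style, ssig, seps, sq, sstyle, spec.r_cut)


def _solute_kernel_args(spec: SystemSpec):
    if spec.solute is None:
        spos = np.empty((0, 3))
        n = len(spec.species)
        z = np.empty((n, 0))
        return False, spos, z, z, z, z, np.empty((n, 0), np.int64), 1.0
    spos = solute_site_positions(spec)
    s_sig2, s_eps, s_qq, s_shift, s_style = _solute_tables(spec, spec.solute)
    return True, spos, s_sig2, s_eps, s_qq, s_shift, s_style, spec.solute.coupling


@dataclass(frozen=True)
class SiteGroup:
    """A set of interaction sites (positions in angstrom, LJ + charge)."""

    positions: np.ndarray
    charges: np.ndarray
    sigmas: np.ndarray
    epsilons: np.ndarray
    styles: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.styles is None:
            object.__setattr__(
                self, "styles", np.zeros(len(self.charges), dtype=np.int64)
            )

    @classmethod
    def single(cls, position, charge=0.0, sigma=3.0, epsilon=0.2,
               style="lj") -> "SiteGroup":
        return cls(
            positions=np.asarray(position, dtype=float).reshape(1, 3),
            charges=np.array([charge], dtype=float),
            sigmas=np.array([sigma], dtype=float),
            epsilons=np.array([epsilon], dtype=float),
            styles=np.array([STYLE_CODE[style]], dtype=np.int64),
        )


def pair_energy(
    group_a: SiteGroup,
    group_b: SiteGroup,
    box_length: float,
    r_cut: float,
    coulomb_scheme: str = "none",
) -> float:
    """Total interaction energy between two site groups (kcal/mol).

    Lennard-Jones terms use Lorentz-Berthelot mixing and are truncated and
    shifted to zero at ``r_cut``; Coulomb terms (scheme "shifted-force") use
    the shifted-force form.  Site pairs at or beyond ``r_cut`` contribute
    exactly zero.
    """
    if r_cut > box_length / 2 + 1e-12:
        raise ValueError("r_cut must not exceed box_length/2")
    pa = np.asarray(group_a.positions, dtype=float)
    pb = np.asarray(group_b.positions, dtype=float)
    d = pa[:, None, :] - pb[None, :, :]
    d -= box_length * np.floor(d / box_length + 0.5)
    r2 = np.einsum("ijk,ijk->ij", d, d)
    if np.any(r2 < 1e-20):
        raise ValueError("coincident sites (r = 0) in pair_energy")
    sig2, eps, qq, shift, style = _mixed_tables(
        group_a.sigmas, group_a.epsilons, group_a.charges, group_a.styles,
        group_b.sigmas, group_b.epsilons, group_b.charges, group_b.styles,
        r_cut,
    )
    inside = r2 < r_cut * r_cut
    sr6 = np.where(inside, (sig2 / r2) ** 3, 0.0)
    hard = style == STYLE_CODE["hard"]
    rep = style == STYLE_CODE["repulsive"]
    u = np.where(rep, 4.0 * eps * sr6**2, 4.0 * eps * (sr6**2 - sr6)) - np.where(
        inside, shift, 0.0
    )
    u[hard] = np.where(r2[hard] < sig2[hard], _kernels.HARD_OVERLAP_ENERGY, 0.0)
    u = np.where(inside, u, 0.0)
    e = float(u.sum())
    if coulomb_scheme == "shifted-force":
        r = np.sqrt(r2)
        u_c = np.where(
            inside & ~hard, qq * (1.0 / r - 1.0 / r_cut + (r - r_cut) / r_cut**2), 0.0
        )
        e += float(u_c.sum())
    elif coulomb_scheme != "none":
        raise ValueError(f"unknown coulomb_scheme {coulomb_scheme!r}")
    return e


def build_configuration(spec: SystemSpec, seed: int) -> Trajectory:
    """Place all particles at random without hard overlaps (one-frame trajectory).

    Particles are inserted sequentially at uniform positions; a trial position
    is rejected when any minimum-image distance to an already placed particle
    (or solute site) falls below ``OVERLAP_FRACTION`` times the mixed sigma.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_particles
    spi = spec.species_index_array()
    sig, _, _, style = _species_arrays(spec)
    L = spec.box_length
    pos = np.empty((n, 3))
    if spec.solute is not None:
        spos = solute_site_positions(spec)
        _, _, ssig, _ = spec.solute.site_arrays()
        sstyle = spec.solute.site_styles()
    else:
        spos = np.empty((0, 3))
        ssig = np.empty(0)
        sstyle = np.empty(0, np.int64)
    hard_code = STYLE_CODE["hard"]
    max_attempts = 2000
    for i in range(n):
        placed = False
        for _ in range(max_attempts):
            trial = rng.uniform(0.0, L, size=3)
            ok = True
            if i > 0:
                d = pos[:i] - trial
                d -= L * np.floor(d / L + 0.5)
                r = np.sqrt((d**2).sum(axis=1))
                # hard-sphere pairs must not start overlapped at all
                frac = np.where(
                    (style[spi[:i]] == hard_code) | (style[spi[i]] == hard_code),
                    1.0, OVERLAP_FRACTION)
                cut = frac * 0.5 * (sig[spi[:i]] + sig[spi[i]])
                ok = bool(np.all(r >= cut))
            if ok and spos.shape[0]:
                d = spos - trial
                d -= L * np.floor(d / L + 0.5)
                r = np.sqrt((d**2).sum(axis=1))
                frac = np.where(
                    (sstyle == hard_code) | (style[spi[i]] == hard_code),
                    1.0, OVERLAP_FRACTION)
                cut = frac * 0.5 * (ssig + sig[spi[i]])
                ok = bool(np.all(r >= cut))
            if ok:
                pos[i] = trial
                placed = True
                break
        if not placed:
            density = n / L**3
            raise PackingError(
                f"failed to place particle {i} of {n} after {max_attempts} attempts "
                f"(number density {density:.4f} / A^3 too high for overlap-free packing)"
            )
    return Trajectory(
        spec=spec,
        frames=[pos],
        species_index=spi,
        sweeps_between_frames=0,
        acceptance_rate=1.0,
        seed=seed,
    )


def run_sampling(
    config: Trajectory,
    n_sweeps: int,
    sample_interval: int,
    seed: int,
    max_disp: float = 0.4,
    jump_fraction: float = 0.1,
) -> Trajectory:
    """Metropolis MC from the last frame of ``config``; frames stored every
    ``sample_interval`` sweeps.

    One sweep is N single-particle trial moves (particles picked at random);
    a ``jump_fraction`` of the trials are uniform relocations, which keep
    binding equilibria of strongly attracted species ergodic.  The run is
    bit-reproducible for a given seed.
    """
    if n_sweeps <= 0:
        raise ValueError("n_sweeps must be positive")
    if sample_interval <= 0:
        raise ValueError("sample_interval must be positive")
    spec = config.spec
    if spec.temperature <= 0:
        raise ValueError("temperature must be positive")
    n = spec.n_particles
    spi = config.species_index
    sig2, eps, qq, shift, style = _species_tables(spec)
    has_sol, spos, s_sig2, s_eps, s_qq, s_shift, s_style, coupling = _solute_kernel_args(spec)
    coul = _coul_flag(spec.coulomb_scheme)
    b = _beta(spec.temperature)
    rng = np.random.default_rng(seed)
    pos = config.frames[-1].copy()
    if n == 0:
        nf = n_sweeps // sample_interval
        return Trajectory(
            spec=spec,
            frames=[pos.copy() for _ in range(nf)],
            species_index=spi,
            sweeps_between_frames=sample_interval,
            acceptance_rate=1.0,
            seed=seed,
        )
    frames: list[np.ndarray] = []
    n_acc = 0
    n_moves_total = 0
    n_blocks = n_sweeps // sample_interval
    leftover = n_sweeps - n_blocks * sample_interval
    for _ in range(n_blocks):
        nm = sample_interval * n
        rand = rng.random((nm, 6))
        n_acc += _kernels.mc_chunk(
            pos, spi, sig2, eps, qq, shift, style,
            has_sol, spos, s_sig2, s_eps, s_qq, s_shift, s_style, coupling,
            spec.box_length, spec.r_cut, coul, b, max_disp, jump_fraction, rand)
        n_moves_total += nm
        frames.append(pos.copy())
    if leftover:
        nm = leftover * n
        rand = rng.random((nm, 6))
        n_acc += _kernels.mc_chunk(
            pos, spi, sig2, eps, qq, shift, style,
            has_sol, spos, s_sig2, s_eps, s_qq, s_shift, s_style, coupling,
            spec.box_length, spec.r_cut, coul, b, max_disp, jump_fraction, rand)
        n_moves_total += nm
    acc = n_acc / n_moves_total if n_moves_total else 1.0
    return Trajectory(
        spec=spec,
        frames=frames,
        species_index=spi,
        sweeps_between_frames=sample_interval,
        acceptance_rate=acc,
        seed=seed,
    )
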