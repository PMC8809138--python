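"""Numba kernels for the Monte Carlo engine and energy evaluation.

All kernels use the minimum-image convention in a cubic box of side L and a
truncated-and-shifted Lennard-Jones potential; electrostatics, when enabled
(coul=1), use the shifted-force Coulomb form which brings both the energy and
the force continuously to zero at the cutoff.
"""

import numba as nb
import numpy as np

COUL_NONE = 0
COUL_SHIFTED_FORCE = 1

STYLE_LJ = 0
STYLE_REPULSIVE = 1
STYLE_HARD = 2

#: Energy assigned to a hard-sphere overlap (kcal/mol); effectively infinite
#: at any temperature of interest while keeping arithmetic finite.
HARD_OVERLAP_ENERGY = 1.0e6


@nb.njit(cache=False, inline="always")
def _mi(d, L):
    # minimum image for one coordinate difference
    return d - L * np.floor(d / L + 0.5)


@nb.njit(cache=False, inline="always")
def _pair_u(r2, sig2, eps, qq, shift, rcut, coul, style):
    """Pair energy at squared distance r2 (r2 < rcut^2 assumed)."""
    if style == STYLE_HARD:
        return HARD_OVERLAP_ENERGY if r2 < sig2 else 0.0
    u = 0.0
    if eps > 0.0:
        sr2 = sig2 / r2
        sr6 = sr2 * sr2 * sr2
        if style == STYLE_REPULSIVE:
            u += 4.0 * eps * sr6 * sr6 - shift
        else:
            u += 4.0 * eps * (sr6 * sr6 - sr6) - shift
    if coul == COUL_SHIFTED_FORCE and qq != 0.0:
        r = np.sqrt(r2)
        u += qq * (1.0 / r - 1.0 / rcut + (r - rcut) / (rcut * rcut))
    return u


@nb.njit(cache=False)
def particle_energy(pos, spi, i, rx, ry, rz, sig2_tab, eps_tab, qq_tab, shift_tab,
                    style_tab, L, rcut, coul):
    """Energy of particle i placed at (rx,ry,rz) with all other particles."""
    rcut2 = rcut * rcut
    si = spi[i]
    e = 0.0
    for j in range(pos.shape[0]):
        if j == i:
            continue
        dx = _mi(rx - pos[j, 0], L)
        dy = _mi(ry - pos[j, 1], L)
        dz = _mi(rz - pos[j, 2], L)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < rcut2:
            sj = spi[j]
            e += _pair_u(r2, sig2_tab[si, sj], eps_tab[si, sj], qq_tab[si, sj],
                         shift_tab[si, sj], rcut, coul, style_tab[si, sj])
    return e


@nb.njit(cache=False)
def solute_particle_energy(rx, ry, rz, s, spos, s_sig2, s_eps, s_qq, s_shift,
                           s_style, L, rcut, coul):
    """Solute-particle pair energy for one particle of species s at (rx,ry,rz)."""
    rcut2 = rcut * rcut
    e = 0.0
    for m in range(spos.shape[0]):
        dx = _mi(rx - spos[m, 0], L)
        dy = _mi(ry - spos[m, 1], L)
        dz = _mi(rz - spos[m, 2], L)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < rcut2:
            e += _pair_u(r2, s_sig2[s, m], s_eps[s, m], s_qq[s, m], s_shift[s, m],
                         rcut, coul, s_style[s, m])
    return e


@nb.njit(cache=False)
def frame_solute_energies(pos, spi, spos, s_sig2, s_eps, s_qq, s_shift,
                          s_style, L, rcut, coul, coupling, out):
    """Per-particle solute pair energies for one frame (written into out)."""
    for j in range(pos.shape[0]):
        out[j] = coupling * solute_particle_energy(
            pos[j, 0], pos[j, 1], pos[j, 2], spi[j], spos,
            s_sig2, s_eps, s_qq, s_shift, s_style, L, rcut, coul)


@nb.njit(cache=False)
def mc_chunk(pos, spi, sig2_tab, eps_tab, qq_tab, shift_tab, style_tab,
             has_solute, spos, s_sig2, s_eps, s_qq, s_shift, s_style, coupling,
             L, rcut, coul, beta, max_disp, jump_fraction, rand):
    """Run one chunk of Metropolis single-particle moves.

    Moves are local displacements of size <= max_disp; with probability
    ``jump_fraction`` a move is instead a uniform relocation anywhere in the
    box (a symmetric proposal, so detailed balance is preserved).  Jumps give
    ergodic binding/unbinding of strongly attracted species that local
    diffusion alone equilibrates too slowly.

    ``rand`` has shape (n_moves, 6): particle pick, jump decision, three
    position uniforms, acceptance uniform.  Positions are updated in place;
    the number of accepted moves is returned.
    """
    n = pos.shape[0]
    nacc = 0
    for k in range(rand.shape[0]):
        i = int(rand[k, 0] * n)
        if i >= n:
            i = n - 1
        ox, oy, oz = pos[i, 0], pos[i, 1], pos[i, 2]
        e_old = particle_energy(pos, spi, i, ox, oy, oz, sig2_tab, eps_tab,
                                qq_tab, shift_tab, style_tab, L, rcut, coul)
        if rand[k, 1] < jump_fraction:
            tx = rand[k, 2] * L
            ty = rand[k, 3] * L
            tz = rand[k, 4] * L
        else:
            tx = ox + max_disp * (2.0 * rand[k, 2] - 1.0)
            ty = oy + max_disp * (2.0 * rand[k, 3] - 1.0)
            tz = oz + max_disp * (2.0 * rand[k, 4] - 1.0)
            tx -= L * np.floor(tx / L)
            ty -= L * np.floor(ty / L)
            tz -= L * np.floor(tz / L)
        e_new = particle_energy(pos, spi, i, tx, ty, tz, sig2_tab, eps_tab,
                                qq_tab, shift_tab, style_tab, L, rcut, coul)
        if has_solute:
            s = spi[i]
            e_old += coupling * solute_particle_energy(
                ox, oy, oz, s, spos, s_sig2, s_eps, s_qq, s_shift, s_style, L, rcut, coul)
            e_new += coupling * solute_particle_energy(
                tx, ty, tz, s, spos, s_sig2, s_eps, s_qq, s_shift, s_style, L, rcut, coul)
        de = e_new - e_old
        accept = False
        if de <= 0.0:
            accept = True
        elif rand[k, 5] < np.exp(-beta * de):
            accept = True
        if accept:
            pos[i, 0] = tx
            pos[i, 1] = ty
            pos[i, 2] = tz
            nacc += 1
    return nacc


@nb.njit(cache=False)
def min_pair_distance(pos, L):
    """Smallest minimum-image pair distance over all particle pairs."""
    n = pos.shape[0]
    best = 1.0e30
    for i in range(n):
        for j in range(i + 1, n):
            dx = _mi(pos[i, 0] - pos[j, 0], L)
            dy = _mi(pos[i, 1] - pos[j, 1], L)
            dz = _mi(pos[i, 2] - pos[j, 2], L)
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            if r < best:
                best = r
    return best


@nb.njit(cache=False)
def pair_distance_counts(pos_a, pos_b, same, L, dr, nbins, counts):
    """Histogram of minimum-image pair distances between two selections.

    ``same`` flags identical selections (self pairs excluded, each unordered
    pair counted twice to keep the (a,b)/(b,a) symmetry exact).
    """
    for i in range(pos_a.shape[0]):
        for j in range(pos_b.shape[0]):
            if same and i == j:
                continue
            dx = _mi(pos_a[i, 0] - pos_b[j, 0], L)
            dy = _mi(pos_a[i, 1] - pos_b[j, 1], L)
            dz = _mi(pos_a[i, 2] - pos_b[j, 2], L)
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            b = int(r / dr)
            if b < nbins:
                counts[b] += 1.0
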