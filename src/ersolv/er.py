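"""Energy-representation free-energy functional and additive corrections.

The solvation free energy of a fixed solute is evaluated from the
solution-system distribution rho_i(eps) and the reference-system distribution
rho0_i(eps) of solute-molecule pair energies, species by species:

    dG_i = <nu>_i + RT * integral [ rho_i ln(rho_i/rho0_i) - (rho_i - rho0_i) ] d eps

The first term is the mean solute-solvent interaction energy of species i in
the solution system; the second is the solvent-reorganization free energy, a
relative-entropy-like endpoint functional of the two distributions.  It
vanishes when rho_i = rho0_i, reduces to the linear-response result
(<nu> + <nu>0)/2 for equal-variance Gaussian distributions, and vanishes to
first order in a weak solute-solvent coupling.

In the region where the solution density vanishes -- dominated by the
high-energy overflow bin, i.e. solute-solvent overlap -- the reorganization
term is the cavity (excluded-volume) cost -RT ln P(0), the probability that
a random insertion meets no molecule of the species there.  P(0) is
estimated from the reference-side insertion-count statistics: with mean
overlap count M and count variance V (from the bin-pair second moments) the
count law is closed by the binomial/negative-binomial family matched to
(M, V), giving

    -ln P(0) = M^2 / (M - V) * ln(M / V),

which reduces to the Poisson result M as V -> M, lies above it for the
sub-Poisson counts of a correlated repulsive fluid, and below it for
super-Poisson (clustered) counts.  Periodic-boundary self-energy and
long-range dispersion corrections enter as separate additive terms, so the
species decomposition closes exactly:

    dG_total = sum_i dG_i + dG_self + dG_tail.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

from .constants import COULOMB_K, R_KCAL, WIGNER_XI
from .distributions import EnergyMesh, ReferenceStatistics, SpeciesDistribution

__all__ = [
    "SpeciesTerm",
    "SolvationResult",
    "er_free_energy",
    "self_energy_correction",
    "dispersion_tail_correction",
    "EmptyReferenceBinError",
]


def _region_variance(ref: ReferenceStatistics, region: np.ndarray) -> Optional[float]:
    """Variance of the total insertion count over a bin region, or None."""
    if ref.second_moment is None:
        return None
    m = ref.masses
    cov = ref.second_moment - np.outer(m, m)
    sub = cov[np.ix_(region, region)]
    return float(sub.sum())


def _neg_log_gf(mean: float, variance: Optional[float], phi: float,
                n_insertions: int) -> float:
    """-ln E[phi^N] for the repulsive-region molecule count N.

    The count law is closed by the binomial (V < M) / Poisson (V = M) /
    negative-binomial (V > M) family matched to mean M and variance V; phi is
    the per-molecule Boltzmann factor E[exp(-beta eps)] over the region.
    Without second moments the Poisson form M (1 - phi) is used.
    """
    if mean <= 0.0 or phi >= 1.0:
        return 0.0
    if variance is None or abs(variance - mean) <= 1e-8 * mean:
        return mean * (1.0 - phi)
    if variance <= 0.0:
        # every insertion met the identical count: resolution limit of the sample
        variance = mean / max(n_insertions, 2)
    if variance < mean:
        p = (mean - variance) / mean
        return -(mean / p) * np.log1p(-p * (1.0 - phi))
    a = (variance - mean) / mean**2
    return np.log1p(a * mean * (1.0 - phi)) / a


class EmptyReferenceBinError(ValueError):
    """Solution density present in a bin with zero reference density.

    This is the dominant silent failure mode of insufficient reference-system
    sampling; by default it aborts the evaluation.  Passing
    ``regularize_empty_reference=True`` floors the reference mass instead.
    """


@dataclass
class SpeciesTerm:
    """Per-species pieces of the free-energy functional on the mesh.

    ``energy_terms`` and ``reorg_terms`` are per-bin contributions (finite
    bins then overflow, kcal/mol) to the mean-interaction and reorganization
    parts; their sums give ``mean_interaction`` and ``reorganization`` and
    ``dG = mean_interaction + reorganization`` holds identically.
    ``f_profile`` is the reorganization free energy per molecule, f(eps),
    where the solution density is nonzero (NaN elsewhere).
    """

    species: str
    dG: float
    mean_interaction: float
    reorganization: float
    energy_terms: np.ndarray
    reorg_terms: np.ndarray
    f_profile: np.ndarray


@dataclass
class SolvationResult:
    """Solvation free energy with species decomposition and corrections."""

    temperature: float
    mesh: EnergyMesh
    species_terms: dict[str, SpeciesTerm]
    dG_self: float
    tail_correction: float
    regularized_bins: dict[str, int]

    @property
    def dG_total(self) -> float:
        return float(
            sum(t.dG for t in self.species_terms.values())
            + self.dG_self + self.tail_correction
        )

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self.species_terms)

    def dG_species(self) -> dict[str, float]:
        return {s: t.dG for s, t in self.species_terms.items()}


def er_free_energy(
    solution: Mapping[str, SpeciesDistribution],
    reference: Mapping[str, ReferenceStatistics],
    temperature: float,
    *,
    self_energy: float = 0.0,
    tail_correction: float = 0.0,
    regularize_empty_reference: bool = False,
    regularization_floor: float = 0.5,
) -> SolvationResult:
    """Evaluate the ER functional on matched solution/reference distributions.

    ``regularization_floor`` is the pseudo-count (in insertion counts) used to
    floor empty reference bins when regularization is enabled; its use is
    recorded per species in ``regularized_bins``.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if set(solution) != set(reference):
        raise ValueError(
            f"species mismatch: solution has {sorted(solution)}, "
            f"reference has {sorted(reference)}"
        )
    rt = R_KCAL * temperature
    terms: dict[str, SpeciesTerm] = {}
    regularized: dict[str, int] = {}
    mesh = None
    for sp in solution:
        sol = solution[sp]
        ref = reference[sp]
        if sol.mesh != ref.mesh:
            raise ValueError(f"mesh mismatch between solution and reference for {sp!r}")
        if mesh is None:
            mesh = sol.mesh
        elif sol.mesh != mesh:
            raise ValueError("all species must share one mesh")
        m = sol.masses
        m0 = ref.masses
        # ignore numerically negligible solution mass (< 1e-12 molecules)
        bad = (m > 1e-12 * max(sol.total_mass, 1.0)) & (m0 <= 0)
        n_reg = int(bad.sum())
        if n_reg:
            if not regularize_empty_reference:
                b = int(np.argmax(bad))
                edges = mesh.edges
                lo = edges[b] if b < mesh.n_bins else edges[-1]
                hi = edges[b + 1] if b < mesh.n_bins else np.inf
                raise EmptyReferenceBinError(
                    f"species {sp!r}: solution density present in bin "
                    f"[{lo:g}, {hi:g}) kcal/mol where the reference density is zero; "
                    "increase reference insertions or pass "
                    "regularize_empty_reference=True"
                )
            m0 = m0.copy()
            m0[bad] = regularization_floor / max(ref.n_insertions, 1)
        regularized[sp] = n_reg
        beta = 1.0 / rt
        nb = mesh.n_bins
        # solution-side relative-entropy term wherever both densities exist
        kl = np.zeros_like(m)
        both = (m > 0) & (m0 > 0)
        kl[both] = rt * (m[both] * np.log(m[both] / m0[both]) - m[both] + m0[both])
        # repulsive region: finite bins fully at eps >= 0, plus the overflow bin
        rep = np.append(mesh.edges[:-1] >= 0.0, True)
        ebar0 = np.divide(ref.energy_mass0, m0, out=np.zeros_like(m0),
                          where=m0 > 0)
        with np.errstate(under="ignore"):
            s_w = np.where(rep & (m0 > 0), m0 * -np.expm1(-beta * ebar0), 0.0)
        s_w = np.clip(s_w, 0.0, None)
        mass_rep = float(m0[rep].sum())
        weight_sum = float(s_w.sum())
        a_hat = np.zeros_like(m)
        if mass_rep > 0 and weight_sum > 0:
            phi = 1.0 - weight_sum / mass_rep
            var_rep = _region_variance(ref, rep)
            cavity = rt * _neg_log_gf(mass_rep, var_rep, phi, ref.n_insertions)
            # per-bin shares follow the Poisson (Boltzmann-weighted) pattern so
            # any later energy-domain partition stays additive
            a_hat = cavity * s_w / weight_sum
        # depletion factor: 1 where the solution no longer populates the bin
        # (count statistics rule), 0 where solution and reference agree
        # (solution-side rule); the blend keeps rho = rho0 -> reorg = 0 exact
        alpha = np.zeros_like(m)
        pos0 = m0 > 0
        alpha[pos0] = np.clip(1.0 - m[pos0] / m0[pos0], 0.0, 1.0)
        e_terms = sol.energy_mass
        reorg = np.where(
            rep,
            alpha * a_hat + (1.0 - alpha) * (e_terms + kl) - e_terms,
            kl,
        )
        # attractive bins the solution never populated: Poisson pinning cost
        att_only_ref = (~rep) & (m <= 0) & (m0 > 0)
        reorg[att_only_ref] = rt * m0[att_only_ref]
        f_profile = np.full_like(m, np.nan)
        f_profile[both] = reorg[both] / m[both]
        energy_terms = sol.energy_mass.copy()
        mean_int = float(energy_terms.sum())
        reorg_total = float(reorg.sum())
        terms[sp] = SpeciesTerm(
            species=sp,
            dG=mean_int + reorg_total,
            mean_interaction=mean_int,
            reorganization=reorg_total,
            energy_terms=energy_terms,
            reorg_terms=reorg,
            f_profile=f_profile,
        )
    assert mesh is not None
    return SolvationResult(
        temperature=temperature,
        mesh=mesh,
        species_terms=terms,
        dG_self=self_energy,
        tail_correction=tail_correction,
        regularized_bins=regularized,
    )


def self_energy_correction(
    net_charge: float,
    box_length: float,
    mode: str = "constant",
    value: Optional[float] = None,
) -> float:
    """Periodic-boundary self-energy of a charged solute (kcal/mol).

    mode "constant": cubic-lattice Wigner correction xi * k_e * q^2 / (2 L)
    with xi = -2.837297.  mode "external": return a precomputed value (for
    solutes whose correction was obtained elsewhere, e.g. with multipole
    image terms).  Vanishes for neutral solutes and in the infinite-box limit.
    """
    if box_length <= 0:
        raise ValueError("box_length must be positive")
    if mode == "external":
        if value is None:
            raise ValueError("mode='external' requires a value")
        return float(value)
    if mode != "constant":
        raise ValueError(f"unknown mode {mode!r}")
    return WIGNER_XI * COULOMB_K * net_charge**2 / (2.0 * box_length)


def dispersion_tail_correction(
    densities: Mapping[str, float],
    sigma: Mapping[str, np.ndarray],
    epsilon: Mapping[str, np.ndarray],
    r_cut: float,
) -> float:
    """Long-range Lennard-Jones correction beyond the cutoff (kcal/mol).

    For each species i with number density rho_i (molecules per cubic
    angstrom) and mixed solute-site parameters (sigma, epsilon arrays over
    solute sites), adds 4 pi rho_i * integral_{r_cut}^inf u_LJ(r) r^2 dr in
    closed form:

        16 pi rho_i eps [ sigma^12 / (9 r_c^9) - sigma^6 / (3 r_c^3) ].
    """
    if r_cut <= 0:
        raise ValueError("r_cut must be positive")
    total = 0.0
    for sp, rho in densities.items():
        sig = np.atleast_1d(np.asarray(sigma[sp], dtype=float))
        eps = np.atleast_1d(np.asarray(epsilon[sp], dtype=float))
        term = 16.0 * np.pi * rho * eps * (
            sig**12 / (9.0 * r_cut**9) - sig**6 / (3.0 * r_cut**3)
        )
        total += float(term.sum())
    return total
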