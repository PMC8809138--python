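"""System definitions for the toy solvation model.

The model is deliberately minimal while keeping the statistical structure the
energy-representation analysis needs: a cubic periodic box holding three
single-site solvent species (a neutral "water", cations and anions) and,
optionally, a rigid multi-site solute held at the box centre.  Interactions
are truncated-and-shifted Lennard-Jones with Lorentz-Berthelot mixing plus,
optionally, shifted-force Coulomb electrostatics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "SpeciesSpec",
    "SoluteSite",
    "SoluteSpec",
    "SystemSpec",
    "Trajectory",
]

COULOMB_SCHEMES = ("none", "shifted-force")

#: "lj" is the full 12-6 potential; "repulsive" keeps only the r^-12 wall
#: (a near-WCA particle); "hard" is a hard sphere of diameter lj_sigma.
INTERACTION_STYLES = ("lj", "repulsive", "hard")


@dataclass(frozen=True)
class SpeciesSpec:
    """One single-site solvent species (water, cation or anion).

    Parameters
    ----------
    name:
        Species label used to tag energy samples ("water", "cation", ...).
    count:
        Number of molecules of this species in the box.
    charge:
        Charge in elementary charges.
    lj_sigma, lj_epsilon:
        Lennard-Jones size (angstrom) and well depth (kcal/mol).
    """

    name: str
    count: int
    charge: float = 0.0
    lj_sigma: float = 3.0
    lj_epsilon: float = 0.2
    style: str = "lj"

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError(f"species {self.name!r}: count must be >= 0")
        if self.lj_sigma <= 0:
            raise ValueError(f"species {self.name!r}: lj_sigma must be > 0")
        if self.lj_epsilon < 0:
            raise ValueError(f"species {self.name!r}: lj_epsilon must be >= 0")
        if self.style not in INTERACTION_STYLES:
            raise ValueError(f"species {self.name!r}: style must be one of {INTERACTION_STYLES}")


@dataclass(frozen=True)
class SoluteSite:
    """One rigid interaction site of the solute."""

    offset: tuple[float, float, float]
    charge: float = 0.0
    lj_sigma: float = 3.4
    lj_epsilon: float = 0.3
    style: str = "lj"

    def __post_init__(self) -> None:
        off = np.asarray(self.offset, dtype=float)
        if off.shape != (3,) or not np.all(np.isfinite(off)):
            raise ValueError("site offset must be a finite 3-vector")
        if self.lj_sigma <= 0:
            raise ValueError("site lj_sigma must be > 0")
        if self.lj_epsilon < 0:
            raise ValueError("site lj_epsilon must be >= 0")
        if self.style not in INTERACTION_STYLES:
            raise ValueError(f"site style must be one of {INTERACTION_STYLES}")


@dataclass(frozen=True)
class SoluteSpec:
    """Rigid multi-site solute.

    ``coupling`` linearly scales every solute-solvent pair energy; it is the
    switch used for weak-coupling checks (the fully coupled solute has
    coupling 1, a non-interacting ghost has coupling 0).
    """

    sites: tuple[SoluteSite, ...]
    rigid: bool = True
    coupling: float = 1.0

    def __post_init__(self) -> None:
        if len(self.sites) < 1:
            raise ValueError("solute needs at least one site")
        if not self.rigid:
            raise ValueError("only rigid solutes are supported")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def net_charge(self) -> float:
        return float(sum(s.charge for s in self.sites))

    def site_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Offsets (M,3), charges, sigmas, epsilons as arrays."""
        off = np.array([s.offset for s in self.sites], dtype=float)
        q = np.array([s.charge for s in self.sites], dtype=float)
        sig = np.array([s.lj_sigma for s in self.sites], dtype=float)
        eps = np.array([s.lj_epsilon for s in self.sites], dtype=float)
        return off, q, sig, eps

    def site_styles(self) -> np.ndarray:
        return np.array([STYLE_CODE[s.style] for s in self.sites], dtype=np.int64)

    def scaled(self, coupling: float) -> "SoluteSpec":
        return SoluteSpec(sites=self.sites, rigid=self.rigid, coupling=coupling)


@dataclass(frozen=True)
class SystemSpec:
    """Full definition of one simulated system (solvent with optional solute)."""

    box_length: float
    temperature: float
    species: tuple[SpeciesSpec, ...]
    solute: Optional[SoluteSpec] = None
    r_cut: float = 8.0
    coulomb_scheme: str = "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.box_length <= 0:
            raise ValueError("box_length must be > 0")
        if self.r_cut <= 0 or self.r_cut > self.box_length / 2 + 1e-12:
            raise ValueError(
                f"r_cut must lie in (0, box_length/2]; got r_cut={self.r_cut}, "
                f"box_length={self.box_length}"
            )
        if self.coulomb_scheme not in COULOMB_SCHEMES:
            raise ValueError(
                f"coulomb_scheme must be one of {COULOMB_SCHEMES}, got {self.coulomb_scheme!r}"
            )
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ValueError("species names must be unique")
        if self.coulomb_scheme != "none":
            q = sum(s.count * s.charge for s in self.species)
            if self.solute is not None:
                q += self.solute.net_charge
            if abs(q) > 1e-9:
                raise ValueError(
                    f"total charge must vanish with electrostatics on; got {q:g} e"
                )

    @property
    def n_particles(self) -> int:
        return int(sum(s.count for s in self.species))

    @property
    def species_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.species)

    def species_index_array(self) -> np.ndarray:
        """Per-particle species index, particles concatenated in species order."""
        return np.repeat(
            np.arange(len(self.species)), [s.count for s in self.species]
        ).astype(np.int64)

    def with_solute(self, solute: Optional[SoluteSpec]) -> "SystemSpec":
        return SystemSpec(
            box_length=self.box_length,
            temperature=self.temperature,
            species=self.species,
            solute=solute,
            r_cut=self.r_cut,
            coulomb_scheme=self.coulomb_scheme,
            seed=self.seed,
        )


@dataclass
class Trajectory:
    """Sampled configurations of one system.

    ``frames`` holds one (N, 3) position array per stored frame, positions
    wrapped into [0, L).  The particle ordering (and hence ``species_index``)
    is fixed across frames.  When the generating spec contains a solute, the
    solute sat rigid at the box centre during sampling.
    """

    spec: SystemSpec
    frames: list = field(default_factory=list)
    species_index: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    sweeps_between_frames: int = 0
    acceptance_rate: float = 1.0
    seed: int = 0

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def box_length(self) -> float:
        return self.spec.box_length

    @property
    def has_solute(self) -> bool:
        return self.spec.solute is not None

    def positions(self, frame: int) -> np.ndarray:
        return self.frames[frame]


#: Integer codes matching the energy kernels; mixing takes the "harder" style.
STYLE_CODE = {"lj": 0, "repulsive": 1, "hard": 2}


def mix_styles(codes_a: np.ndarray, codes_b: np.ndarray) -> np.ndarray:
    """Pairwise interaction style: hard dominates, then repulsive, then LJ."""
    return np.maximum(np.asarray(codes_a)[:, None], np.asarray(codes_b)[None, :])


def mix_lorentz_berthelot(
    sig_a: np.ndarray, eps_a: np.ndarray, sig_b: np.ndarray, eps_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Lorentz-Berthelot combination: arithmetic sigma, geometric epsilon."""
    sig = 0.5 * (np.asarray(sig_a)[:, None] + np.asarray(sig_b)[None, :])
    eps = np.sqrt(np.asarray(eps_a)[:, None] * np.asarray(eps_b)[None, :])
    return sig, eps


def solute_site_positions(spec: SystemSpec) -> np.ndarray:
    """Solute site coordinates with the solute centred in the box."""
    if spec.solute is None:
        raise ValueError("system has no solute")
    off, _, _, _ = spec.solute.site_arrays()
    centre = np.full(3, spec.box_length / 2.0)
    return off + centre
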