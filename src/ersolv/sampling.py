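"""Species-tagged solute-solvent pair-energy sampling.

Two sampling routes feed the energy-representation analysis:

* ``sample_solution_energies`` reads solute-molecule pair energies off frames
  sampled *with* the solute present (the solution system);
* ``sample_insertions`` performs Widom-style test-particle insertions of the
  solute at uniform positions and orientations into frames sampled *without*
  it (the reference system).

Both return the pair energy of the solute with every solvent molecule,
grouped by species, plus the per-frame / per-insertion total.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import _kernels
from .engine import _coul_flag, _solute_tables
from .system import SoluteSpec, Trajectory, solute_site_positions

__all__ = [
    "SolutionEnergySamples",
    "InsertionSamples",
    "sample_solution_energies",
    "sample_insertions",
    "radial_distribution",
]


@dataclass
class SolutionEnergySamples:
    """Solute-molecule pair energies from the solution system.

    ``energies[species]`` is an (n_frames, count) array; ``totals`` holds the
    per-frame solute-solvent interaction energy nu, which equals the sum of
    every species' pair energies by construction.
    """

    energies: dict[str, np.ndarray]
    totals: np.ndarray
    temperature: float

    @property
    def n_frames(self) -> int:
        return len(self.totals)

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self.energies)

    def counts(self) -> dict[str, int]:
        return {s: a.shape[1] for s, a in self.energies.items()}


@dataclass
class InsertionSamples:
    """Solute-molecule pair energies from test insertions into the reference system."""

    energies: dict[str, np.ndarray]
    totals: np.ndarray
    positions: np.ndarray
    frame_index: np.ndarray
    n_insertions_per_frame: int
    temperature: float

    @property
    def n_insertions(self) -> int:
        return len(self.totals)

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self.energies)

    def counts(self) -> dict[str, int]:
        return {s: a.shape[1] for s, a in self.energies.items()}


def sample_solution_energies(
    traj: Trajectory, solute: Optional[SoluteSpec] = None
) -> SolutionEnergySamples:
    """Pair energies of the (fixed, centred) solute with every molecule, per frame."""
    spec = traj.spec
    if solute is None:
        solute = spec.solute
    if spec.solute is None:
        raise ValueError("trajectory was sampled without a solute; "
                         "use sample_insertions for reference-system statistics")
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    spos = solute_site_positions(spec)
    s_sig2, s_eps, s_qq, s_shift, s_style = _solute_tables(spec, solute)
    coul = _coul_flag(spec.coulomb_scheme)
    n = spec.n_particles
    per_frame = np.empty((traj.n_frames, n))
    buf = np.empty(n)
    for f, frame in enumerate(traj.frames):
        _kernels.frame_solute_energies(
            frame, traj.species_index, spos, s_sig2, s_eps, s_qq, s_shift, s_style,
            spec.box_length, spec.r_cut, coul, solute.coupling, buf)
        per_frame[f] = buf
    energies = {}
    start = 0
    for sp in spec.species:
        energies[sp.name] = per_frame[:, start:start + sp.count].copy()
        start += sp.count
    totals = per_frame.sum(axis=1)
    return SolutionEnergySamples(energies=energies, totals=totals,
                                 temperature=spec.temperature)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix from a normalized random quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def sample_insertions(
    traj: Trajectory,
    solute: SoluteSpec,
    n_per_frame: int,
    seed: int,
) -> InsertionSamples:
    """Uniform test-particle insertions of the solute into reference frames.

    Positions are uniform over the box; multi-site solutes additionally get a
    uniform random orientation per insertion.  Deterministic for a given seed.
    """
    if n_per_frame <= 0:
        raise ValueError("n_per_frame must be positive")
    spec = traj.spec
    if spec.solute is not None:
        raise ValueError("reference trajectory must be sampled without the solute")
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    rng = np.random.default_rng(seed)
    base = spec.with_solute(solute)
    s_sig2, s_eps, s_qq, s_shift, s_style = _solute_tables(base, solute)
    coul = _coul_flag(spec.coulomb_scheme)
    off, _, _, _ = solute.site_arrays()
    multi = solute.n_sites > 1
    n = spec.n_particles
    n_ins = traj.n_frames * n_per_frame
    per_ins = np.empty((n_ins, n))
    positions = np.empty((n_ins, 3))
    frame_index = np.empty(n_ins, dtype=np.int64)
    buf = np.empty(n)
    k = 0
    for f, frame in enumerate(traj.frames):
        for _ in range(n_per_frame):
            centre = rng.uniform(0.0, spec.box_length, size=3)
            if multi:
                rot = _random_rotation(rng)
                spos = off @ rot.T + centre
            else:
                spos = off + centre
            _kernels.frame_solute_energies(
                frame, traj.species_index, spos, s_sig2, s_eps, s_qq, s_shift, s_style,
                spec.box_length, spec.r_cut, coul, solute.coupling, buf)
            per_ins[k] = buf
            positions[k] = centre
            frame_index[k] = f
            k += 1
    energies = {}
    start = 0
    for sp in spec.species:
        energies[sp.name] = per_ins[:, start:start + sp.count].copy()
        start += sp.count
    totals = per_ins.sum(axis=1)
    return InsertionSamples(
        energies=energies, totals=totals, positions=positions,
        frame_index=frame_index, n_insertions_per_frame=n_per_frame,
        temperature=spec.temperature)


def radial_distribution(
    traj: Trajectory,
    tags_a: Sequence[str] | str,
    tags_b: Sequence[str] | str,
    dr: float,
    r_max: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Radial distribution function g(r) between two species selections.

    Standard pair-count estimator normalized by the ideal-gas expectation
    (exact spherical-shell volumes, minimum-image distances).  Returns the
    bin-centre grid and g(r).
    """
    if dr <= 0:
        raise ValueError("dr must be positive")
    L = traj.box_length
    if r_max > L / 2 + 1e-12:
        raise ValueError("r_max must not exceed box_length/2")
    if isinstance(tags_a, str):
        tags_a = [tags_a]
    if isinstance(tags_b, str):
        tags_b = [tags_b]
    names = traj.spec.species_names
    idx_a = np.isin(traj.species_index, [names.index(t) for t in tags_a])
    idx_b = np.isin(traj.species_index, [names.index(t) for t in tags_b])
    n_a = int(idx_a.sum())
    n_b = int(idx_b.sum())
    if n_a == 0 or n_b == 0:
        raise ValueError("empty species selection in radial_distribution")
    nbins = int(np.floor(r_max / dr))
    counts = np.zeros(nbins)
    same = bool(np.array_equal(idx_a, idx_b))
    for frame in traj.frames:
        _kernels.pair_distance_counts(
            np.ascontiguousarray(frame[idx_a]), np.ascontiguousarray(frame[idx_b]),
            same, L, dr, nbins, counts)
    counts /= traj.n_frames
    edges = dr * np.arange(nbins + 1)
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    rho_b = (n_b - (1 if same else 0)) / L**3
    # counts are ordered pairs: n_a choices times expected partners in shell
    ideal = n_a * rho_b * shell
    g = counts / ideal
    r = 0.5 * (edges[1:] + edges[:-1])
    return r, g
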