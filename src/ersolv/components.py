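"""Energy-domain split of species free-energy contributions.

Each species' contribution lives on the pair-energy coordinate and is split
at ``eps_max`` into an interaction part (eps < eps_max: hydrogen-bond-scale
attractions, dispersion, and the associated solvent reorganization) and an
excluded-volume part (eps >= eps_max: the cavity-formation cost from
solute-solvent overlap).  The split is a partition of the already-computed
per-bin terms, so dG_int_i + dG_EV_i = dG_i holds at machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .er import SolvationResult

__all__ = ["ComponentResult", "energy_domain_split"]

#: Default energy-domain boundary (kcal/mol) separating attractive
#: interactions from the excluded-volume region.
DEFAULT_EPS_MAX = 20.0


@dataclass
class ComponentResult:
    """Interaction / excluded-volume split of each species' contribution."""

    eps_max: float
    dG_int: dict[str, float]
    dG_EV: dict[str, float]

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self.dG_int)

    def totals(self) -> tuple[float, float]:
        return float(sum(self.dG_int.values())), float(sum(self.dG_EV.values()))


def energy_domain_split(result: SolvationResult, eps_max: float | None = None) -> ComponentResult:
    """Split every species' dG_i at ``eps_max`` (must coincide with a mesh edge).

    ``eps_max`` defaults to the mesh's final finite edge, in which case the
    excluded-volume part is exactly the overflow-bin contribution.  An
    interior mesh edge moves the high-energy finite bins into the
    excluded-volume part as well; any other value is rejected rather than
    silently re-binned.
    """
    mesh = result.mesh
    if eps_max is None:
        eps_max = mesh.eps_max
    edge_match = np.isclose(mesh.edges, eps_max, rtol=0.0, atol=1e-9)
    if not edge_match.any():
        raise ValueError(
            f"eps_max = {eps_max:g} kcal/mol does not coincide with a mesh edge; "
            "rebuild the mesh instead of re-binning"
        )
    cut = int(np.argmax(edge_match))  # finite bins [0, cut) are interaction
    dg_int: dict[str, float] = {}
    dg_ev: dict[str, float] = {}
    for sp, term in result.species_terms.items():
        contrib = term.energy_terms + term.reorg_terms
        dg_int[sp] = float(contrib[:cut].sum())
        dg_ev[sp] = float(contrib[cut:].sum())
    return ComponentResult(eps_max=float(eps_max), dG_int=dg_int, dG_EV=dg_ev)
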