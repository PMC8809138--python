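"""Physical constants and unit conventions.

Internal units throughout the package: energies in kcal/mol, lengths in
angstrom, temperatures in kelvin, charges in elementary charges e,
concentrations in mol/L.
"""

#: Gas constant, kcal/(mol K).
R_KCAL: float = 1.987204e-3

#: Coulomb prefactor k_e = e^2/(4 pi eps0), kcal angstrom / (mol e^2).
COULOMB_K: float = 332.0636

#: Wigner lattice constant for a point charge in a cubic box with a
#: neutralizing background (dimensionless, in units of 1/L).
WIGNER_XI: float = -2.837297

#: Gas constant in L atm / (mol K); used only for vapour-pressure conversion.
R_LATM: float = 0.0820573661

#: Avogadro constant, 1/mol.
N_AVOGADRO: float = 6.02214076e23

#: cubic-angstrom to litre conversion.
A3_TO_L: float = 1.0e-27


def beta(temperature: float) -> float:
    """Inverse thermal energy 1/(R T) in mol/kcal."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return 1.0 / (R_KCAL * temperature)


def molarity_from_count(n: int, box_length: float) -> float:
    """Molar concentration of ``n`` particles in a cubic box of side ``box_length`` (angstrom)."""
    volume_l = box_length**3 * A3_TO_L
    return n / (N_AVOGADRO * volume_l)
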