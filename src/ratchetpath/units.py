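"""Unit system and physical constants.

Internal units: length in Angstrom, time in ps, mass in amu (g/mol),
energy in kcal/mol, temperature in Kelvin.  Force constants quoted in
pN/Angstrom (the convention for the ratchet bias strength alpha) are
converted on input.
"""

#: Boltzmann constant, kcal mol^-1 K^-1.
KB = 1.987204e-3

#: 1 pN*Angstrom expressed in kcal/mol (1e-22 J * N_A / 4184 J/kcal).
PN_ANGSTROM_TO_KCAL_MOL = 1.4393e-2

#: Acceleration conversion: (kcal/mol/Angstrom) / amu -> Angstrom/ps^2.
ACC_CONVERSION = 418.4


def alpha_to_kcal(alpha_pn_per_ang: float) -> float:
    """Convert a bias force constant from pN/Angstrom to kcal/mol/Angstrom^2."""
    return alpha_pn_per_ang * PN_ANGSTROM_TO_KCAL_MOL


def kbt(temperature: float) -> float:
    """Thermal energy k_B*T in kcal/mol."""
    return KB * temperature
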