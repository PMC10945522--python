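"""Unit system and physical constants.

Internal units everywhere: length in Angstrom, energy in kcal/mol, time in ps,
mass in amu, charge in units of the elementary charge, temperature in Kelvin.
Conversions happen only at I/O boundaries.
"""

#: Boltzmann constant, kcal/mol/K
KB = 0.0019872

#: Avogadro's number, 1/mol
N_AVOGADRO = 6.022e23

#: Coulomb constant e^2/(4 pi eps0), kcal/mol * Angstrom
COULOMB_K = 332.0637

#: kinetic-energy conversion: 1 amu * (A/ps)^2 in kcal/mol
MVSQ2E = 2.390057e-3

#: default solvent dielectric at 300 K
DIELECTRIC_WATER = 78.0

#: thermal energy at 300 K, kcal/mol
KT_300 = KB * 300.0


def kt(temperature: float) -> float:
    """Thermal energy k_B*T in kcal/mol."""
    return KB * temperature
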