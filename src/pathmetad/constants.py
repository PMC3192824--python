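"""Physical constants in the package unit system.

Units throughout: distances in Å, energies in kcal/mol, time in ps,
temperatures in K, masses in amu, angles in degrees at API boundaries.
"""

#: Boltzmann constant, kcal/(mol K).
KB_KCAL: float = 0.0019872041

#: Conversion from kcal/(mol Å) force per amu mass to acceleration in Å/ps².
#: 1 kcal/mol = 4184 J/mol = 418.4 amu Å²/ps².
KCAL_PER_MOL_TO_AMU_A2_PS2: float = 418.4

#: Default simulation temperature (K).
DEFAULT_TEMPERATURE: float = 300.0


def kbt(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy k_B·T in kcal/mol."""
    return KB_KCAL * temperature
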