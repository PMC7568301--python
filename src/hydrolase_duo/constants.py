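"""Physical constants and global unit conventions.

Energies are in kcal/mol, lengths in Å, time in s, concentrations in µM
(enzyme concentrations in nM where noted), temperatures in K.
"""

#: Gas constant, kcal/(mol·K).
R_KCAL: float = 1.987204e-3

#: Boltzmann constant, J/K (CODATA 2018, exact).
KB_J: float = 1.380649e-23

#: Planck constant, J·s (CODATA 2018, exact).
H_J: float = 6.62607015e-34

#: Default temperature for sampling, kinetics and rates: 30 °C.
DEFAULT_TEMPERATURE: float = 303.15


def kt(temperature: float) -> float:
    """Thermal energy k_B·T expressed in kcal/mol (i.e. R·T)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return R_KCAL * temperature


def eyring_prefactor(temperature: float) -> float:
    """Attempt frequency k_B·T/h in s⁻¹ at the given temperature."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB_J * temperature / H_J
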