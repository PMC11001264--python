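"""Physical constants and unit conventions.

All coordinates are in nm, times in ps, energies in kJ/mol and
temperatures in K throughout the package.  The membrane normal is the
z-axis by convention.
"""

#: Boltzmann constant in kJ mol^-1 K^-1 (CODATA).
KB = 0.008314462618

#: Default analysis temperature (physiological, K).
DEFAULT_TEMPERATURE = 310.0


def kt(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy k_B*T in kJ/mol."""
    return KB * temperature
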