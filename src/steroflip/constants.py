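"""Physical constants and unit conventions.

Canonical units throughout the package: nm, ns, kJ/mol, K.
Rates are reported in s^-1 (1/ns = 1e9 s^-1).
"""

#: Gas constant in kJ mol^-1 K^-1.
GAS_CONSTANT_KJ: float = 8.314e-3

#: Default simulation temperature (K).
DEFAULT_TEMPERATURE: float = 310.0

#: ns -> s conversion for rate constants.
NS_TO_S: float = 1e-9


def thermal_energy(temperature: float) -> float:
    """Molar thermal energy RT in kJ/mol at the given temperature (K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return GAS_CONSTANT_KJ * temperature
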