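"""Physical constants and unit helpers used across the package."""

#: Molar gas constant, J mol^-1 K^-1.
R_GAS = 8.314

#: Zero of the Celsius scale in kelvin.
T_CELSIUS_ZERO = 273.15


def celsius_to_kelvin(t_c: float) -> float:
    return t_c + T_CELSIUS_ZERO


def kelvin_to_celsius(t_k: float) -> float:
    return t_k - T_CELSIUS_ZERO
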