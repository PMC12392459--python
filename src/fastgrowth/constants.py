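"""Physical constants and unit helpers.

All free energies and work values in this package are in kcal/mol and
temperatures in kelvin, so the molar gas constant is expressed in
kcal mol^-1 K^-1 and ``beta`` carries units of mol/kcal.
"""

import math

#: Molar gas constant in kcal mol^-1 K^-1.
R_KCAL: float = 1.987204e-3

#: Default simulation temperature (K) for the solvation protocols handled here.
DEFAULT_TEMPERATURE: float = 300.0


def beta(temperature: float) -> float:
    """Inverse thermal energy 1/(RT) in mol/kcal."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return 1.0 / (R_KCAL * temperature)


def rt(temperature: float) -> float:
    """Thermal energy RT in kcal/mol."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return R_KCAL * temperature


def rt_ln10(temperature: float) -> float:
    """RT ln(10) in kcal/mol — one LogP unit expressed as a transfer free energy.

    At 300 K this evaluates to ~1.372 kcal/mol (commonly quoted as 1.37).
    """
    return rt(temperature) * math.log(10.0)
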