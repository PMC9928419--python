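"""Physical constants and unit conversions used throughout the package.

All internal energies are in kcal/mol, distances in nm, angles in rad,
temperatures in K, concentrations in mol/L unless stated otherwise.
"""

#: Ideal gas constant in kcal mol^-1 K^-1.
R_KCAL = 1.98720425e-3

#: kJ per kcal (thermochemical calorie).
KJ_PER_KCAL = 4.184

#: Default temperature (K); matches 25 C used for both simulations and ITC.
T_DEFAULT = 298.15

#: Standard-state volume per molecule at 1 M, in nm^3 (1 L / N_A).
V0_NM3 = 1.6606


def kj_to_kcal(x):
    """Convert kJ/mol to kcal/mol (scalar or array)."""
    return x / KJ_PER_KCAL


def kcal_to_kj(x):
    """Convert kcal/mol to kJ/mol (scalar or array)."""
    return x * KJ_PER_KCAL


def rt(temperature: float = T_DEFAULT) -> float:
    """Thermal energy RT in kcal/mol at the given temperature."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return R_KCAL * temperature
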