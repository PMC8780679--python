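"""Physical constants and unit conversions.

Internal units throughout the package: length nm, time ps, energy kJ/mol,
temperature K.  Permeability is reported in cm/s (1 nm/ps = 1e5 cm/s).
"""

#: Molar gas constant, kJ/mol/K (CODATA).  Free energies are molar, so the
#: "Boltzmann constant times temperature" of the resistivity formula is RT.
R_GAS = 0.008314462618

#: Conversion factor: permeability in nm/ps -> cm/s.
#: 1 nm/ps = 1e-7 cm / 1e-12 s = 1e5 cm/s.
NM_PER_PS_TO_CM_PER_S = 1.0e5

#: Atomic mass unit in kg; with volumes in nm^3 (=1e-27 m^3) a mass density
#: in amu/nm^3 is converted to kg/m^3 by this bare number.
AMU_PER_NM3_TO_KG_PER_M3 = 1.66053906660


def beta(temperature: float) -> float:
    """Inverse molar thermal energy 1/(R*T) in mol/kJ."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return 1.0 / (R_GAS * temperature)


def rt(temperature: float) -> float:
    """Molar thermal energy R*T in kJ/mol."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return R_GAS * temperature
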