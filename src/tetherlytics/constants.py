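"""Physical constants and unit conventions.

The package works internally in molecular-simulation units:

* length     — nanometres (nm)
* time       — nanoseconds (ns)
* energy     — kJ/mol
* temperature — Kelvin

Lateral diffusion coefficients are *reported* in nm^2/us (the customary
scale for lipid diffusion) and converted at the I/O boundary; everything
else stays in nm^2/ns.  Electrical quantities use SI units (s, V, A, Ohm,
F, S) throughout.
"""

#: Boltzmann constant in kJ/mol/K (i.e. the molar gas constant).
K_B = 0.0083145

#: Vacuum permittivity, F/m.
EPSILON_0 = 8.854e-12

#: Default temperature for the coarse-grained membrane analyses, K.
DEFAULT_TEMPERATURE_MD = 320.0

#: Default temperature for electrical measurements (20 C), K.
DEFAULT_TEMPERATURE_ELECTRICAL = 293.15

#: nm^2/ns -> nm^2/us conversion for reported lateral diffusion.
NM2_NS_TO_NM2_US = 1000.0


def beta(temperature: float) -> float:
    """Inverse thermal energy 1/(k_B T) in mol/kJ."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return 1.0 / (K_B * temperature)
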