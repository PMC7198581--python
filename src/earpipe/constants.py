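"""Physical constants and repo-wide unit conventions.

Units are SI throughout: displacement in m, force in N, stiffness in N/m,
temperature in K. Energies are reported in units of k_B*T.
"""

BOLTZMANN: float = 1.380649e-23
"""Boltzmann constant k_B in J/K (2019 SI exact value)."""

ROOM_TEMPERATURE: float = 294.15
"""Default bath temperature in K (21 degC, typical for the recordings emulated here)."""


def kbt(temperature: float = ROOM_TEMPERATURE) -> float:
    """Thermal energy k_B*T in joules at the given temperature."""
    return BOLTZMANN * temperature
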