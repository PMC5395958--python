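"""Physical constants and the package-wide unit conventions.

All public interfaces use one fixed set of units:

=============  ========
quantity       unit
=============  ========
voltage        mV
current        pA (unitary currents reported in fA)
capacitance    pF
charge         fC
conductance    pS (pS/pF when density-normalized)
resistance     MOhm
time           s (protocol durations also quoted in ms where noted)
frequency      Hz
temperature    K
=============  ========

Every conversion between these working units and SI goes through the
factors defined here; no module hard-codes its own.
"""

# CODATA 2018 exact values
ELEMENTARY_CHARGE = 1.602176634e-19  # C
BOLTZMANN = 1.380649e-23  # J/K

#: default bath temperature, K ("room temperature")
ROOM_TEMPERATURE = 296.15

# SI prefixes for the working units
FEMTO = 1e-15
PICO = 1e-12
NANO = 1e-9
MICRO = 1e-6
MILLI = 1e-3
MEGA = 1e6
GIGA = 1e9


def thermal_voltage_mV(temperature: float = ROOM_TEMPERATURE) -> float:
    """kT/e0 in mV (~25.5 mV at 296.15 K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be > 0 K, got {temperature}")
    return BOLTZMANN * temperature / ELEMENTARY_CHARGE / MILLI
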