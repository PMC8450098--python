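"""Physical constants used throughout the two-state melting model.

These are fixed module-level constants, deliberately not configurable:
every published thermodynamic value this package is compared against was
derived with exactly these numbers, so allowing overrides would silently
break cross-checks between modules.
"""

#: Gas constant in cal mol^-1 K^-1 (thermodynamic calorie convention used
#: throughout optical-melting literature).
GAS_CONSTANT: float = 1.987

#: 37 degrees Celsius in Kelvin; the reference temperature for free energies.
T37_K: float = 310.15

#: Conversion offset between Celsius and Kelvin.
CELSIUS_OFFSET: float = 273.15
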