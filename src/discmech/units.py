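"""Internal vs reported units.

Internal units are SI-consistent throughout the package: T1/T2 in ms, MTR
and FA as fractions, ADC in mm^2/s, moduli in MPa, viscosity in MPa s,
permeabilities in 1e-15 m^4/(N s).  The literature tables report MTR x100,
FA x10^-2 and ADC x10^-4 mm^2/s; these conversions live here and nowhere
else.
"""

from __future__ import annotations

#: multiply an internal value by this factor to obtain the reported scale
REPORTING_SCALE = {
    "T1_ms": 1.0,
    "T2_ms": 1.0,
    "MTR": 100.0,
    "FA": 100.0,
    "ADC": 1e4,
    "E": 1.0,
    "k_r": 1.0,
    "H_A0": 1.0,
    "k_0": 1.0,
    "k_a": 1.0,
}


def to_reported(var: str, value):
    """Internal units -> the scale printed in the study tables."""
    return value * REPORTING_SCALE[var]


def from_reported(var: str, value):
    """Printed scale -> internal units."""
    return value / REPORTING_SCALE[var]
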