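"""Unit conventions and conversions.

All internal quantities are SI (m, s, Pa, kg, m^3/s).  Clinical units
(mmHg, ml/s, ml/mmHg) appear only at interfaces: configuration files,
reports, and the lumped-parameter (Windkessel) module, whose parameters
are conventionally stated in mmHg.s/ml and ml/mmHg.
"""

from __future__ import annotations

MMHG_PER_PA = 1.0 / 133.322
PA_PER_MMHG = 133.322

ML_PER_M3 = 1.0e6
M3_PER_ML = 1.0e-6


def mmhg_convert(value, direction: str):
    """Convert pressure between SI (Pa) and mmHg.

    Parameters
    ----------
    value : float or array
        Pressure in the source unit.
    direction : {"to_SI", "to_mmHg"}
        ``to_SI`` interprets *value* as mmHg and returns Pa;
        ``to_mmHg`` interprets *value* as Pa and returns mmHg.
    """
    if direction == "to_SI":
        return value * PA_PER_MMHG
    if direction == "to_mmHg":
        return value * MMHG_PER_PA
    raise ValueError(f"direction must be 'to_SI' or 'to_mmHg', got {direction!r}")
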