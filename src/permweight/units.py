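"""Unit constants and conversions.

Internal bookkeeping is in reduced units (lengths in Å, times in ps,
energies in kcal/mol); conversion to cm/s and 1/s happens only in the
flux analysis layer.
"""

import math

#: Gas constant in kcal/(mol K).
R_KCAL_MOL_K = 1.987204258640832e-3

#: 1 Å expressed in cm.
ANGSTROM_TO_CM = 1.0e-8

#: 1 ps expressed in s.
PS_TO_S = 1.0e-12

LN10 = math.log(10.0)


def kT(temperature: float = 300.0) -> float:
    """Thermal energy in kcal/mol at ``temperature`` (K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return R_KCAL_MOL_K * temperature
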