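"""Unit conventions and physical constants.

Geometry is stored in micrometres; all PDE assembly happens in SI units, so
every solver converts coordinates with :data:`UM` at its boundary.
"""

#: metres per micrometre
UM = 1e-6
#: metres per nanometre
NM = 1e-9
#: pascal per mmHg (conversion constant used throughout)
MMHG_TO_PA = 133.322
#: vacuum permittivity, F/m
EPS0 = 8.8541878128e-12


def mmhg_to_pa(p_mmhg: float) -> float:
    """Convert a pressure from mmHg to Pa (1 mmHg = 133.322 Pa)."""
    return p_mmhg * MMHG_TO_PA


def pa_to_mmhg(p_pa: float) -> float:
    """Convert a pressure from Pa to mmHg."""
    return p_pa / MMHG_TO_PA
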