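"""Unit conversion constants and helpers.

Everything inside the package is SI.  Clinical units (mmHg for pressures and
oxygen tensions, mmHg·s/cm³ for terminal resistances) are converted exactly
once at the input/output boundary with the constants below.
"""

#: Pascals per millimetre of mercury.
MMHG_TO_PA = 133.322

#: Pa·s/m³ per mmHg·s/cm³ (1 cm³ = 1e-6 m³).
MMHG_S_PER_CM3_TO_SI = MMHG_TO_PA / 1e-6


def mmhg_to_pa(p_mmhg):
    return p_mmhg * MMHG_TO_PA


def pa_to_mmhg(p_pa):
    return p_pa / MMHG_TO_PA


def terminal_resistance_to_si(r_mmhg_s_cm3):
    """Convert a terminal resistance from mmHg·s/cm³ to Pa·s/m³."""
    return r_mmhg_s_cm3 * MMHG_S_PER_CM3_TO_SI


def terminal_resistance_from_si(r_si):
    """Convert a terminal resistance from Pa·s/m³ to mmHg·s/cm³."""
    return r_si / MMHG_S_PER_CM3_TO_SI
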