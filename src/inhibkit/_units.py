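"""Unit conversions.

Concentrations are carried as μmol/L everywhere in the public API; the
quenching and binding fits need mol/L because the literature constants
(Ksv, Ka) are in L/mol. The conversion lives here and nowhere else.
"""

UM_PER_M = 1e6

GAS_CONSTANT = 8.314  # J/(mol*K)
LN10 = 2.303  # decadic-log factor as conventionally rounded in this field


def um_to_m(c_um: float) -> float:
    """Convert a concentration from μmol/L to mol/L."""
    return c_um / UM_PER_M


def m_to_um(c_m: float) -> float:
    """Convert a concentration from mol/L to μmol/L."""
    return c_m * UM_PER_M
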