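"""Unit conversions.

Internal computations run in CGS (cm, s, g, dyn). Clinical quantities
cross the API boundary in mmHg (pressure), mL/s (flow), mmHg*s/mL
(resistance) and mL/mmHg (compliance).
"""

MMHG = 1333.22  # dyn/cm^2 per mmHg


def mmhg_to_cgs(p_mmhg: float) -> float:
    """Pressure mmHg -> dyn/cm^2."""
    return p_mmhg * MMHG


def cgs_to_mmhg(p_dyn_cm2: float) -> float:
    """Pressure dyn/cm^2 -> mmHg."""
    return p_dyn_cm2 / MMHG


def resistance_to_cgs(r_mmhg_s_ml: float) -> float:
    """Resistance mmHg*s/mL -> dyn*s/cm^5."""
    return r_mmhg_s_ml * MMHG


def resistance_to_clinical(r_cgs: float) -> float:
    """Resistance dyn*s/cm^5 -> mmHg*s/mL."""
    return r_cgs / MMHG


def compliance_to_cgs(c_ml_mmhg: float) -> float:
    """Compliance mL/mmHg -> cm^5/dyn."""
    return c_ml_mmhg / MMHG


def compliance_to_clinical(c_cgs: float) -> float:
    """Compliance cm^5/dyn -> mL/mmHg."""
    return c_cgs * MMHG
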