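"""Centralised unit conversions.

Scenario files and the treatment tables use bench units (mL/min, mol/L,
cm/s, hours); all internal computation is SI (m, s, mol/m^3, m/s).
"""

ML = 1e-6            # m^3
MINUTE = 60.0        # s
HOUR = 3600.0        # s


def ml_per_min_to_m3_per_s(q: float) -> float:
    return q * ML / MINUTE


def m3_per_s_to_ml_per_min(q: float) -> float:
    return q / ML * MINUTE


def cm_per_s_to_m_per_s(k: float) -> float:
    return k * 1e-2


def m_per_s_to_cm_per_s(k: float) -> float:
    return k * 1e2


def mol_per_l_to_mol_per_m3(c: float) -> float:
    return c * 1e3


def mol_per_m3_to_mol_per_l(c: float) -> float:
    return c * 1e-3


def hours_to_s(t: float) -> float:
    return t * HOUR


def s_to_hours(t: float) -> float:
    return t / HOUR


def conductivity_to_permeability(k_ms: float, mu: float, rho_w: float, g: float) -> float:
    """Hydraulic conductivity k (m/s) to intrinsic permeability K (m^2)."""
    return k_ms * mu / (rho_w * g)
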