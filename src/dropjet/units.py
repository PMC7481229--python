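"""Unit conversions between SI (used internally everywhere) and the bench
units microfluidics people actually quote: µL/min for flow rates, mPa·s for
viscosity, mN/m for interfacial tension, µm for channel dimensions.
"""

# 1 µL/min in m³/s
UL_PER_MIN = 1e-9 / 60.0


def ul_min_to_m3_s(q_ul_min: float) -> float:
    """Convert a volumetric flow rate from µL/min to m³/s."""
    return q_ul_min * UL_PER_MIN


def m3_s_to_ul_min(q_m3_s: float) -> float:
    """Convert a volumetric flow rate from m³/s to µL/min."""
    return q_m3_s / UL_PER_MIN


def mpa_s_to_pa_s(eta_mpa_s: float) -> float:
    """Dynamic viscosity, mPa·s → Pa·s."""
    return eta_mpa_s * 1e-3


def mn_m_to_n_m(sigma_mn_m: float) -> float:
    """Interfacial tension, mN/m → N/m."""
    return sigma_mn_m * 1e-3


def um_to_m(x_um: float) -> float:
    """Length, µm → m."""
    return x_um * 1e-6


def m_to_um(x_m: float) -> float:
    """Length, m → µm."""
    return x_m * 1e6


def m3_to_pl(v_m3: float) -> float:
    """Volume, m³ → pL."""
    return v_m3 * 1e15


def m3_to_ul(v_m3: float) -> float:
    """Volume, m³ → µL."""
    return v_m3 * 1e9


def s_to_us(t_s: float) -> float:
    """Time, s → µs."""
    return t_s * 1e6
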