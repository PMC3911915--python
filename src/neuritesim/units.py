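"""Unit conversion helpers.

Internal state is SI throughout: metres, seconds, moles, mol/m^3.
Note that 1 mM == 1 mol/m^3, so a polymerization rate quoted in
m/(s.mM) multiplies a concentration in mol/m^3 directly.  The
human-facing layers (CLI, CSV output, figures) use micrometres,
minutes/hours and micromolar, matching how neurite outgrowth data
are usually reported.
"""

UM = 1e-6  # metres per micrometre
MINUTE = 60.0  # seconds per minute
HOUR = 3600.0  # seconds per hour
UMOLAR = 1e-3  # mol/m^3 per micromolar (1 uM = 1e-3 mol/m^3)


def m_to_um(x: float) -> float:
    return x / UM


def um_to_m(x: float) -> float:
    return x * UM


def molar_conc_to_um(c: float) -> float:
    """mol/m^3 -> micromolar."""
    return c / UMOLAR


def um_conc_to_molar(c: float) -> float:
    """micromolar -> mol/m^3."""
    return c * UMOLAR


def speed_to_mm_per_h(v: float) -> float:
    """m/s -> mm/h."""
    return v * 3.6e6


def s_to_h(t: float) -> float:
    return t / HOUR


def h_to_s(t: float) -> float:
    return t * HOUR


def s_to_min(t: float) -> float:
    return t / MINUTE


def min_to_s(t: float) -> float:
    return t * MINUTE
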