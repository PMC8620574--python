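"""Unit conversion helpers.

All internal quantities are SI (Pa, m, s, mol/m^3).  Literature values for
tissue transport parameters are conventionally tabulated in mmHg, cm and
minutes; the converters here are the single place those conventions are
translated.
"""

from __future__ import annotations

MMHG_TO_PA: float = 133.322
CM_TO_M: float = 1e-2
MIN_TO_S: float = 60.0


def mmhg(value: float) -> float:
    """Pressure in mmHg -> Pa."""
    return value * MMHG_TO_PA


def per_mmhg(value: float) -> float:
    """Quantity per mmHg -> per Pa."""
    return value / MMHG_TO_PA


def cm_per_mmhg_s(value: float) -> float:
    """Hydraulic conductivity in cm/(mmHg s) -> m/(Pa s)."""
    return value * CM_TO_M / MMHG_TO_PA


def per_min(value: float) -> float:
    """Rate in 1/min -> 1/s."""
    return value / MIN_TO_S


def mm2_per_s(value: float) -> float:
    """Diffusivity in mm^2/s -> m^2/s."""
    return value * 1e-6
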