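"""Carbon isotope discrimination arithmetic for kernel samples.

The isotope composition of plant tissue, δ13C_p (‰ vs. the VPDB
standard), is measured by mass spectrometry and supplied as input.
Discrimination against 13C relative to air is

    Δ13C = (δ13C_a − δ13C_p) / (1 + δ13C_p / 1000),

with δ13C of free air taken as −8.0 ‰.  In C3 plants Δ13C integrates
stomatal openness over grain filling: closed stomata deplete the
substomatal CO2 pool of 12C, forcing more 13C fixation and lowering
Δ13C, which is why it tracks water stress and grain yield.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "DELTA13C_AIR_PM",
    "delta13c_from_composition",
    "composition_from_delta13c",
]

#: Isotope composition of atmospheric CO2 (‰).
DELTA13C_AIR_PM = -8.0


def delta13c_from_composition(delta_p, delta_a: float = DELTA13C_AIR_PM):
    """Discrimination Δ13C (‰) from plant composition δ13C_p (‰).

    Strictly decreasing in ``delta_p``; equals 0 when plant matches air.
    """
    delta_p = np.asarray(delta_p, dtype=float)
    if np.any(delta_p <= -1000.0):
        raise ValueError("delta13c_plant <= -1000 permil makes the denominator singular")
    out = (delta_a - delta_p) / (1.0 + delta_p / 1000.0)
    return float(out) if out.ndim == 0 else out


def composition_from_delta13c(big_delta, delta_a: float = DELTA13C_AIR_PM):
    """Algebraic inverse: δ13C_p (‰) from a target Δ13C (‰).

    Used by the trial simulator to write plot tables in the measured
    (composition) scale.  Round-trips with the forward map to 1e-9 ‰.
    """
    big_delta = np.asarray(big_delta, dtype=float)
    if np.any(big_delta <= -1000.0):
        raise ValueError("big_delta13c <= -1000 permil makes the denominator singular")
    out = (delta_a - big_delta) / (1.0 + big_delta / 1000.0)
    return float(out) if out.ndim == 0 else out
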