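"""Independent reference implementations used only by the tests.

These are deliberately naive scalar transliterations of the published
recursions, kept free of any code from the package so they can serve as
oracles for the vectorized implementations.
"""

from __future__ import annotations

import math


def chill_portions_reference(temps_c, *,
                             slp=1.6, tetmlt=277.0, a0=1.395e5, a1=2.567e18,
                             e0=4153.5, e1=12888.8, kelvin=273.0):
    """Per-hour Dynamic Model loop; returns (portions, intermediate_E)."""
    e = 0.0
    xi_prev = 0.0
    portions = 0.0
    for t_c in temps_c:
        tk = t_c + kelvin
        sr = math.exp(slp * tetmlt * (tk - tetmlt) / tk)
        xi = sr / (1.0 + sr)
        xs = (a0 / a1) * math.exp((e1 - e0) / tk)
        ak1 = a1 * math.exp(-e1 / tk)
        s = e if e < 1.0 else e * (1.0 - xi_prev)
        e = xs - (xs - s) * math.exp(-ak1)
        if e >= 1.0:
            portions += xi * e
        xi_prev = xi
    return portions, e


def gdh_reference(t_c, tb=4.0, tu=26.0, tc=36.0, f=1.0):
    """Scalar cosine GDH response."""
    if t_c < tb or t_c > tc:
        return 0.0
    if t_c <= tu:
        return f * ((tu - tb) / 2.0) * (1.0 + math.cos(math.pi + math.pi * (t_c - tb) / (tu - tb)))
    return f * (tu - tb) * (1.0 + math.cos(math.pi / 2.0 + (math.pi / 2.0) * (t_c - tu) / (tc - tu)))
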