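"""Independent rasterization oracle for the unit-cell metal fraction.

The braid surface is the plane tiled by two families of parallel
``omega``-wide strips (the wires).  In lattice coordinates (a, b) along the
two strut directions, one period is the unit square; family-1 centerlines
sit at integer b, family-2 at integer a, and the perpendicular spacing
between adjacent parallel centerlines is the rhombus height
``S * sin(2*alpha)``.  A point is metal iff its perpendicular distance to
either family is at most ``omega/2``; the metal fraction is estimated by
pixel-counting that union on an n-by-n midpoint grid over one period.

This never touches the closed form it is used to check.
"""

import math

import numpy as np


def raster_metal_fraction(S: float, omega: float, alpha_deg: float,
                          n: int = 2000) -> float:
    spacing = S * math.sin(math.radians(2.0 * alpha_deg))
    frac = (np.arange(n) + 0.5) / n
    dist = np.minimum(frac, 1.0 - frac) * spacing  # to nearest centerline
    hit = dist <= 0.5 * omega
    metal = hit[:, None] | hit[None, :]
    return float(metal.mean())
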