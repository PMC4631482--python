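"""Average-protein Wilson intensity curve.

Mean diffracted intensity of a protein crystal versus resolution is, to a
good approximation, a universal curve: strong at low resolution, a
characteristic minimum near 6 Å (where solvent and secondary-structure
contributions cancel), a secondary maximum near 4.5 Å, then a smooth
decay that for a real crystal is further attenuated by the Debye–Waller
factor ``exp(-2 B s²)`` with ``s = h/2``.

The tabulation below is the package's own smooth rendering of that
canonical shape, normalised to 1 at h = 0 and interpolated
piecewise-linearly in h².  It is package data: every simulated intensity
and every Wilson fit in this package refers to the same table, so fits
against simulated data are self-consistent by construction.
"""

from __future__ import annotations

import numpy as np

# knots: (h in Å⁻¹, relative mean intensity).  d = 1/h for orientation:
# h = 0.167 → 6 Å minimum, h = 0.222 → 4.5 Å secondary maximum.
_KNOTS_H = np.array(
    [0.0, 0.04, 0.08, 0.125, 0.167, 0.20, 0.222, 0.25, 0.286, 0.333,
     0.40, 0.50, 0.667, 0.80, 1.00, 1.25, 1.50]
)
_KNOTS_I = np.array(
    [1.00, 0.62, 0.33, 0.165, 0.110, 0.135, 0.150, 0.140, 0.120, 0.095,
     0.068, 0.045, 0.024, 0.015, 0.0085, 0.0045, 0.0025]
)

_KNOTS_H2 = _KNOTS_H**2


def standard_wilson_curve(h):
    """Relative mean protein intensity at diffraction vector length ``h``.

    Piecewise-linear in h² between fixed knots; h outside the table is
    clamped to the end values.  Pure function of h.
    """
    h = np.asarray(h, dtype=float)
    out = np.interp(h**2, _KNOTS_H2, _KNOTS_I)
    return out if out.ndim else float(out)


def curve_knots() -> tuple[np.ndarray, np.ndarray]:
    """The (h, intensity) knots of the tabulation, copied."""
    return _KNOTS_H.copy(), _KNOTS_I.copy()
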