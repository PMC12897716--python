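"""Reference properties of liquid water at 1 atm.

The force-field parameterization needs two experimental inputs at the
simulation temperature: the mass density of water (which sets the cutoff
radius through the reduced density) and the isothermal compressibility
(which sets the water-water repulsion through the dimensionless inverse
compressibility).

Density follows the Kell (1975) 1-atm correlation, the standard reference
representation of the density of air-free water between 0 and 150 degC; it
reproduces the IAPWS values to better than 0.01% in the range used here.
Isothermal compressibility is interpolated piecewise-cubically from Kell's
1-atm table (5 K spacing, units of 1e-11 / Pa).

Supported temperature range: 273.15 K to 373.15 K.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import RangeError

T_MIN = 273.15
T_MAX = 373.15

# Kell (1975) density correlation coefficients, t in degC, rho in kg/m^3.
_KELL_NUM = np.array(
    [999.83952, 16.945176, -7.9870401e-3, -46.170461e-6, 105.56302e-9, -280.54253e-12]
)
_KELL_DEN = 16.879850e-3

# Kell (1975) isothermal compressibility of water at 1 atm.
# Rows: t (degC), kappa_T (1e-11 / Pa).
_KAPPA_TABLE = np.array(
    [
        [0.0, 50.885],
        [5.0, 49.171],
        [10.0, 47.810],
        [15.0, 46.735],
        [20.0, 45.895],
        [25.0, 45.250],
        [30.0, 44.774],
        [35.0, 44.444],
        [40.0, 44.243],
        [45.0, 44.157],
        [50.0, 44.174],
        [55.0, 44.286],
        [60.0, 44.496],
        [65.0, 44.788],
        [70.0, 45.166],
        [75.0, 45.622],
        [80.0, 46.159],
        [85.0, 46.777],
        [90.0, 47.475],
        [95.0, 48.240],
        [100.0, 49.110],
    ]
)

_kappa_spline = CubicSpline(_KAPPA_TABLE[:, 0], _KAPPA_TABLE[:, 1] * 1e-11)


def _check_range(T: float) -> None:
    if not (T_MIN <= T <= T_MAX):
        raise RangeError(
            f"T={T} K outside supported water-property range "
            f"[{T_MIN}, {T_MAX}] K"
        )


def water_density(T: float) -> float:
    """Mass density of water at 1 atm, kg/m^3, for T in kelvin."""
    _check_range(T)
    t = T - 273.15
    num = _KELL_NUM @ t ** np.arange(6)
    return float(num / (1.0 + _KELL_DEN * t))


def water_compressibility(T: float) -> float:
    """Isothermal compressibility of water at 1 atm, 1/Pa, for T in kelvin."""
    _check_range(T)
    return float(_kappa_spline(T - 273.15))


def water_properties(T: float) -> tuple[float, float]:
    """Return ``(density kg/m^3, kappa_T 1/Pa)`` of water at temperature T (K).

    Raises
    ------
    RangeError
        If T lies outside the tabulated 273.15-373.15 K range.
    """
    return water_density(T), water_compressibility(T)
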