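"""Seawater density, stratification and stability.

Density is computed with the one-atmosphere International Equation of
State of Seawater (EOS-80): sigma-t = rho(S, T, p=0) - 1000 kg m^-3.
Over the shallow (< 350 m) coastal casts this package targets, the
pressure terms contribute < 0.15 kg m^-3 to vertical density contrasts
and are neglected (documented approximation); the practical consequence
for N^2 at a metre-scale halocline is far below the stratification
class thresholds.

The Brunt-Vaisala frequency squared,

    N^2 = -(g / rho) * d(rho)/d(-z)  =  (g / rho) * d(rho)/dz,

with z positive downward, is evaluated by centred differences on
adjacent 1-m bins and reported at layer midpoints.  Positive N^2 means
hydrostatically stable.  Stations are classed as non-stratified
(N^2 < 2e-5 rad^2 s^-2), weakly stratified (2e-5 <= N^2 <= 5e-5) or
strongly stratified (N^2 > 5e-5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .station_io import DepthProfile

__all__ = [
    "GRAVITY",
    "N2_WEAK_THRESHOLD",
    "N2_STRONG_THRESHOLD",
    "StratificationClass",
    "density_eos80",
    "sigma_t",
    "brunt_vaisala_n2",
    "stratification_class",
]

GRAVITY = 9.81  # m s^-2

#: N^2 class boundaries, rad^2 s^-2
N2_WEAK_THRESHOLD = 2e-5
N2_STRONG_THRESHOLD = 5e-5


@dataclass(frozen=True)
class StratificationClass:
    label: str  # non-stratified | weakly-stratified | strongly-stratified
    n2_value: float


def density_eos80(salinity, temperature):
    """Seawater density rho(S, T, p=0), kg m^-3 (EOS-80, one atmosphere).

    S is practical salinity, T in-situ temperature in deg C (ITS-68 vs
    ITS-90 differences are negligible at this precision).
    """
    S = np.asarray(salinity, dtype=float)
    T = np.asarray(temperature, dtype=float)
    # pure-water density (Bigg 1967, as adopted by EOS-80)
    rho_w = (999.842594 + 6.793952e-2 * T - 9.095290e-3 * T**2
             + 1.001685e-4 * T**3 - 1.120083e-6 * T**4 + 6.536332e-9 * T**5)
    A = (8.24493e-1 - 4.0899e-3 * T + 7.6438e-5 * T**2
         - 8.2467e-7 * T**3 + 5.3875e-9 * T**4)
    B = -5.72466e-3 + 1.0227e-4 * T - 1.6546e-6 * T**2
    C = 4.8314e-4
    return rho_w + A * S + B * S * np.sqrt(np.abs(S)) + C * S**2


def _check_grids(a: DepthProfile, b: DepthProfile) -> None:
    if len(a) != len(b) or not np.array_equal(a.depths, b.depths):
        n = min(len(a), len(b))
        mism = np.nonzero(a.depths[:n] != b.depths[:n])[0]
        where = a.depths[mism[0]] if mism.size else max(a.depths[-1], b.depths[-1])
        raise ValueError(f"depth grids differ, first offending depth {where} m")


def sigma_t(temperature: DepthProfile, salinity: DepthProfile) -> DepthProfile:
    """Density anomaly sigma-t = rho(S, T, 0) - 1000 on the shared grid."""
    _check_grids(temperature, salinity)
    st = density_eos80(salinity.values, temperature.values) - 1000.0
    return DepthProfile(temperature.station_id, "sigma_t",
                        temperature.depths, st)


def brunt_vaisala_n2(temperature: DepthProfile, salinity: DepthProfile,
                     pressure: DepthProfile | None = None) -> DepthProfile:
    """N^2 (rad^2 s^-2) at midpoints between adjacent valid bins.

    ``pressure`` is accepted for interface symmetry but unused: the
    one-atmosphere EOS neglects compressibility (see module docstring).
    A midpoint whose difference stencil touches a missing bin is NaN.
    """
    _check_grids(temperature, salinity)
    if len(temperature) < 2:
        raise ValueError("N^2 needs at least two bins")
    rho = density_eos80(salinity.values, temperature.values)
    dz = np.diff(temperature.depths)
    drho = np.diff(rho)
    rho_mid = 0.5 * (rho[:-1] + rho[1:])
    n2 = GRAVITY / rho_mid * drho / dz
    midpoints = 0.5 * (temperature.depths[:-1] + temperature.depths[1:])
    return DepthProfile(temperature.station_id, "n2", midpoints, n2)


def stratification_class(n2: float) -> StratificationClass:
    """Three-way stability class from an N^2 value."""
    if not np.isfinite(n2):
        raise ValueError("N^2 must be finite")
    if n2 < N2_WEAK_THRESHOLD:
        label = "non-stratified"
    elif n2 <= N2_STRONG_THRESHOLD:
        label = "weakly-stratified"
    else:
        label = "strongly-stratified"
    return StratificationClass(label, float(n2))
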