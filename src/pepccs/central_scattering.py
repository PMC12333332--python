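"""Closed-form-route collision integrals for central potentials.

For a spherically symmetric potential the classical deflection angle has the
one-dimensional quadrature form

    chi(b, g) = pi - 2 b * Integral_{r_c}^{inf} dr / (r^2 sqrt(1 - b^2/r^2 - V(r)/E))

with ``r_c`` the outermost classical turning point and ``E`` the collision
energy.  This module evaluates that integral (and the thermal
momentum-transfer average built on it) by deterministic quadrature — a route
entirely independent of the trajectory integration in
:mod:`pepccs.ccs_engines`, which it serves to validate.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .mobility_core import KB_KCAL_MOL, KCAL_TO_DA_A2_PS2

__all__ = [
    "central_deflection_angle",
    "central_cross_section",
    "central_collision_integral",
]


def central_deflection_angle(
    potential: Callable[[np.ndarray], np.ndarray],
    mass: float,
    b: float,
    speed: float,
    r_max: float = 200.0,
) -> float:
    """Deflection angle (radians) in a central potential by quadrature.

    ``potential(r)`` returns kcal/mol at radius r (A); ``mass`` (Da) and
    ``speed`` (A/ps) set the collision energy E = m g^2 / 2.
    """
    if b < 0 or speed <= 0:
        raise ValueError("need b >= 0 and speed > 0")
    energy = 0.5 * mass * speed**2 / KCAL_TO_DA_A2_PS2  # kcal/mol

    def f_of_r(r: float) -> float:
        return 1.0 - (b / r) ** 2 - float(potential(np.array([r]))[0]) / energy

    # outermost turning point: scan inward from r_max for the sign change
    rs = np.geomspace(r_max, 1e-3, 2000)
    vals = 1.0 - (b / rs) ** 2 - np.asarray(potential(rs)) / energy
    neg = np.flatnonzero(vals <= 0.0)
    if b == 0.0 and len(neg) == 0:
        raise RuntimeError("no turning point found for head-on collision")
    if len(neg) == 0:
        raise RuntimeError("no turning point located; increase r_max")
    i = neg[0]
    if i == 0:
        raise RuntimeError("turning point beyond r_max")
    r_c = brentq(f_of_r, rs[i], rs[i - 1], xtol=1e-12, rtol=1e-14)
    if b == 0.0:
        return np.pi

    # substitute u = (1/r) = u_c (1 - s^2): integrable endpoint
    u_c = 1.0 / r_c

    def integrand(s: float) -> float:
        u = u_c * (1.0 - s * s)
        if u <= 0.0:
            return 0.0
        r = 1.0 / u
        f = 1.0 - (b * u) ** 2 - float(potential(np.array([r]))[0]) / energy
        if f <= 0.0:
            return 0.0
        return 2.0 * u_c * s / np.sqrt(f)

    val, _ = quad(integrand, 0.0, 1.0, limit=400, epsabs=1e-11, epsrel=1e-10)
    return np.pi - 2.0 * b * val


def central_cross_section(
    potential: Callable[[np.ndarray], np.ndarray],
    mass: float,
    speed: float,
    b_max: float,
    n_b: int = 400,
) -> float:
    """Momentum-transfer cross section Q(g) = 2 pi Int (1-cos chi) b db (A^2)
    by Gauss-Legendre quadrature dense in b."""
    nodes, weights = np.polynomial.legendre.leggauss(n_b)
    b = 0.5 * b_max * (nodes + 1.0)
    w = 0.5 * b_max * weights
    integrand = np.array(
        [
            (1.0 - np.cos(central_deflection_angle(potential, mass, bi, speed)))
            * bi
            for bi in b
        ]
    )
    return float(2.0 * np.pi * np.sum(w * integrand))


def central_collision_integral(
    potential: Callable[[np.ndarray], np.ndarray],
    reduced_mass: float,
    dynamics_mass: float,
    temperature: float,
    b_max: float,
    n_u: int = 48,
    u_max: float = 25.0,
    n_b: int = 400,
) -> float:
    """Thermally averaged Omega(1,1) (A^2) for a central potential.

    Dense Gauss-Legendre quadrature of (1/2) Int_0^inf u^2 e^-u Q(g(u)) du
    with u = reduced_mass g^2 / (2 kB T); the scattering itself uses
    ``dynamics_mass`` to mirror the frozen-ion trajectory convention.
    """
    kT = KB_KCAL_MOL * temperature * KCAL_TO_DA_A2_PS2  # Da A^2/ps^2
    nodes, weights = np.polynomial.legendre.leggauss(n_u)
    u = 0.5 * u_max * (nodes + 1.0)
    w = 0.5 * u_max * weights
    total = 0.0
    for ui, wi in zip(u, w):
        g = np.sqrt(2.0 * kT * ui / reduced_mass)
        q = central_cross_section(potential, dynamics_mass, g, b_max, n_b=n_b)
        total += wi * ui**2 * np.exp(-ui) * q
    return 0.5 * total
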