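"""Independent closed-form and brute-force oracles used by the tests.

These implementations deliberately avoid the package's own code paths:
Bessel-function profiles evaluated directly, dense polygonal
discretization for geometric quantities, and quadrature-based fluxes.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import quad
from scipy.special import jv, yv


def womersley_pipe(r_m, R_m, omega, nu, rho, G=1.0):
    """Oscillatory pipe-flow profile u(r) for pressure-gradient amplitude G."""
    beta = np.sqrt(-1j * omega / nu)
    return G / (1j * omega * rho) * (1 - jv(0, beta * r_m) / jv(0, beta * R_m))


def womersley_pipe_flux(R_m, omega, nu, rho, G=1.0):
    beta = np.sqrt(-1j * omega / nu)
    bracket = (np.pi * R_m**2
               - 2 * np.pi * R_m * jv(1, beta * R_m) / (beta * jv(0, beta * R_m)))
    return G / (1j * omega * rho) * bracket


def womersley_annulus(r_m, Ri_m, Ro_m, omega, nu, rho, G=1.0):
    """Oscillatory concentric-annulus profile with no slip on both walls."""
    beta = np.sqrt(-1j * omega / nu)
    M = np.array([[jv(0, beta * Ri_m), yv(0, beta * Ri_m)],
                  [jv(0, beta * Ro_m), yv(0, beta * Ro_m)]])
    a, b = np.linalg.solve(M, np.ones(2, dtype=complex))
    prof = 1 - (a * jv(0, beta * r_m) + b * yv(0, beta * r_m))
    return G / (1j * omega * rho) * prof


def womersley_annulus_flux(Ri_m, Ro_m, omega, nu, rho, G=1.0):
    """Flux by dense quadrature of the closed-form profile."""
    def re_part(r):
        return np.real(womersley_annulus(r, Ri_m, Ro_m, omega, nu, rho, G) * r)

    def im_part(r):
        return np.imag(womersley_annulus(r, Ri_m, Ro_m, omega, nu, rho, G) * r)

    re = quad(re_part, Ri_m, Ro_m, limit=400)[0]
    im = quad(im_part, Ri_m, Ro_m, limit=400)[0]
    return 2 * np.pi * (re + 1j * im)


def poiseuille_annulus(r_m, Ri_m, Ro_m, mu, G=1.0):
    """Steady annular Poiseuille profile for pressure gradient G = -dp/dy."""
    k = (Ro_m**2 - Ri_m**2) / np.log(Ro_m / Ri_m)
    return G / (4 * mu) * (Ro_m**2 - r_m**2 + k * np.log(r_m / Ro_m))


def poiseuille_annulus_conductance(Ri_m, Ro_m, mu):
    """Q / G for the steady annulus (m^3/s per Pa/m)."""
    num = Ro_m**4 - Ri_m**4 - (Ro_m**2 - Ri_m**2) ** 2 / np.log(Ro_m / Ri_m)
    return np.pi * num / (8 * mu)


def polygon_area_perimeter(curves, n=512):
    """Shoelace area and arc length of closed curves given as callables
    t in [0,1) -> (x, y); the first curve is the outer boundary, the rest
    are holes."""
    area = 0.0
    perim = 0.0
    for k, curve in enumerate(curves):
        t = np.arange(n) / n
        pts = np.array([curve(tt) for tt in t])
        x, y = pts[:, 0], pts[:, 1]
        a = 0.5 * np.abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
        seg = np.hypot(np.diff(x, append=x[0]), np.diff(y, append=y[0]))
        perim += seg.sum()
        area += a if k == 0 else -a
    return area, perim
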