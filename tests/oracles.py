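"""Independent numerical oracles used by the test suite.

These deliberately avoid the code paths they check: the wall-pressure
oracle is a method-of-images summation of free-space regularized dipoles,
the flat-plate friction oracle integrates the boundary-layer similarity
ODE directly, and the filter oracle is the closed-form Butterworth
magnitude response.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq
from scipy.special import erf


def free_dipole_pressure(points: np.ndarray, x0: np.ndarray, F: np.ndarray,
                         sigma: float) -> np.ndarray:
    """Free-space pressure of a Gaussian-regularized concentrated force.

    Solves lap p = div(-F g) with g an isotropic Gaussian of width sigma:
    p = -F . grad(Phi), Phi(r) = -erf(r / (sqrt(2) sigma)) / (4 pi r).
    """
    dx = points - x0
    r = np.sqrt((dx**2).sum(axis=-1))
    r = np.maximum(r, 1e-12)
    e = erf(r / (math.sqrt(2.0) * sigma))
    gauss = np.exp(-(r**2) / (2.0 * sigma**2)) * 2.0 / (math.sqrt(2.0 * math.pi) * sigma)
    dPhi_dr = e / (4.0 * math.pi * r**2) - gauss / (4.0 * math.pi * r)
    return (dx @ F) / r * dPhi_dr


def image_wall_pressure(points: np.ndarray, x0: np.ndarray, F: np.ndarray,
                        box_lengths: np.ndarray, sigma: float,
                        shells: int = 5) -> np.ndarray:
    """Wall pressure by the method of images for rigid (Neumann) walls.

    The even mirror extension across each wall maps the source at x0 to
    images at 2 n L +- x0 per axis, with the force component along an axis
    flipping sign on each reflection about that axis.  ``shells`` controls
    the truncation of the image lattice.

    The sign convention matches the reaction the object exerts on the
    fluid (source density div(-F g)), and the result is defined only up to
    an additive constant (the free-space series decays at infinity, the
    box solution uses a zero-mean gauge), so comparisons must remove the
    means.
    """
    p = np.zeros(len(points))
    L = np.asarray(box_lengths, dtype=float)
    idx = range(-shells, shells + 1)
    for nx in idx:
        for sx in (1, -1):
            cx = 2 * nx * L[0] + sx * x0[0]
            for ny in idx:
                for sy in (1, -1):
                    cy = 2 * ny * L[1] + sy * x0[1]
                    for nz in idx:
                        for sz in (1, -1):
                            c = np.array([cx, cy, 2 * nz * L[2] + sz * x0[2]])
                            Fi = -F * np.array([sx, sy, sz])
                            p += free_dipole_pressure(points, c, Fi, sigma)
    return p


def blasius_wall_shear_coefficient() -> float:
    """f''(0) of the Blasius similarity equation f''' + f f''/2 = 0.

    Solved by shooting with a stiff-free RK integrator; the classical
    value is about 0.332057.
    """

    def rhs(_eta, y):
        return [y[1], y[2], -0.5 * y[0] * y[2]]

    def miss(s):
        sol = solve_ivp(rhs, (0.0, 12.0), [0.0, 0.0, s], rtol=1e-10, atol=1e-12)
        return sol.y[1, -1] - 1.0

    return brentq(miss, 0.1, 1.0, xtol=1e-12)


def blasius_drag_by_integration(U: float, length: float, width: float,
                                rho: float, nu: float, n_x: int = 2001) -> float:
    """One-sided flat-plate friction drag by integrating the wall shear
    tau(x) = mu U f''(0) sqrt(U / (nu x)) along the plate."""
    fpp0 = blasius_wall_shear_coefficient()
    mu = rho * nu
    x = np.linspace(0.0, length, n_x)[1:]  # skip the leading-edge singularity
    tau = mu * U * fpp0 * np.sqrt(U / (nu * x))
    drag = np.trapezoid(tau, x) + 2.0 * mu * U * fpp0 * math.sqrt(U / nu) * math.sqrt(x[0])
    # the second term integrates the x^{-1/2} singularity analytically on [0, x0]
    return drag * width


def butterworth_gain(f: np.ndarray, cutoff: float, order: int,
                     zero_phase: bool) -> np.ndarray:
    """Magnitude response of a low-pass Butterworth filter; squared for
    forward-backward (zero-phase) application."""
    mag = 1.0 / np.sqrt(1.0 + (np.asarray(f, dtype=float) / cutoff) ** (2 * order))
    return mag**2 if zero_phase else mag


def second_order_ringdown(t: np.ndarray, f_n: float, zeta: float) -> np.ndarray:
    """Unit-impulse response shape of an underdamped second-order system:
    exp(-zeta w t) sin(w sqrt(1-zeta^2) t)."""
    w = 2.0 * math.pi * f_n
    wd = w * math.sqrt(1.0 - zeta**2)
    return np.exp(-zeta * w * t) * np.sin(wd * t)
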