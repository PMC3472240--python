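"""Shared fixtures and independent numerical oracles for the test suite.

The oracles here are deliberately naive (dense master-equation integration,
Crank-Nicolson PDE stepping, brute-force sphere fitting) so they stay
independent of the implementation paths they check.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.linalg import solve_banded
from scipy.optimize import least_squares


@pytest.fixture
def regular_tet():
    """Vertices of a regular tetrahedron with unit edge length."""
    return np.array([
        [0.0, 0.0, 0.0],
        [1.0, 0.0, 0.0],
        [0.5, np.sqrt(3.0) / 2.0, 0.0],
        [0.5, np.sqrt(3.0) / 6.0, np.sqrt(2.0 / 3.0)],
    ])


# ---------------------------------------------------------------------------
# geometric oracle: direct sphere fits
# ---------------------------------------------------------------------------

def fit_circumsphere(points):
    """Least-squares sphere through four points (center, radius)."""
    p = np.asarray(points, dtype=float)

    def resid(z):
        c, r = z[:3], z[3]
        return np.linalg.norm(p - c, axis=1) - r

    z0 = np.concatenate([p.mean(axis=0), [1.0]])
    sol = least_squares(resid, z0, xtol=1e-15, ftol=1e-15)
    return sol.x[:3], sol.x[3]


def fit_insphere(points):
    """Largest inscribed sphere: equal distance to the four face planes."""
    p = np.asarray(points, dtype=float)
    faces = [np.delete(np.arange(4), j) for j in range(4)]
    normals, offsets = [], []
    for j, f in enumerate(faces):
        a, b, c = p[f]
        n = np.cross(b - a, c - a)
        n = n / np.linalg.norm(n)
        if np.dot(n, p[j] - a) > 0:  # make the normal point inward
            n = -n
        normals.append(-n)
        offsets.append(np.dot(-n, a))
    normals = np.asarray(normals)
    offsets = np.asarray(offsets)

    def resid(z):
        c, r = z[:3], z[3]
        return (offsets - normals @ c) - r

    z0 = np.concatenate([p.mean(axis=0), [0.1]])
    sol = least_squares(resid, z0, xtol=1e-15, ftol=1e-15)
    return sol.x[:3], abs(sol.x[3])


# ---------------------------------------------------------------------------
# chemical master equation oracles (dense, tiny state spaces)
# ---------------------------------------------------------------------------

def decay_chain_moments(n0: int, k: float, t: float):
    """Mean and sd of N(t) for N -> N-1 at rate k*N, by integrating the
    master equation over the full (n0+1)-state space."""
    from scipy.integrate import solve_ivp

    def rhs(_, p):
        n = np.arange(n0 + 1)
        out = -k * n * p
        out[:-1] += k * n[1:] * p[1:]
        return out

    p0 = np.zeros(n0 + 1)
    p0[n0] = 1.0
    sol = solve_ivp(rhs, (0.0, t), p0, rtol=1e-10, atol=1e-12)
    p = sol.y[:, -1]
    n = np.arange(n0 + 1)
    mean = float(np.dot(n, p))
    var = float(np.dot(n ** 2, p) - mean ** 2)
    return mean, np.sqrt(max(var, 0.0))


def pairwise_death_mean(n0: int, c: float, t: float):
    """Mean count for the A+B -> C chain with equal counts (state j = number
    of pairs consumed; rate c*(n0-j)^2), via master-equation integration."""
    from scipy.integrate import solve_ivp

    def rhs(_, p):
        j = np.arange(n0 + 1)
        rate = c * (n0 - j) ** 2
        out = -rate * p
        out[1:] += rate[:-1] * p[:-1]
        return out

    p0 = np.zeros(n0 + 1)
    p0[0] = 1.0
    sol = solve_ivp(rhs, (0.0, t), p0, rtol=1e-10, atol=1e-12)
    p = sol.y[:, -1]
    return float(np.dot(n0 - np.arange(n0 + 1), p))


def birth_death_stationary(birth: float, death: float, nmax: int):
    """Stationary pmf of 0 -> A (rate ``birth``), A -> 0 (rate ``death`` per
    molecule), from detailed balance on a truncated chain."""
    logw = np.zeros(nmax + 1)
    for n in range(1, nmax + 1):
        logw[n] = logw[n - 1] + np.log(birth / (death * n))
    w = np.exp(logw - logw.max())
    return w / w.sum()


# ---------------------------------------------------------------------------
# 1D diffusion PDE oracle (Crank-Nicolson, reflective ends)
# ---------------------------------------------------------------------------

def crank_nicolson_1d(c0_profile, D, L, times, dt=1e-5, source=None,
                      clamp_mask=None):
    """Integrate dc/dt = D c_xx + source on [0, L] with no-flux ends.

    ``c0_profile``: initial cell-center values (nx cells); ``source``: per-cell
    rate added each step; ``clamp_mask``: cells held at their initial value.
    Returns {t: profile} at the requested times.
    """
    c = np.asarray(c0_profile, dtype=float).copy()
    nx = len(c)
    dx = L / nx
    r = D * dt / (2 * dx * dx)
    main = np.full(nx, 1 + 2 * r)
    main[0] -= r
    main[-1] -= r
    ab = np.zeros((3, nx))
    ab[0, 1:] = -r
    ab[1] = main
    ab[2, :-1] = -r
    init = c.copy()
    out = {}
    t = 0.0
    tmax = max(times)
    while t < tmax - 1e-12:
        rhs = c.copy()
        rhs[1:-1] += r * (c[2:] - 2 * c[1:-1] + c[:-2])
        rhs[0] += r * (c[1] - c[0])
        rhs[-1] += r * (c[-2] - c[-1])
        if source is not None:
            rhs += dt * source
        c = solve_banded((1, 1), ab, rhs)
        if clamp_mask is not None:
            c[clamp_mask] = init[clamp_mask]
        t += dt
        for tt in times:
            if abs(t - tt) < dt / 2:
                out[tt] = c.copy()
    return np.linspace(dx / 2, L - dx / 2, nx), out
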