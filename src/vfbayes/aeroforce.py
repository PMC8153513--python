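"""Quasi-1D Bernoulli pressure on the glottal surface and nodal loads.

Each free-surface node is a station ``s`` of a symmetric glottal channel
with local area ``A(s) = 2 (midline_x - x(s)) * l_gl`` (mm^2), floored at
a small positive value during contact.  The jet separates where the area
exceeds ``A_sep = 1.3 A_min``; downstream of separation in the area sense
the pressure recovers nothing:

    p(s) = p_sub - (p_sub - p_sup) (A_sep / A(s))^2    if A(s) < A_sep
    p(s) = p_sub                                        otherwise

The pressure acts along the inward normal of the (deformed) surface and is
integrated edge-wise with linear shape functions: a constant edge pressure
(mean of the two station values) times edge length splits equally between
the end nodes.  Forces are per unit anterior-posterior depth (N/m * m = N
per metre of depth); the glottal length enters only through the areas.

An optional mode assigns ``p_sup`` to stations superior to the minimum
section (a common physical variant); it is off by default, keeping the
printed area-only branch rule.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "RHO_AIR",
    "SEPARATION_RATIO",
    "A_FLOOR_MM2",
    "area_profile",
    "bernoulli_pressure",
    "nodal_forces",
    "flow_rate",
]

RHO_AIR = 1.14  # kg/m^3
SEPARATION_RATIO = 1.3
A_FLOOR_MM2 = 1e-3  # contact floor for the local area
MM = 1e-3


@njit(cache=True)
def _area_profile(chain_x_mm, midline_mm, l_gl_mm, a_floor):
    n = chain_x_mm.shape[0]
    A = np.empty(n)
    for i in range(n):
        a = 2.0 * (midline_mm - chain_x_mm[i]) * l_gl_mm
        A[i] = a if a > a_floor else a_floor
    return A


@njit(cache=True)
def _bernoulli(A, p_sub, p_sup, supraglottal_mode, a_sep_in=-1.0):
    n = A.shape[0]
    a_min = A[0]
    i_min = 0
    for i in range(1, n):
        if A[i] < a_min:
            a_min = A[i]
            i_min = i
    a_sep = SEPARATION_RATIO * a_min if a_sep_in <= 0.0 else a_sep_in
    p = np.empty(n)
    for i in range(n):
        if supraglottal_mode and i > i_min:
            p[i] = p_sup
        elif A[i] < a_sep:
            r = a_sep / A[i]
            p[i] = p_sub - (p_sub - p_sup) * r * r
        else:
            p[i] = p_sub
    return p, a_min


@njit(cache=True)
def _nodal_forces(p, chain_xz_mm):
    """Edge-wise pressure integration along the inward surface normal.

    The chain runs inferior -> superior with the tissue on the low-x side,
    so for an edge direction d = (dx, dz) the inward normal is
    (-dz, dx) / |d|.
    """
    n = chain_xz_mm.shape[0]
    F = np.zeros((n, 2))
    for e in range(n - 1):
        dx = (chain_xz_mm[e + 1, 0] - chain_xz_mm[e, 0]) * MM
        dz = (chain_xz_mm[e + 1, 1] - chain_xz_mm[e, 1]) * MM
        pe = 0.5 * (p[e] + p[e + 1])
        # p * L * n_hat with n_hat = (-dz, dx)/L: the length cancels
        fx = -pe * dz
        fz = pe * dx
        F[e, 0] += 0.5 * fx
        F[e, 1] += 0.5 * fz
        F[e + 1, 0] += 0.5 * fx
        F[e + 1, 1] += 0.5 * fz
    return F


def area_profile(chain_xz_mm, midline_x_mm: float, l_gl_mm: float) -> np.ndarray:
    """Local glottal area (mm^2) at each station, floored during contact."""
    chain = np.ascontiguousarray(np.asarray(chain_xz_mm, float))
    x = chain[:, 0] if chain.ndim == 2 else chain
    return _area_profile(np.ascontiguousarray(x), midline_x_mm, l_gl_mm, A_FLOOR_MM2)


def bernoulli_pressure(
    A_profile,
    p_sub: float,
    p_sup: float = 0.0,
    supraglottal_mode: bool = False,
    a_sep: float | None = None,
) -> np.ndarray:
    """Pressure (Pa) at each station from the branch rule above.

    ``a_sep`` normally derives from the profile minimum (1.3 A_min); pass
    it explicitly to evaluate the branch rule against a fixed separation
    area.  ``supraglottal_mode`` assigns p_sup to stations past the
    minimum section (the default inside the simulator; see module notes).
    """
    import warnings

    if p_sub < p_sup:
        warnings.warn("p_sub < p_sup: reversed driving pressure", stacklevel=2)
    A = np.ascontiguousarray(np.asarray(A_profile, float))
    p, _ = _bernoulli(
        A, p_sub, p_sup, supraglottal_mode, -1.0 if a_sep is None else a_sep
    )
    return p


def nodal_forces(p_profile, chain_xz_mm) -> np.ndarray:
    """(n, 2) nodal force components (unit depth) on the surface chain."""
    p = np.ascontiguousarray(np.asarray(p_profile, float))
    chain = np.ascontiguousarray(np.asarray(chain_xz_mm, float))
    return _nodal_forces(p, chain)


def flow_rate(a_min_mm2, p_sub: float, p_sup: float = 0.0) -> np.ndarray:
    """Glottal volumetric flow rate in mL/s: Q = 1.3 A_min sqrt(2 dp / rho_air).

    Zero when the glottis is closed (area at the contact floor) or when the
    driving pressure is non-positive.
    """
    a = np.asarray(a_min_mm2, float)
    dp = p_sub - p_sup
    if dp <= 0:
        return np.zeros_like(a)
    v = np.sqrt(2.0 * dp / RHO_AIR)  # m/s
    q_m3 = SEPARATION_RATIO * (a * 1e-6) * v
    q_m3 = np.where(a <= A_FLOOR_MM2, 0.0, q_m3)
    return q_m3 * 1e6  # -> mL/s
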