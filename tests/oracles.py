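"""Independent oracle implementations used only by the test suite.

Each oracle deliberately takes a different computational route from the
package code it cross-checks: brute-force grids instead of derivative
optimizers, explicit rate-constant flux sums instead of the packaged
closed form, and numeric bisection instead of analytic inversion.
"""

from __future__ import annotations

import math

import numpy as np

KB = 1.380649e-23
E0 = 1.602176634e-19


def grid_fit_nlc(v, cm, temperature=296.15, n_vh=161, n_z=81):
    """Brute-force NLC fit: grid over (V_h, z), linear solve (Q_max, C_lin).

    For fixed (V_h, z) the Boltzmann-derivative model is linear in
    Q_max and C_lin, so each grid node costs one 2x2 least-squares
    solve.  Returns (q_max, v_h, z, c_lin, sse).
    """
    v = np.asarray(v, float)
    cm = np.asarray(cm, float)
    vt = KB * temperature / E0 * 1e3  # mV
    vh_grid = np.linspace(v.min() - 30.0, v.max() + 30.0, n_vh)
    z_grid = np.linspace(0.3, 1.5, n_z)
    best = None
    ones = np.ones_like(v)
    for vh in vh_grid:
        for z in z_grid:
            b = 1.0 / (1.0 + np.exp(-z * (v - vh) / vt))
            phi = z / vt * b * (1.0 - b)  # NLC per unit Q_max
            A = np.column_stack([ones, phi])
            coef, *_ = np.linalg.lstsq(A, cm, rcond=None)
            resid = cm - A @ coef
            sse = float(resid @ resid)
            if coef[1] >= 0 and coef[0] > 0 and (best is None or sse < best[4]):
                best = (float(coef[1]), float(vh), float(z), float(coef[0]), sse)
    return best


def eyring_two_flux(v_mV, g, q, delta, p_rel, temperature=296.15):
    """Single-barrier current via explicit unidirectional fluxes.

    Outward flux crosses (1 - delta) of the field, inward flux delta,
    each an Eyring rate exponential; the prefactor is chosen so the
    P = 1 slope at 0 mV equals g.  Units follow the packaged model
    (g in pS -> current in pA).
    """
    vt = KB * temperature / E0 * 1e3  # mV
    u = q * v_mV / vt
    prefactor = g * vt / q * 1e-3
    flux_out = p_rel * math.exp((1.0 - delta) * u)
    flux_in = math.exp(-delta * u)
    return prefactor * (flux_out - flux_in)


def bisect_reversal(current_fn, lo=-400.0, hi=400.0, tol=1e-9):
    """Numeric bisection of a current function's zero crossing, mV."""
    flo, fhi = current_fn(lo), current_fn(hi)
    assert flo < 0 < fhi, "reversal not bracketed"
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if current_fn(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def grid_perm_ratio(e_rev_mV, cat_in, cat_out, an_in, an_out,
                    temperature=296.15, n=100_000):
    """Dense log-spaced grid search for the anion/cation permeability
    ratio reproducing a measured reversal potential (two-ion case)."""
    vt = KB * temperature / E0 * 1e3
    ratios = np.geomspace(1e-4, 1e4, n)
    e = vt * np.log((cat_out + ratios * an_in) / (cat_in + ratios * an_out))
    return float(ratios[np.argmin(np.abs(e - e_rev_mV))])
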