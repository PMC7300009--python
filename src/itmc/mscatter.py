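"""Goudsmit-Saunderson multiple elastic scattering.

The angular distribution after a condensed step of ``t = Sigma_SR * s``
elastic mean free paths in a medium with screening parameter ``eta`` is the
Legendre series

    F_GS(mu, t, eta) = sum_l (l + 1/2) P_l(mu) exp(-t g_l(eta)),

with moments ``g_l`` of the screened-Rutherford single-scattering density.
Moments below ``GS_ORDER_SWITCH`` are computed by quadrature; above it the
small-angle closed form ``1 - y K_1(y)``, ``y = 2 sqrt(l(l+1) eta)`` is
used (the two agree to better than 0.01% at order 100 over the supported
eta range).

Direct tabulation of F_GS is hopeless for linear interpolation because the
distribution is extremely forward peaked, so sampling goes through the
spreading transformation ``u = (1+A)(1 - 2A / (1 + 2A - mu))`` which maps
mu in [-1, 1] to u in [0, 1] and flattens the density to near-uniform for a
well chosen spreading parameter ``A(t, eta)``.  A three-dimensional inverse
CDF of u over (xi, log t, log eta) is precompiled once; sampling is one
uniform number, a trilinear interpolation, and the closed-form back
transformation to mu.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import eval_legendre, k1

from .inverse_cdf import InverseCdfTable, default_xi_grid

GS_ORDER_SWITCH = 100
T_RANGE = (1e1, 1e5)
ETA_RANGE = (1e-9, 1e-3)

_N_T, _N_ETA, _N_U = 32, 32, 512
_MAX_TERMS = 250_000
_BLOCK = 512

# Gauss-Legendre nodes in v = ln(s + 2 eta), s = 1 - mu: resolves the
# near-singular forward peak of the screened-Rutherford density
_GL_X, _GL_W = np.polynomial.legendre.leggauss(4000)


def _exact_moments(l_values: np.ndarray, eta: float) -> np.ndarray:
    """g_l by quadrature of (1 - P_l(mu)) p(mu, eta) over mu in [-1, 1]."""
    lo, hi = math.log(2.0 * eta), math.log(2.0 + 2.0 * eta)
    v = 0.5 * (hi - lo) * (_GL_X + 1.0) + lo
    jac = 0.5 * (hi - lo)
    s = np.exp(v) - 2.0 * eta
    mu = 1.0 - s
    weight = 2.0 * eta * (1.0 + eta) / (s + 2.0 * eta) * jac * _GL_W
    P = eval_legendre(np.asarray(l_values)[:, None], mu[None, :])
    return (1.0 - P) @ weight


def gs_moment(l, eta, order_switch: int = GS_ORDER_SWITCH):
    """Goudsmit-Saunderson moment g_l(eta).

    Exact quadrature below ``order_switch``; Kawrakow-Bielajew small-angle
    closed form at or above it.
    """
    l_arr = np.atleast_1d(np.asarray(l, dtype=int))
    eta = float(eta)
    if eta <= 0.0:
        raise ValueError("screening parameter must be positive")
    out = np.empty(l_arr.shape, dtype=float)
    lo = l_arr < order_switch
    if np.any(lo):
        out[lo] = _exact_moments(l_arr[lo], eta)
    if np.any(~lo):
        out[~lo] = small_angle_moment(l_arr[~lo], eta)
    out[l_arr == 0] = 0.0
    return out if np.ndim(l) else float(out[0])


def small_angle_moment(l, eta):
    """1 - y K1(y) with y = 2 sqrt(l(l+1) eta)."""
    l = np.asarray(l, dtype=float)
    y = 2.0 * np.sqrt(l * (l + 1.0) * eta)
    out = np.where(y > 0, 1.0 - y * k1(np.maximum(y, 1e-300)), 0.0)
    return out


def g1_closed_form(eta: float) -> float:
    """<1 - mu> of the screened-Rutherford density (closed form)."""
    return (2.0 * eta * (1.0 + eta) * (math.log((1.0 + eta) / eta) - 1.0)
            + 2.0 * eta**2)


_MOMENT_CACHE: dict[float, np.ndarray] = {}


def _moment_array(n_terms: int, eta: float) -> np.ndarray:
    cached = _MOMENT_CACHE.get(eta)
    if cached is not None and cached.size >= n_terms:
        return cached[:n_terms]
    l = np.arange(n_terms)
    g = small_angle_moment(l, eta)
    n_exact = min(GS_ORDER_SWITCH, n_terms)
    g[:n_exact] = _exact_moments(l[:n_exact], eta)
    g[0] = 0.0
    if len(_MOMENT_CACHE) > 64:
        _MOMENT_CACHE.clear()
    _MOMENT_CACHE[eta] = g
    return g


def f_gs(mu, t, eta, rtol: float = 1e-7, max_terms: int = _MAX_TERMS,
         return_terms: bool = False):
    """Evaluate the smooth part of F_GS(mu, t, eta) by Legendre summation.

    The returned density excludes the no-scattering point mass
    ``exp(-t)`` at mu = 1 (negligible for t >= 10 but kept explicit in the
    table builder); it integrates to ``1 - exp(-t)``.  Terms are summed in
    blocks with the asymptotic tail ``(l + 1/2) P_l exp(-t)`` subtracted,
    which converges absolutely; summation stops when a whole block changes
    the result by less than ``rtol`` relative.
    """
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    if t <= 0 or eta <= 0:
        raise ValueError("t and eta must be positive")
    e_t = math.exp(-t)
    total = np.zeros_like(mu)
    p_prev = np.ones_like(mu)          # P_0
    p_curr = mu.copy()                 # P_1
    l_done = 0
    n_alloc = _BLOCK
    g = _moment_array(n_alloc, eta)
    converged = False
    while l_done < max_terms:
        hi = l_done + _BLOCK
        if hi > g.size:
            g = _moment_array(min(max(2 * g.size, hi), max_terms + _BLOCK),
                              eta)
        block = np.zeros_like(mu)
        for l in range(l_done, hi):
            if l == 0:
                P = p_prev
            elif l == 1:
                P = p_curr
            else:
                P = ((2 * l - 1) * mu * p_curr - (l - 1) * p_prev) / l
                p_prev, p_curr = p_curr, P
            w = math.exp(-t * g[l]) - e_t
            if w != 0.0:
                block += (l + 0.5) * w * P
        total += block
        l_done = hi
        scale = np.max(np.abs(total)) + 1e-300
        if np.max(np.abs(block)) < rtol * scale:
            converged = True
            break
    if not converged:
        raise RuntimeError(
            f"GS series did not converge after {l_done} terms "
            f"(t={t:g}, eta={eta:g})")
    out = np.clip(total, 0.0, None)
    if return_terms:
        return out, l_done
    return out if np.ndim(mu) else float(out[0])


def _f_gs_matrix(mu: np.ndarray, t_values: np.ndarray, eta: float,
                 rtol: float = 1e-7) -> np.ndarray:
    """Smooth F_GS on a mu grid for many t at once (shared moments).

    Blocked Legendre recurrence with matrix accumulation; returns an array
    of shape (n_t, n_mu).
    """
    e_t = np.exp(-t_values)[:, None]
    total = np.zeros((t_values.size, mu.size))
    g = _moment_array(_BLOCK, eta)
    p_prev = np.ones_like(mu)
    p_curr = mu.copy()
    l_done = 0
    while l_done < _MAX_TERMS:
        hi = l_done + _BLOCK
        if hi > g.size:
            g = _moment_array(min(max(2 * g.size, hi),
                                  _MAX_TERMS + _BLOCK), eta)
        P_block = np.empty((_BLOCK, mu.size))
        for j, l in enumerate(range(l_done, hi)):
            if l == 0:
                P = p_prev
            elif l == 1:
                P = p_curr
            else:
                P = ((2 * l - 1) * mu * p_curr - (l - 1) * p_prev) / l
                p_prev, p_curr = p_curr, P
            P_block[j] = P
        l_arr = np.arange(l_done, hi)
        W = (l_arr + 0.5)[None, :] * (
            np.exp(-np.outer(t_values, g[l_done:hi])) - e_t)
        block = W @ P_block
        total += block
        l_done = hi
        if np.max(np.abs(block)) < rtol * (np.max(np.abs(total)) + 1e-300):
            break
    else:
        raise RuntimeError("GS series did not converge in matrix build")
    return np.clip(total, 0.0, None)


def spreading_A(t, eta):
    """Spreading parameter A(t, eta) (hard-coded semi-empirical fit)."""
    t = np.asarray(t, dtype=float)
    x = np.log(t)
    poly = -1.293 + x * (1.434 - x * (0.07152 - 0.002553 * x))
    return np.asarray(eta, dtype=float) * (t + 4.0) * poly


def u_transform(mu, A):
    """mu in [-1, 1] -> u in [0, 1]; mu=1 -> u=0, mu=-1 -> u=1."""
    mu = np.asarray(mu, dtype=float)
    A = np.asarray(A, dtype=float)
    return (1.0 + A) * (1.0 - 2.0 * A / (1.0 + 2.0 * A - mu))

def u_inverse(u, A):
    """Inverse of the spreading transformation."""
    u = np.asarray(u, dtype=float)
    A = np.asarray(A, dtype=float)
    return 1.0 - 2.0 * A * u / (1.0 + A - u)


def q_sr(u, t, eta, A=None):
    """Transformed multiple-scattering density of u (Eq. of the
    spreading transformation applied to F_GS); integrates to ~1 for t
    large enough that the no-scatter atom is negligible."""
    u = np.asarray(u, dtype=float)
    if A is None:
        A = spreading_A(t, eta)
    mu = u_inverse(u, A)
    return 2.0 * A * (1.0 + A) / (1.0 + A - u) ** 2 * f_gs(mu, t, eta)


def variational_A(t: float, eta: float) -> float:
    """Solve the flatness condition for A directly (test oracle).

    Minimizes int (q_SR(u) - 1)^2 du over A by golden-section search; the
    production code uses the hard-coded fit instead.
    """
    from scipy.optimize import minimize_scalar
    u = np.linspace(1e-4, 1.0 - 1e-4, 201)
    F_cache: dict[float, np.ndarray] = {}

    def cost(logA):
        A = math.exp(logA)
        mu = u_inverse(u, A)
        f = f_gs(mu, t, eta)
        q = 2.0 * A * (1.0 + A) / (1.0 + A - u) ** 2 * f
        return float(np.mean((q - 1.0) ** 2))

    A0 = float(spreading_A(t, eta))
    res = minimize_scalar(cost, bracket=(math.log(A0) - 1.5,
                                         math.log(A0) + 1.5))
    return math.exp(res.x)


class MsTables:
    """Precompiled 3-D inverse q_SR table: u over (xi, log t, log eta)."""

    def __init__(self, table: InverseCdfTable, order_switch: int):
        self.qsr_inverse = table
        self.gs_order_switch = order_switch
        self.clamp_count = 0

    def sample_mu(self, xi, t, eta):
        """One uniform number -> deflection cosine after a condensed step.

        Out-of-range (t, eta) are clamped to the table edges and counted.
        """
        t = np.asarray(t, dtype=float)
        eta = np.asarray(eta, dtype=float)
        n_clamped = int(np.count_nonzero(
            (t < T_RANGE[0]) | (t > T_RANGE[1])
            | (eta < ETA_RANGE[0]) | (eta > ETA_RANGE[1])))
        if n_clamped:
            self.clamp_count += n_clamped
        tc = np.clip(t, *T_RANGE)
        ec = np.clip(eta, *ETA_RANGE)
        u = self.qsr_inverse.sample(xi, np.log(tc), np.log(ec))
        u = np.clip(u, 0.0, 1.0)
        return u_inverse(u, spreading_A(tc, ec))


_MS_CACHE: MsTables | None = None


def build_ms_table(n_t: int = _N_T, n_eta: int = _N_ETA,
                   n_u: int = _N_U) -> MsTables:
    """Build the 3-D inverse multiple-scattering table.

    For every (t, eta) grid point the transformed density q_SR(u) is
    evaluated on a fine u grid (including the explicit no-scattering atom
    exp(-t) at u = 0) and inverted onto the common xi grid.
    """
    t_grid = np.geomspace(*T_RANGE, n_t)
    eta_grid = np.geomspace(*ETA_RANGE, n_eta)
    xi = default_xi_grid()
    u = np.linspace(0.0, 1.0, n_u)
    values = np.empty((xi.size, n_t, n_eta))
    for k, eta in enumerate(eta_grid):
        A = spreading_A(t_grid, eta)            # (n_t,)
        mu_cols = u_inverse(u[None, :], A[:, None])
        # evaluate F_GS on the union mu grid column by column in t
        for j, t in enumerate(t_grid):
            f = _f_gs_matrix(mu_cols[j], np.array([t]), eta)[0]
            q = 2.0 * A[j] * (1.0 + A[j]) / (1.0 + A[j] - u) ** 2 * f
            cdf = np.concatenate(
                [[0.0], np.cumsum(0.5 * (q[1:] + q[:-1]) * np.diff(u))])
            atom = math.exp(-t)
            cdf = (atom + cdf) / (atom + cdf[-1])
            cdf[0] = 0.0
            cdf = np.maximum.accumulate(cdf)
            cdf += np.linspace(0.0, 1e-12, cdf.size)
            cdf /= cdf[-1]
            col = np.interp(xi, cdf, u)
            col[0], col[-1] = 0.0, 1.0
            values[:, j, k] = np.maximum.accumulate(col)
    table = InverseCdfTable(
        axes=[xi, np.log(t_grid), np.log(eta_grid)], values=values)
    return MsTables(table, GS_ORDER_SWITCH)


def get_ms_tables() -> MsTables:
    """Module-level cached multiple-scattering tables."""
    global _MS_CACHE
    if _MS_CACHE is None:
        _MS_CACHE = build_ms_table()
    return _MS_CACHE
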