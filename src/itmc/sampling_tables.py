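"""Builders for the photon / electron inverse-CDF sampling tables.

Angular maps for coherent and incoherent photon scattering follow the
published grid convention: the deflection cosine axis carries 100 points on
[-1, 1] and the log-energy axis 250 points on log E in [-6.91, 6.42]
(E in MeV).  Transport clamps queries to the supported 1 keV - 100 MeV
range.  Bremsstrahlung photon-energy fractions and Moller knock-on
energies are tabulated over (xi, log T).
"""

from __future__ import annotations

import math

import numpy as np

from .constants import M_E_C2
from .elements import Element
from .inverse_cdf import (InverseCdfTable, build_inverse_cdf,
                          default_xi_grid, invert_cdf_columns)
from .materials import Material
from . import xs

MU_GRID_N = 100
LOGE_GRID_N = 250
LOGE_RANGE = (-6.91, 6.42)

_MU_GRID = np.linspace(-1.0, 1.0, MU_GRID_N)
_LOGE_GRID = np.linspace(*LOGE_RANGE, LOGE_GRID_N)


def _element_list(target) -> list[tuple[Element, float]]:
    if isinstance(target, Material):
        return list(zip(target.elements, target.number_densities))
    return [(target, 1.0)]


def _column_mu_grid(alpha: float) -> np.ndarray:
    """Per-energy integration grid for the photon angular maps.

    The published map axes are (xi, log E) with a 100-point uniform mu
    backbone, but at MeV energies the coherent forward peak (and the
    incoherent-function notch) live entirely inside the last uniform
    cell, because the relevant scale is the momentum transfer
    q = k alpha sqrt(1 - mu).  The column CDF is therefore integrated on
    the union of the uniform backbone with points log-spaced in q, which
    resolves the peak at every energy; the inverse CDF is then stored on
    the standard xi grid.
    """
    from .constants import K_COH
    q_max = K_COH * alpha * math.sqrt(2.0)
    q = np.geomspace(max(q_max * 1e-7, 1e-7), q_max, 700)
    mu_q = 1.0 - (q / (K_COH * alpha)) ** 2
    grid = np.union1d(_MU_GRID, np.clip(mu_q, -1.0, 1.0))
    return np.unique(grid)


class CoherentMuMap:
    """Coherent-scattering angular map sampled in momentum-transfer space.

    The quantiles are stored as y = (1 - mu) alpha^2 (proportional to the
    squared momentum transfer), which is nearly energy-independent where
    the form factor dominates, so the interpolation between the published
    log-E columns is benign even though the forward peak position scales
    as 1/alpha^2.  ``sample`` converts back to the scattering cosine with
    the query energy.
    """

    def __init__(self, table: InverseCdfTable):
        self.table = table

    def sample(self, xi, log_E):
        log_E = np.asarray(log_E, dtype=float)
        alpha2 = np.exp(2.0 * (log_E - math.log(M_E_C2)))
        y = self.table.sample(xi, log_E)
        return np.clip(1.0 - y / alpha2, -1.0, 1.0)

    @property
    def values(self):
        return self.table.values

    @property
    def axes(self):
        return self.table.axes


def build_coherent_mu_map(target) -> CoherentMuMap:
    """Angular map of the coherent scattering cosine over (xi, log E).

    The per-energy density is (1 + mu^2) F0^2(Z, q(mu, E)), weighted over
    the elements of a material by number density.
    """
    E = np.exp(_LOGE_GRID)
    # the form-factor quantile has sharp shoulders: a denser xi grid than
    # the shared 256-point default keeps the interpolated CDF within the
    # sampler-vs-oracle tolerance
    xi = default_xi_grid(1024)
    values = np.empty((xi.size, LOGE_GRID_N))
    for j, Ej in enumerate(E):
        alpha = Ej / M_E_C2
        mu = _column_mu_grid(alpha)
        pdf = np.zeros_like(mu)
        for elem, w in _element_list(target):
            pdf += w * xs.coherent_dcs(elem, Ej, mu)
        col = build_inverse_cdf(pdf, mu, xi, refine=2)
        # y decreases along xi (mu increases); store reversed so the
        # table is a proper increasing quantile function — the xi grid is
        # symmetric, so the sampled distribution is unchanged and
        # xi = 1 still maps to backscatter (mu = -1)
        values[:, j] = ((1.0 - col.values) * alpha**2)[::-1]
    return CoherentMuMap(InverseCdfTable(
        axes=[xi, _LOGE_GRID.copy()],
        values=np.maximum.accumulate(values, axis=0)))


def build_incoherent_mu_map(target, free_electron: bool = False
                            ) -> InverseCdfTable:
    """Inverse-CDF map of the Compton scattering cosine over (xi, log E).

    Density S(Z, q) K(alpha, mu), normalized numerically per energy
    column.  ``free_electron=True`` drops the incoherent scattering
    function (S = Z), reducing sampling to pure Klein-Nishina — used by
    the Fano-mode idealization.
    """
    E = np.exp(_LOGE_GRID)
    xi = default_xi_grid()
    values = np.empty((xi.size, LOGE_GRID_N))
    for j, Ej in enumerate(E):
        alpha = Ej / M_E_C2
        mu = _column_mu_grid(alpha)
        K = xs.klein_nishina_dcs(alpha, mu)
        pdf = np.zeros_like(mu)
        for elem, w in _element_list(target):
            if free_electron:
                S = float(elem.Z)
            else:
                S = elem.S(xs.momentum_transfer(alpha, mu))
            pdf += w * S * K
        col = build_inverse_cdf(pdf, mu, xi, refine=2)
        values[:, j] = col.values
    return InverseCdfTable(axes=[xi, _LOGE_GRID.copy()], values=values)


_K_GRID_N = 160
_W_GRID_N = 160
_LOGT_GRID_N = 120


def build_brems_k_table(material: Material, E_B: float,
                        T_range=(1.05e-2, 100.0)) -> InverseCdfTable:
    """Inverse CDF of the radiated energy fraction k over (xi, log T).

    Per T column the density is the linear-fit spectrum summed over
    elements, sum_i n_i Z_i^2 a_i (1 - b_i k) / k on k in [k_B, 1] with
    k_B = E_B / T.  Columns with T <= E_B have empty support and are
    marked invalid.
    """
    logT = np.linspace(math.log(T_range[0]), math.log(T_range[1]),
                       _LOGT_GRID_N)
    T = np.exp(logT)
    xi = default_xi_grid()
    values = np.empty((xi.size, T.size))
    valid = T > E_B
    # sample in y = ln(k/k_B) so the 1/k singularity integrates exactly
    for j, Tj in enumerate(T):
        if not valid[j]:
            values[:, j] = 1.0
            continue
        kB = E_B / Tj
        y = np.linspace(0.0, math.log(1.0 / kB), _K_GRID_N)
        k = kB * np.exp(y)
        pdf = np.zeros_like(k)
        for elem, n in zip(material.elements, material.number_densities):
            pdf += n * elem.Z**2 * elem.brems_a * (1.0 - elem.brems_b * k)
        cdf = np.concatenate(
            [[0.0], np.cumsum(0.5 * (pdf[1:] + pdf[:-1]) * np.diff(y))])
        cdf /= cdf[-1]
        col = np.interp(xi, cdf, k)
        col[0], col[-1] = kB, 1.0
        values[:, j] = np.maximum.accumulate(col)
    return InverseCdfTable(axes=[xi, logT], values=values, valid=valid)


def build_moller_w_table(material: Material, E_M: float,
                         T_range=None) -> InverseCdfTable:
    """Inverse CDF of the knock-on energy W over (xi, log T).

    W is tabulated as the fraction eps = W / T on [E_M / T, 1/2] with the
    Moller density; columns with T < 2 E_M are invalid (no catastrophic
    collision possible).
    """
    if T_range is None:
        T_range = (2.0 * E_M * 1.0001, 100.0)
    logT = np.linspace(math.log(T_range[0]), math.log(T_range[1]),
                       _LOGT_GRID_N)
    T = np.exp(logT)
    xi = default_xi_grid()
    values = np.empty((xi.size, T.size))
    valid = T > 2.0 * E_M
    for j, Tj in enumerate(T):
        if not valid[j]:
            values[:, j] = 0.5
            continue
        eps0 = E_M / Tj
        # log-spaced eps resolves the 1/W^2 peak at the threshold
        eps = np.geomspace(eps0, 0.5, _W_GRID_N)
        pdf = xs.moller_dcs(Tj, eps * Tj, element_Z=1.0)
        cdf = np.concatenate(
            [[0.0], np.cumsum(0.5 * (pdf[1:] + pdf[:-1]) * np.diff(eps))])
        cdf /= cdf[-1]
        col = np.interp(xi, cdf, eps)
        col[0], col[-1] = eps0, 0.5
        values[:, j] = np.maximum.accumulate(col)
    return InverseCdfTable(axes=[xi, logT], values=values, valid=valid)


def build_compton_profile_tables(element: Element) -> dict[str, InverseCdfTable]:
    """Per-shell inverse CDFs of the projected momentum p_z (a.u.)."""
    from .elements import _profile_ppf
    xi = default_xi_grid(512)
    out = {}
    for sh in element.shells:
        pz = _profile_ppf(np.clip(xi, 1e-9, 1.0 - 1e-9), sh.p0)
        pz[0], pz[-1] = pz[1] - 1.0, pz[-2] + 1.0
        out[sh.label] = InverseCdfTable(
            axes=[xi], values=np.maximum.accumulate(pz))
    return out
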