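"""Cross sections and stopping powers evaluated by the transport engine.

Photon side: Klein-Nishina (optionally modified by the incoherent
scattering function), Thomson x form-factor coherent scattering,
photoelectric absorption with subshell selection, and pair production.
Electron side: Moller inelastic scattering and bremsstrahlung above the
catastrophic thresholds, the restricted (collision + radiative) stopping
power below them, and screened-Rutherford elastic scattering parameters.

Conventions: photon energy ``alpha`` is in electron rest-mass units, all
other energies in MeV; ``mu`` is the cosine of the polar scattering angle;
microscopic cross sections in cm^2, macroscopic in 1/cm.
"""

from __future__ import annotations

import math

import numpy as np

from .constants import K_COH, M_E_C2, N_A, R_E
from .elements import ENERGY_GRID, Element
from .materials import Material

_TWO_PI_RE2_MEC2 = 2.0 * math.pi * R_E**2 * M_E_C2

# ---------------------------------------------------------------------------
# Compton / Klein-Nishina


def compton_kinematics(alpha, mu):
    """Scattered photon energy and recoil kinetic energy for free Compton.

    Returns ``(alpha_prime, T_electron_MeV)``.
    """
    alpha = np.asarray(alpha, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if np.any(alpha <= 0.0):
        raise ValueError("photon energy must be positive")
    if np.any((mu < -1.0) | (mu > 1.0)):
        raise ValueError("scattering cosine outside [-1, 1]")
    alpha_prime = alpha / (1.0 + alpha * (1.0 - mu))
    return alpha_prime, (alpha - alpha_prime) * M_E_C2


def klein_nishina_dcs(alpha, mu):
    """Klein-Nishina dsigma/dmu per electron (cm^2)."""
    alpha_prime, _ = compton_kinematics(alpha, mu)
    r = alpha_prime / np.asarray(alpha, dtype=float)
    mu = np.asarray(mu, dtype=float)
    return math.pi * R_E**2 * r**2 * (r + 1.0 / r + mu**2 - 1.0)


def klein_nishina_total(alpha):
    """Integrated Klein-Nishina cross section per electron (closed form)."""
    a = np.asarray(alpha, dtype=float)
    t1 = (1.0 + a) / a**2 * (2.0 * (1.0 + a) / (1.0 + 2.0 * a)
                             - np.log1p(2.0 * a) / a)
    return 2.0 * math.pi * R_E**2 * (
        t1 + np.log1p(2.0 * a) / (2.0 * a) - (1.0 + 3.0 * a)
        / (1.0 + 2.0 * a) ** 2)


def momentum_transfer(alpha, mu):
    """q (1/Angstrom) for photon energy alpha scattered through mu."""
    alpha = np.asarray(alpha, dtype=float)
    mu = np.asarray(mu, dtype=float)
    return K_COH * alpha * np.sqrt(np.clip(1.0 - mu, 0.0, None))


def atomic_factors(element: Element, q):
    """Interpolated (F0, S) at momentum transfer q >= 0 (1/Angstrom)."""
    q = np.asarray(q, dtype=float)
    if np.any(q < 0.0):
        raise ValueError("momentum transfer must be nonnegative")
    return element.f0(q), element.S(q)


def coherent_dcs(element: Element, E, mu):
    """Coherent (Rayleigh) dsigma/dmu (cm^2): pi r_e^2 (1+mu^2) F0^2.

    Anomalous scattering factors are taken as zero, so only the real form
    factor F0 enters.
    """
    alpha = np.asarray(E, dtype=float) / M_E_C2
    mu = np.asarray(mu, dtype=float)
    if np.any((mu < -1.0) | (mu > 1.0)):
        raise ValueError("scattering cosine outside [-1, 1]")
    q = momentum_transfer(alpha, mu)
    f0, _ = atomic_factors(element, q)
    return math.pi * R_E**2 * (1.0 + mu**2) * f0**2


def incoherent_dcs(element: Element, E, mu):
    """Bound-Compton dsigma/dmu: S(Z, q) * K(alpha, mu) (cm^2)."""
    alpha = np.asarray(E, dtype=float) / M_E_C2
    q = momentum_transfer(alpha, mu)
    _, S = atomic_factors(element, q)
    return S * klein_nishina_dcs(alpha, mu)


_MU_QUAD_X, _MU_QUAD_W = np.polynomial.legendre.leggauss(512)

_element_photon_tables: dict[int, dict[str, np.ndarray]] = {}


def _photon_tables(element: Element) -> dict[str, np.ndarray]:
    """Per-element integrated coherent/incoherent cross sections on the
    shared energy grid (Gauss-Legendre quadrature over mu)."""
    key = id(element)
    if key not in _element_photon_tables:
        alpha = ENERGY_GRID / M_E_C2
        mu = _MU_QUAD_X[None, :]
        a = alpha[:, None]
        coh = coherent_dcs(element, ENERGY_GRID[:, None]
                           * np.ones_like(mu), np.broadcast_to(
                               mu, (alpha.size, mu.size)))
        inc = incoherent_dcs(element, ENERGY_GRID[:, None]
                             * np.ones_like(mu), np.broadcast_to(
                                 mu, (alpha.size, mu.size)))
        del a
        _element_photon_tables[key] = {
            "coherent": coh @ _MU_QUAD_W,
            "incoherent": inc @ _MU_QUAD_W,
        }
    return _element_photon_tables[key]


def element_photon_xs(element: Element, E, channel: str):
    """Interpolated integrated cross section (cm^2) for one channel."""
    E = np.asarray(E, dtype=float)
    if channel in ("coherent", "incoherent"):
        table = _photon_tables(element)[channel]
    elif channel == "photoelectric":
        table = element.pe_xs
    elif channel == "pair":
        table = element.pair_xs
    else:
        raise ValueError(f"unknown channel {channel!r}")
    logE = np.log(np.clip(E, ENERGY_GRID[0], ENERGY_GRID[-1]))
    return np.interp(logE, np.log(ENERGY_GRID), table)


PHOTON_CHANNELS = ("coherent", "incoherent", "photoelectric", "pair")


def photoelectric(element: Element, E):
    """(sigma_pe, subshell probabilities) at photon energy E (MeV)."""
    E = np.asarray(E, dtype=float)
    logE = np.log(np.clip(E, ENERGY_GRID[0], ENERGY_GRID[-1]))
    lg = np.log(ENERGY_GRID)
    sigma = np.interp(logE, lg, element.pe_xs)
    sigma = np.where(E < ENERGY_GRID[0], 0.0, sigma)
    # subshell availability is a hard edge: recompute fractions at E rather
    # than interpolating across an edge
    strengths = np.array(
        [s.occupancy * (s.binding_energy / element.shells[0].binding_energy)
         ** 1.5 for s in element.shells])
    open_shell = np.array([E > s.binding_energy for s in element.shells],
                          dtype=float)
    weighted = strengths.reshape((-1,) + (1,) * E.ndim) * open_shell
    tot = weighted.sum(axis=0)
    probs = weighted / np.maximum(tot, 1e-300)
    return sigma, probs


def photon_macro_xs(material: Material, E, include_coherent: bool = True):
    """Total macroscopic photon cross section and branch probabilities.

    Returns ``(Sigma_total 1/cm, {channel: probability})``.  The pair
    branch is zero below 2 m_e c^2 by construction of the fixture tables.
    """
    E = np.asarray(E, dtype=float)
    if np.any((E < 1e-3) | (E > 100.0)):
        raise ValueError("photon energy outside supported 1 keV - 100 MeV")
    sigmas = {}
    for ch in PHOTON_CHANNELS:
        tot = np.zeros_like(E, dtype=float)
        for elem, n in zip(material.elements, material.number_densities):
            tot = tot + n * element_photon_xs(elem, E, ch)
        sigmas[ch] = tot
    if not include_coherent:
        sigmas["coherent"] = np.zeros_like(sigmas["coherent"])
    total = sum(sigmas.values())
    probs = {ch: sigmas[ch] / total for ch in sigmas}
    return total, probs


# ---------------------------------------------------------------------------
# Moller / bremsstrahlung


def _beta2_tau(T):
    T = np.asarray(T, dtype=float)
    tau = T / M_E_C2
    beta2 = 1.0 - 1.0 / (1.0 + tau) ** 2
    return beta2, tau


def moller_dcs(T, W, element_Z: float = 1.0):
    """Moller dsigma/dW (cm^2/MeV) per atom of atomic number element_Z."""
    T = np.asarray(T, dtype=float)
    W = np.asarray(W, dtype=float)
    beta2, tau = _beta2_tau(T)
    g2 = (tau / (tau + 1.0)) ** 2
    h = (2.0 * tau + 1.0) / (tau + 1.0) ** 2
    pref = _TWO_PI_RE2_MEC2 * element_Z / (beta2 * W**2)
    return pref * (1.0 + W**2 / (T - W) ** 2 + g2 * (W / T) ** 2
                   - h * W / (T - W))


def moller_xs(T, E_M: float, material: Material):
    """Total macroscopic Moller cross section Sigma_M (1/cm).

    Zero when no catastrophic collision is possible (E_M > T/2).
    """
    T = np.asarray(T, dtype=float)
    beta2, tau = _beta2_tau(T)
    nZ = material.electron_density
    with np.errstate(divide="ignore", invalid="ignore"):
        eps = E_M / T
        g2 = (tau / (tau + 1.0)) ** 2
        h = (2.0 * tau + 1.0) / (tau + 1.0) ** 2
        bracket = ((1.0 - 2.0 * eps) / (eps * (1.0 - eps))
                   + g2 * (0.5 - eps) - h * np.log((1.0 - eps) / eps))
        out = _TWO_PI_RE2_MEC2 * nZ / (beta2 * T) * bracket
    return np.where(eps >= 0.5, 0.0, np.clip(out, 0.0, None))


def brems_dcs(T, k, element: Element):
    """Bremsstrahlung dsigma/dk per atom with the linear-fit spectrum."""
    T = np.asarray(T, dtype=float)
    k = np.asarray(k, dtype=float)
    beta2, _ = _beta2_tau(T)
    f = element.brems_a * (1.0 - element.brems_b * k)
    return element.Z**2 / (beta2 * k) * f


def brems_xs(T, E_B: float, material: Material):
    """Total macroscopic catastrophic bremsstrahlung cross section (1/cm)."""
    T = np.asarray(T, dtype=float)
    beta2, _ = _beta2_tau(T)
    with np.errstate(divide="ignore", invalid="ignore"):
        kB = E_B / T
        out = np.zeros_like(T, dtype=float)
        for elem, n in zip(material.elements, material.number_densities):
            out = out + (elem.brems_a * n * elem.Z**2 / beta2
                         * (np.log(1.0 / kB)
                            - elem.brems_b * (1.0 - kB)))
    return np.where(kB >= 1.0, 0.0, np.clip(out, 0.0, None))


def restricted_stopping_power(T, material: Material, E_M: float, E_B: float,
                              include_delta: bool = True):
    """Restricted stopping power L = L_c + L_B (MeV/cm).

    ``L_c`` combines the Bethe soft-collision term with the Moller spectrum
    integrated up to ``min(E_M, T/2)``; ``L_B`` integrates the linear-fit
    bremsstrahlung spectrum up to ``E_B``.  ``include_delta=False`` drops
    the density-effect correction (used by the Fano-mode idealization).
    """
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0.0):
        raise ValueError("kinetic energy must be positive")
    beta2, tau = _beta2_tau(T)
    eps = np.minimum(E_M / T, 0.5)
    pref = _TWO_PI_RE2_MEC2 * material.electron_density / beta2
    F = (-1.0 - beta2 + np.log(eps * (1.0 - eps)) + 1.0 / (1.0 - eps)
         + (1.0 - beta2) * (tau**2 * eps**2 / 2.0
                            + (2.0 * tau + 1.0) * np.log(1.0 - eps)))
    delta = material.density_effect.delta(T) if include_delta else 0.0
    L_c = pref * (np.log(2.0 * (tau + 2.0) * T**2 / material.I**2)
                  + F - delta)
    L_B = np.zeros_like(T, dtype=float)
    eb = np.minimum(E_B, T)
    for elem, n in zip(material.elements, material.number_densities):
        L_B = L_B + (elem.brems_a * n * elem.Z**2 * eb / beta2
                     * (1.0 - elem.brems_b * eb / (2.0 * T)))
    return np.clip(L_c, 1e-12, None) + L_B


# ---------------------------------------------------------------------------
# Elastic scattering (screened Rutherford, Moliere screening)


def screened_rutherford_pdf(mu, eta):
    """Normalized single elastic scattering density p(mu, eta)."""
    mu = np.asarray(mu, dtype=float)
    return 2.0 * eta * (1.0 + eta) / (1.0 + 2.0 * eta - mu) ** 2


def elastic_parameters(T, material: Material):
    """(eta, Sigma_SR) for electrons of kinetic energy T in a material.

    Moliere screening: eta = chi_a^2 / 4 with
    chi_a^2 = chi_0^2 (1.13 + 3.76 (alpha Z / beta)^2),
    chi_0 = alpha_fs Z^(1/3) (m_e c / p) / 0.885.
    The screened-Rutherford total cross section per atom is
    pi r_e^2 Z (Z+1) (m_e c^2 / (p c))^2 / (beta^2 eta (1 + eta)); the
    Z(Z+1) factor folds scattering off atomic electrons into the nuclear
    term.  For mixtures eta is the Z(Z+1)-weighted average.
    """
    T = np.asarray(T, dtype=float)
    beta2, tau = _beta2_tau(T)
    pc2 = T * (T + 2.0 * M_E_C2)
    alpha_fs = 1.0 / 137.035999
    eta_acc = np.zeros_like(T, dtype=float)
    w_acc = np.zeros_like(T, dtype=float)
    sigma_acc = np.zeros_like(T, dtype=float)
    for elem, n in zip(material.elements, material.number_densities):
        Z = elem.Z
        chi0_sq = (alpha_fs * Z ** (1.0 / 3.0) / 0.885) ** 2 \
            * M_E_C2**2 / pc2
        chi_a_sq = chi0_sq * (1.13 + 3.76 * (alpha_fs * Z) ** 2 / beta2)
        eta_i = chi_a_sq / 4.0
        w = n * Z * (Z + 1.0)
        sigma_i = (math.pi * R_E**2 * Z * (Z + 1.0) * M_E_C2**2
                   / (pc2 * beta2 * eta_i * (1.0 + eta_i)))
        eta_acc = eta_acc + w * eta_i
        w_acc = w_acc + w
        sigma_acc = sigma_acc + n * sigma_i
    return eta_acc / w_acc, sigma_acc


# ---------------------------------------------------------------------------
# Energy-transfer coefficient (Fano theory)


def kn_energy_transfer_coeff(material: Material, E,
                             include_other_channels: bool = False):
    """Mass energy-transfer coefficient mu_tr/rho (cm^2/g).

    Default: free-electron Klein-Nishina only — the quantity the idealized
    cavity-theory dose uses in the Compton-dominated regime.  With
    ``include_other_channels`` the (fixture-grade) photoelectric and pair
    energy-transfer terms are added.
    """
    E = np.asarray(E, dtype=float)
    alpha = E / M_E_C2
    mu = _MU_QUAD_X
    a = alpha[..., None]
    ap = a / (1.0 + a * (1.0 - mu))
    frac = (a - ap) / a
    r = ap / a
    K = math.pi * R_E**2 * r**2 * (r + 1.0 / r + mu**2 - 1.0)
    sigma_tr = (frac * K) @ _MU_QUAD_W
    out = material.electron_density / material.mass_density * sigma_tr
    if include_other_channels:
        pe = np.zeros_like(E, dtype=float)
        pr = np.zeros_like(E, dtype=float)
        for elem, n in zip(material.elements, material.number_densities):
            s_pe, _ = photoelectric(elem, E)
            pe = pe + n * s_pe           # photoelectron gets ~all of E
            pr = pr + n * element_photon_xs(elem, E, "pair")
        out = out + (pe + np.clip(1.0 - 2.0 * M_E_C2 / E, 0.0, None) * pr) \
            / material.mass_density
    return out
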