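"""Per-element atomic data built from documented analytic parameterizations.

Every table an element carries (atomic form factor, incoherent scattering
function, shell-wise Compton profiles, photoelectric / pair cross sections,
bremsstrahlung linear fit) is generated deterministically at build time from
closed-form approximations, so the package ships no external data files:

* ``F0(Z, q)`` — Moliere three-term fit to the Thomas-Fermi atomic form
  factor (the Fourier transform of a sum of three screened-exponential
  charge shells).
* ``S(Z, q)`` — impulse-approximation incoherent scattering function,
  obtained shell by shell as the integral of the Compton profile ``J_k`` up
  to the maximum projected momentum permitted when the photon loses at
  least the subshell binding energy (evaluated at backscatter kinematics so
  that S is a one-variable function of the momentum transfer q).
* ``J_k(p_z)`` — hydrogen-like per-shell profile with characteristic
  momentum set by the subshell binding energy,
  ``J(p) = 8 / (3 pi p0) * (1 + (p/p0)^2)^-3`` (unit normalized).
* photoelectric — Born K-shell cross section with a smooth blend between
  the nonrelativistic ``eps^-7/2`` and the high-energy ``1/eps`` regimes;
  subshell shares scale as ``n_i (E_i / E_K)^(3/2)``.
* pair production — Bethe-Heitler with complete-screening saturation and an
  empirical sub-asymptotic suppression.
* bremsstrahlung — linear fit ``f(k) = a (1 - b k)`` of a coarse
  complete-screening scaled spectrum evaluated at a 1 MeV reference.

These are fixture-grade approximations: the right shapes, normalizations
and orders of magnitude, adequate for exercising the transport algorithms,
not a replacement for evaluated data libraries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import (
    HARTREE_MEV,
    INV_FINE_STRUCTURE,
    K_COH,
    M_E_C2,
    R_E,
    SIGMA_THOMSON,
)

FIXTURE_VERSION = 1

#: shared log-spaced photon/electron energy grid (MeV) for all fixture tables
ENERGY_GRID = np.geomspace(1e-3, 100.0, 300)

#: momentum-transfer grid in 1/Angstrom (leading zero for the q=0 limits)
Q_GRID = np.concatenate([[0.0], np.geomspace(1e-3, 1e3, 240)])

_BOHR_ANGSTROM = 0.52917721067
_ALPHA_FS = 1.0 / INV_FINE_STRUCTURE

# symbol -> (Z, A g/mol, I eV, omega_K, shells as (label, E_b eV, occupancy))
# Subshell binding energies are rounded literature values; outer shells are
# lumped.  The first four labels K/L1/L2/L3 drive photoelectric sampling.
_ELEMENT_TABLE: dict[str, tuple] = {
    "H": (1, 1.008, 19.2, 0.0, [("K", 13.6, 1)]),
    "C": (6, 12.011, 78.0, 0.0028,
          [("K", 284.2, 2), ("L1", 19.4, 2), ("L3", 11.3, 2)]),
    "N": (7, 14.007, 82.0, 0.0052,
          [("K", 409.9, 2), ("L1", 37.3, 2), ("L3", 14.5, 3)]),
    "O": (8, 15.999, 95.0, 0.0083,
          [("K", 543.1, 2), ("L1", 41.6, 2), ("L3", 13.6, 4)]),
    "Al": (13, 26.9815385, 166.0, 0.0387,
           [("K", 1559.6, 2), ("L1", 117.8, 2), ("L2", 72.9, 2),
            ("L3", 72.5, 4), ("M", 10.6, 3)]),
    "P": (15, 30.973762, 173.0, 0.0632,
          [("K", 2145.5, 2), ("L1", 189.0, 2), ("L2", 136.0, 2),
           ("L3", 135.0, 4), ("M", 13.0, 5)]),
    "Ca": (20, 40.078, 191.0, 0.163,
           [("K", 4038.5, 2), ("L1", 438.4, 2), ("L2", 349.7, 2),
            ("L3", 346.2, 4), ("M", 34.0, 8), ("N", 6.1, 2)]),
    "Fe": (26, 55.845, 286.0, 0.347,
           [("K", 7112.0, 2), ("L1", 844.6, 2), ("L2", 719.9, 2),
            ("L3", 706.8, 4), ("M", 70.0, 14), ("N", 7.9, 2)]),
    "Pb": (82, 207.2, 823.0, 0.967,
           [("K", 88005.0, 2), ("L1", 15861.0, 2), ("L2", 15200.0, 2),
            ("L3", 13035.0, 4), ("M", 2900.0, 18), ("N", 700.0, 32),
            ("O", 105.0, 18), ("P", 7.4, 4)]),
}

SUPPORTED_ELEMENTS = tuple(_ELEMENT_TABLE)


@dataclass(frozen=True)
class Shell:
    label: str
    binding_energy: float      # MeV
    occupancy: int
    p0: float                  # Compton-profile momentum scale (atomic units)


@dataclass
class Element:
    """Atomic number, molar mass and all fixture physics tables."""

    symbol: str
    Z: int
    A: float                       # g/mol
    I: float                       # mean ionization energy, MeV
    fluorescence_yield_K: float
    shells: list[Shell]
    q_grid: np.ndarray = field(repr=False)
    form_factor: np.ndarray = field(repr=False)        # F0 on q_grid
    incoherent_function: np.ndarray = field(repr=False)  # S on q_grid
    pe_energy_grid: np.ndarray = field(repr=False)
    pe_xs: np.ndarray = field(repr=False)              # sigma_pe(E), cm^2
    pe_shell_fractions: np.ndarray = field(repr=False)  # (n_shell, n_E)
    pair_xs: np.ndarray = field(repr=False)            # sigma_pair(E), cm^2
    brems_a: float = 0.0                               # cm^2
    brems_b: float = 0.0

    @property
    def binding_energies(self) -> dict[str, float]:
        return {s.label: s.binding_energy for s in self.shells}

    @property
    def k_alpha_energy(self) -> float:
        """K fluorescence photon energy (K minus outermost L binding)."""
        eb = self.binding_energies
        e_l = min((v for k, v in eb.items() if k.startswith("L")),
                  default=0.0)
        return eb["K"] - e_l

    def f0(self, q):
        """Atomic form factor at momentum transfer q (1/Angstrom)."""
        q = np.asarray(q, dtype=float)
        return np.interp(q, self.q_grid, self.form_factor,
                         left=float(self.Z), right=0.0)

    def S(self, q):
        """Incoherent scattering function at momentum transfer q."""
        q = np.asarray(q, dtype=float)
        return np.interp(q, self.q_grid, self.incoherent_function,
                         left=0.0, right=float(self.Z))


def _moliere_form_factor(Z: int, q: np.ndarray) -> np.ndarray:
    # Moliere fit to the TF density; Q = 4*pi*q is the Fourier momentum
    # conjugate to r when q = sin(theta/2)/lambda.
    a_tf = 0.885 * _BOHR_ANGSTROM * Z ** (-1.0 / 3.0)
    alphas = (0.10, 0.55, 0.35)
    gammas = (6.0, 1.2, 0.3)
    Q2 = (4.0 * math.pi * q) ** 2
    out = np.zeros_like(Q2)
    for a_i, g_i in zip(alphas, gammas):
        lam2 = (g_i / a_tf) ** 2
        out += a_i * lam2 / (lam2 + Q2)
    return Z * out


def _profile_cdf(u):
    """CDF of the unit hydrogen-like profile at u = p/p0."""
    u = np.asarray(u, dtype=float)
    return (0.5 + np.arctan(u) / math.pi
            + (3.0 * u**3 + 5.0 * u) / (3.0 * math.pi * (1.0 + u**2) ** 2))


def _profile_ppf(xi, p0):
    """Inverse CDF of the hydrogen-like profile (bisection, vectorized)."""
    xi = np.asarray(xi, dtype=float)
    lo = np.full(xi.shape, -60.0)
    hi = np.full(xi.shape, 60.0)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        below = _profile_cdf(mid) < xi
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    return 0.5 * (lo + hi) * p0


def _pz_max(alpha: np.ndarray, binding: float) -> np.ndarray:
    """Largest projected momentum (a.u.) at backscatter for binding E_b."""
    ap = alpha - binding / M_E_C2
    num = 2.0 * alpha * ap - binding / M_E_C2
    return np.where(
        ap <= 0.0, -np.inf, INV_FINE_STRUCTURE * num / (alpha + ap))


def _incoherent_function(shells: list[Shell], q: np.ndarray) -> np.ndarray:
    # Map q -> incident photon energy via backscatter kinematics (mu = -1),
    # q = k * alpha * sqrt(2); then integrate each shell profile up to the
    # kinematic p_z limit for scattered energy E' = E - E_binding.
    alpha = q / (K_COH * math.sqrt(2.0))
    S = np.zeros_like(q)
    for sh in shells:
        pmax = _pz_max(alpha, sh.binding_energy)
        u = np.where(np.isfinite(pmax), pmax / sh.p0, -np.inf)
        S += sh.occupancy * np.where(
            np.isfinite(u), _profile_cdf(np.clip(u, -60, 60)), 0.0)
    return S


def _pe_unit_xs(Z: int, E: np.ndarray) -> np.ndarray:
    """Born K-shell photoelectric cross section (both K electrons), cm^2."""
    eps = E / M_E_C2
    # nonrelativistic eps^-7/2 branch dominating at low E, 1/eps at high E;
    # the sum has the right asymptotes and is monotone decreasing
    blend = math.sqrt(32.0) * eps ** -3.5 + 1.5 / eps
    return Z**5 * _ALPHA_FS**4 * SIGMA_THOMSON * blend


def _pair_xs(Z: int, E: np.ndarray) -> np.ndarray:
    eps = E / M_E_C2
    with np.errstate(divide="ignore", invalid="ignore"):
        born = 28.0 / 9.0 * np.log(np.maximum(2.0 * eps, 1.0)) - 218.0 / 27.0
    screened = 28.0 / 9.0 * math.log(183.0 * Z ** (-1.0 / 3.0)) - 2.0 / 27.0
    shape = np.minimum(born, screened)
    thresh = np.clip(1.0 - 2.0 / np.maximum(eps, 1e-12), 0.0, None) ** 3
    soft = eps / (eps + 25.0)
    out = _ALPHA_FS * R_E**2 * Z * (Z + 1) * shape * thresh * soft
    return np.clip(out, 0.0, None)


def _brems_fit(Z: int) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Linear fit a(1-bk) of the scaled complete-screening spectrum."""
    k = np.linspace(0.025, 0.975, 16)
    L = math.log(183.0 * Z ** (-1.0 / 3.0))
    f = 4.0 * _ALPHA_FS * R_E**2 * L * ((4.0 / 3.0) * (1.0 - k) + k**2)
    # least squares for f = a - (a b) k
    M = np.vstack([np.ones_like(k), -k]).T
    coef, *_ = np.linalg.lstsq(M, f, rcond=None)
    a, ab = coef
    b = float(np.clip(ab / a, 0.0, 1.0))
    return float(a), b, k, f


def build_element(symbol: str) -> Element:
    """Construct the full fixture Element for a supported symbol."""
    if symbol not in _ELEMENT_TABLE:
        raise ValueError(
            f"unsupported element {symbol!r}; supported: "
            f"{', '.join(SUPPORTED_ELEMENTS)}")
    Z, A, I_ev, wk, shell_rows = _ELEMENT_TABLE[symbol]
    shells = []
    for label, eb_ev, occ in shell_rows:
        eb = eb_ev * 1e-6
        p0 = math.sqrt(2.0 * eb / HARTREE_MEV)
        shells.append(Shell(label, eb, occ, p0))
    q = Q_GRID.copy()
    f0 = _moliere_form_factor(Z, q)
    f0[0] = float(Z)
    S = _incoherent_function(shells, q)
    S[0] = 0.0
    S = np.clip(S, 0.0, float(Z))

    E = ENERGY_GRID.copy()
    unit = _pe_unit_xs(Z, E)
    strengths = np.array(
        [s.occupancy * (s.binding_energy / shells[0].binding_energy) ** 1.5
         for s in shells])
    open_shell = np.array(
        [E > s.binding_energy for s in shells])        # (n_shell, n_E)
    weighted = strengths[:, None] * open_shell
    total_strength = weighted.sum(axis=0)
    sigma_pe = unit / strengths[0] * total_strength
    with np.errstate(invalid="ignore", divide="ignore"):
        fractions = np.where(total_strength > 0.0,
                             weighted / np.maximum(total_strength, 1e-300),
                             0.0)
    a, b, _, _ = _brems_fit(Z)
    return Element(
        symbol=symbol, Z=Z, A=A, I=I_ev * 1e-6, fluorescence_yield_K=wk,
        shells=shells, q_grid=q, form_factor=f0, incoherent_function=S,
        pe_energy_grid=E, pe_xs=sigma_pe, pe_shell_fractions=fractions,
        pair_xs=_pair_xs(Z, E), brems_a=a, brems_b=b)
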