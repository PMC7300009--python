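"""Materials: element mixtures with macroscopic number densities.

A material is a named mass-fraction mixture of fixture elements with a bulk
density.  Macroscopic quantities follow the usual additivity rule: the
macroscopic cross section is the number-density-weighted sum of the atomic
cross sections of the constituents.  The mean ionization energy may be set
explicitly (preferred, taken from standard compilations) or derived from
the Bragg ln-average.  The density-effect correction delta(T) uses the
Sternheimer recipe evaluated from (I, rho, composition) at construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import M_E_C2, N_A
from .elements import Element, build_element

_ELEMENT_CACHE: dict[str, Element] = {}


def get_element(symbol: str) -> Element:
    if symbol not in _ELEMENT_CACHE:
        _ELEMENT_CACHE[symbol] = build_element(symbol)
    return _ELEMENT_CACHE[symbol]


@dataclass(frozen=True)
class SternheimerFit:
    """delta(x) = 0 (x<x0); 4.606x - C + a(x1-x)^m (x0<=x<x1); 4.606x - C."""

    C: float
    a: float
    m: float
    x0: float
    x1: float

    def delta(self, T):
        """Density-effect correction at electron kinetic energy T (MeV)."""
        T = np.asarray(T, dtype=float)
        tau = T / M_E_C2
        bg = np.sqrt(np.maximum(tau * (tau + 2.0), 1e-300))
        x = np.log10(bg)
        full = 4.606 * x - self.C
        mid = full + self.a * np.clip(self.x1 - x, 0.0, None) ** self.m
        return np.where(x < self.x0, 0.0, np.where(x < self.x1, mid, full))


def _sternheimer_from_recipe(I_ev: float, rho: float,
                             z_over_a: float) -> SternheimerFit:
    plasma_ev = 28.816 * math.sqrt(max(rho * z_over_a, 1e-30))
    C = 2.0 * math.log(I_ev / plasma_ev) + 1.0
    if rho > 0.1:          # condensed media
        x0 = 0.2 if C < 3.681 else 0.326 * C - 1.0
        x1 = 2.0 if I_ev < 100.0 else 3.0
    else:                  # gases at NTP
        if C < 10.0:
            x0, x1 = 1.6, 4.0
        elif C < 10.5:
            x0, x1 = 1.7, 4.0
        else:
            x0, x1 = 1.8, 4.5
    m = 3.0
    a = max(C - 4.606 * x0, 0.0) / (x1 - x0) ** m
    return SternheimerFit(C=C, a=a, m=m, x0=x0, x1=x1)


@dataclass
class Material:
    name: str
    mass_fractions: dict[str, float]
    mass_density: float                       # g/cm^3
    I: float                                  # MeV
    elements: list[Element] = field(repr=False)
    number_densities: np.ndarray = field(repr=False)   # atoms/cm^3
    electron_density: float = 0.0             # electrons/cm^3
    density_effect: SternheimerFit | None = field(default=None, repr=False)

    @property
    def z_over_a(self) -> float:
        return sum(w * get_element(s).Z / get_element(s).A
                   for s, w in self.mass_fractions.items())

    def with_density(self, rho: float, name: str | None = None) -> "Material":
        """Same composition at a different bulk density."""
        return make_material(name or f"{self.name}(rho={rho:g})",
                             self.mass_fractions, rho, I_ev=self.I * 1e6)


def make_material(name: str, mass_fractions: dict[str, float], rho: float,
                  I_ev: float | None = None) -> Material:
    total = sum(mass_fractions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"mass fractions of {name!r} sum to {total}, not 1")
    elements = [get_element(s) for s in mass_fractions]
    w = np.array([mass_fractions[e.symbol] for e in elements])
    n_i = rho * w * N_A / np.array([e.A for e in elements])
    n_e = float(np.sum(n_i * np.array([e.Z for e in elements])))
    if I_ev is None:
        # Bragg ln-average over electrons
        zw = n_i * np.array([e.Z for e in elements])
        I_ev = math.exp(float(
            np.sum(zw * np.log([e.I * 1e6 for e in elements])) / np.sum(zw)))
    z_over_a = float(np.sum(w * np.array([e.Z / e.A for e in elements])))
    fit = _sternheimer_from_recipe(I_ev, rho, z_over_a)
    return Material(name=name, mass_fractions=dict(mass_fractions),
                    mass_density=rho, I=I_ev * 1e-6, elements=elements,
                    number_densities=n_i, electron_density=n_e,
                    density_effect=fit)


# name -> (composition, density g/cm^3, I eV)
_REGISTRY_SPEC: dict[str, tuple[dict[str, float], float, float | None]] = {
    "water": ({"H": 0.111894, "O": 0.888106}, 1.0, 75.0),
    "air": ({"C": 0.000124, "N": 0.764873, "O": 0.235003}, 1.205e-3, 85.7),
    "lung": ({"H": 0.111894, "O": 0.888106}, 0.26, 75.0),
    "soft_tissue": ({"H": 0.101172, "C": 0.111000, "N": 0.026000,
                     "O": 0.761828}, 1.0, 74.7),
    "cortical_bone": ({"H": 0.034205, "C": 0.155936, "N": 0.042254,
                       "O": 0.437625, "P": 0.103622, "Ca": 0.226358},
                      1.85, 106.4),
    "graphite": ({"C": 1.0}, 1.7, 78.0),
    "aluminum": ({"Al": 1.0}, 2.699, 166.0),
    "steel": ({"Fe": 1.0}, 7.87, 286.0),
}

_MATERIAL_CACHE: dict[str, Material] = {}


def get_material(name: str) -> Material:
    """Look up a registry material (cached)."""
    if name not in _MATERIAL_CACHE:
        if name not in _REGISTRY_SPEC:
            raise KeyError(
                f"unknown material {name!r}; known: "
                f"{', '.join(sorted(_REGISTRY_SPEC))}")
        comp, rho, I_ev = _REGISTRY_SPEC[name]
        _MATERIAL_CACHE[name] = make_material(name, comp, rho, I_ev)
    return _MATERIAL_CACHE[name]


def registry_names() -> list[str]:
    return sorted(_REGISTRY_SPEC)
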